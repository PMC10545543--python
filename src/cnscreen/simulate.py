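"""Synthetic data with known ground truth for every pipeline input.

Three generators mirror the three experimental readouts:

``simulate_screen``
    A pooled in vivo migration screen. Each replicate starts from one
    transduced blood pool (cells per guide ~ multinomial at the configured
    coverage); peripheral tissues subsample that pool neutrally
    (multivariate hypergeometric); CNS tissues subsample it with per-cell
    weights 2^(effect_lfc * efficacy) so that knockouts of migration
    facilitators are depleted and knockouts of brakes enriched; sequencing
    reads are negative-binomially distributed around the cell counts scaled
    to the target depth. Bottleneck-induced overdispersion therefore emerges
    at the cell level rather than being painted onto the reads.

``simulate_flow``
    Per-animal KO/control cell counts in a flow gate, binomially split
    according to a per-tissue true ratio.

``simulate_clones``
    Per-participant TCR clone structures in blood and CSF whose sharing
    probability follows a per-cluster migration propensity, plus a small
    expression matrix whose configured genes track that propensity linearly.

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so each artifact is reproducible in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .counts_io import CountMatrix
from .errors import ConfigError
from .library import NT_TARGET_ID, LibraryManifest, build_manifest

__all__ = [
    "CompartmentSpec",
    "EffectPriors",
    "SimConfig",
    "EffectTruth",
    "simulate_screen",
    "simulate_flow",
    "ClusterSpec",
    "CloneSimConfig",
    "simulate_clones",
]


@dataclass(frozen=True)
class CompartmentSpec:
    """One sampled tissue: bottleneck size (cells drawn from the blood pool)
    and whether planted migration effects act on entry (CNS tissues)."""

    name: str
    bottleneck: int
    cns: bool = False


def default_compartments(n_guides: int, bottleneck_coverage: float = 300.0):
    """Blood / spleen / meninges / parenchyma at a shared bottleneck coverage."""
    b = int(round(bottleneck_coverage * n_guides))
    return (
        CompartmentSpec("blood", b, cns=False),
        CompartmentSpec("spleen", b, cns=False),
        CompartmentSpec("meninges", b, cns=True),
        CompartmentSpec("parenchyma", b, cns=True),
    )


@dataclass(frozen=True)
class EffectPriors:
    """Counts and log2-fold-change priors for planted migration effects.

    ``facilitator_lfc`` is the change in CNS entry probability caused by a
    fully effective knockout of a facilitator (negative: the KO cell enters
    less); ``brake_lfc`` the mirrored positive value. Guide efficacies are
    Beta(``efficacy_a``, ``efficacy_b``) distributed (default mean 0.8).
    """

    n_facilitators: int = 0
    n_brakes: int = 0
    facilitator_lfc: float = -2.0
    brake_lfc: float = 2.0
    lfc_sd: float = 0.0
    efficacy_a: float = 8.0
    efficacy_b: float = 2.0


@dataclass
class SimConfig:
    """Study conditions for one simulated screen.

    Defaults follow the desk-scale screen exercised throughout the test
    suite: 2,000 genes x 4 sgRNAs + 800 NT guides at 1,000x pool coverage,
    four tissues at 300x bottlenecks, 3 replicates, ~500 reads per guide,
    mild negative-binomial overdispersion. ``seed`` is mandatory.
    """

    n_genes: int = 2000
    sgrnas_per_gene: int = 4
    n_nt: int = 800
    n_mirna: int = 0
    coverage: float = 1000.0
    compartments: tuple[CompartmentSpec, ...] | None = None
    replicates: int = 3
    depth: int | None = None  # reads per sample; default 500 * n_guides
    dispersion: float = 0.01
    effects: EffectPriors = field(default_factory=EffectPriors)
    seed: int | None = None

    @property
    def n_guides(self) -> int:
        return (self.n_genes + self.n_mirna) * self.sgrnas_per_gene + self.n_nt

    def resolved(self) -> "SimConfig":
        if self.seed is None:
            raise ConfigError("SimConfig.seed is mandatory")
        comps = self.compartments or default_compartments(self.n_guides)
        depth = self.depth if self.depth is not None else 500 * self.n_guides
        if depth < 1:
            raise ConfigError("depth must be >= 1")
        pool = int(round(self.coverage * self.n_guides))
        for c in comps:
            if c.bottleneck > pool:
                raise ConfigError(
                    f"bottleneck for {c.name} ({c.bottleneck}) exceeds pool size ({pool})"
                )
        return SimConfig(
            n_genes=self.n_genes, sgrnas_per_gene=self.sgrnas_per_gene,
            n_nt=self.n_nt, n_mirna=self.n_mirna, coverage=self.coverage,
            compartments=tuple(comps), replicates=self.replicates,
            depth=depth, dispersion=self.dispersion, effects=self.effects,
            seed=self.seed,
        )


@dataclass
class EffectTruth:
    """Planted ground truth: per-target effect class and lfc, per-guide
    efficacy in [0, 1]. NT targets are always class ``null``."""

    targets: pd.DataFrame  # index target_id; columns effect_class, effect_lfc
    efficacy: pd.Series    # index sgrna_id

    def to_frame(self) -> pd.DataFrame:
        return self.targets


def _draw_truth(
    manifest: LibraryManifest, priors: EffectPriors, rng: np.random.Generator
) -> EffectTruth:
    rec = manifest.records
    gene_targets = rec.loc[rec["target_type"] == "gene", "target_id"].unique()
    n_eff = priors.n_facilitators + priors.n_brakes
    if n_eff > len(gene_targets):
        raise ConfigError("more planted effects than gene targets")
    chosen = rng.choice(gene_targets, size=n_eff, replace=False)
    fac = set(chosen[: priors.n_facilitators])
    brk = set(chosen[priors.n_facilitators:])
    all_targets = rec["target_id"].unique()
    cls = pd.Series("null", index=pd.Index(all_targets, name="target_id"))
    lfc = pd.Series(0.0, index=cls.index)
    cls.loc[list(fac)] = "facilitator"
    cls.loc[list(brk)] = "brake"
    if fac:
        lfc.loc[list(fac)] = priors.facilitator_lfc + priors.lfc_sd * rng.standard_normal(len(fac))
    if brk:
        lfc.loc[list(brk)] = priors.brake_lfc + priors.lfc_sd * rng.standard_normal(len(brk))
    eff = pd.Series(
        rng.beta(priors.efficacy_a, priors.efficacy_b, size=len(rec)),
        index=pd.Index(rec["sgrna_id"], name="sgrna_id"),
        name="efficacy",
    )
    truth_targets = pd.DataFrame({"effect_class": cls, "effect_lfc": lfc})
    return EffectTruth(targets=truth_targets, efficacy=eff)


def _weighted_subsample(
    pool: np.ndarray, weights: np.ndarray, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Probability-proportional-to-weight subsample of cells without
    replacement, approximated by per-guide binomial thinning with inclusion
    probabilities capped at 1 and iteratively renormalised to the target
    size (Poisson sampling)."""
    pool = pool.astype(np.int64)
    if size > pool.sum():
        raise ConfigError("bottleneck exceeds pool size")
    pi = np.zeros_like(weights, dtype=float)
    free = np.ones_like(weights, dtype=bool)
    remaining = float(size)
    for _ in range(50):
        denom = float((pool[free] * weights[free]).sum())
        if denom <= 0:
            break
        c = remaining / denom
        pi[free] = np.minimum(1.0, c * weights[free])
        newly_capped = free & (pi >= 1.0)
        if not newly_capped.any():
            break
        free &= ~newly_capped
        remaining = size - float(pool[~free].sum())
        if remaining <= 0:
            break
    pi = np.clip(pi, 0.0, 1.0)
    return rng.binomial(pool, pi)


def _nb_reads(
    cells: np.ndarray, depth: int, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    total = cells.sum()
    if total == 0:
        return np.zeros_like(cells)
    mean = cells / total * depth
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, 1.0, size=mean.shape) / shape * mean
    return rng.poisson(lam)


def simulate_screen(config: SimConfig):
    """Generate one full screen: manifest, counts, metadata and truth.

    Returns ``(manifest, count_matrix, truth)`` where ``count_matrix`` is a
    :class:`~cnscreen.counts_io.CountMatrix` with attached sample metadata.
    Byte-identical for a fixed seed.
    """
    cfg = config.resolved()
    ss = np.random.SeedSequence(cfg.seed)
    s_manifest, s_truth, s_screen = ss.spawn(3)
    manifest = build_manifest(
        cfg.n_genes, cfg.sgrnas_per_gene, cfg.n_nt, cfg.n_mirna,
        seed=s_manifest.generate_state(1)[0] % (2**31),
    )
    rng_truth = np.random.default_rng(s_truth)
    truth = _draw_truth(manifest, cfg.effects, rng_truth)

    rec = manifest.records
    eff = truth.efficacy.to_numpy()
    tgt_lfc = truth.targets["effect_lfc"].reindex(rec["target_id"]).to_numpy()
    cns_weights = np.power(2.0, tgt_lfc * eff)

    n_guides = cfg.n_guides
    pool_size = int(round(cfg.coverage * n_guides))
    rng = np.random.default_rng(s_screen)

    cols = {}
    meta_rows = []
    for rep in range(1, cfg.replicates + 1):
        pool = rng.multinomial(pool_size, np.full(n_guides, 1.0 / n_guides))
        for comp in cfg.compartments:
            if comp.cns:
                cells = _weighted_subsample(pool, cns_weights, comp.bottleneck, rng)
            else:
                cells = rng.multivariate_hypergeometric(
                    pool, comp.bottleneck, method="marginals"
                )
            reads = _nb_reads(cells, cfg.depth, cfg.dispersion, rng)
            sample_id = f"{comp.name}_r{rep}"
            cols[sample_id] = reads
            meta_rows.append((sample_id, comp.name, rep))

    counts = pd.DataFrame(cols, index=pd.Index(rec["sgrna_id"], name="sgRNA"))
    counts = counts.astype(np.int64)
    meta = pd.DataFrame(
        meta_rows, columns=["sample_id", "tissue", "replicate"]
    ).set_index("sample_id")
    cm = CountMatrix(counts=counts, targets=manifest.targets, meta=meta)
    return manifest, cm, truth


def simulate_flow(
    n_animals: int,
    tissues: list[str],
    true_ratio: dict[str, float] | float,
    cells_per_gate: int | dict[str, int] = 2000,
    seed: int = 0,
    blood_label: str = "blood",
) -> pd.DataFrame:
    """Per-animal KO/control counts for a co-transfer experiment.

    Each (animal, tissue) gate of N cells is split KO vs control with
    ``ko ~ Binomial(N, r / (1 + r))`` at the tissue's true KO/control ratio
    r. Blood defaults to r = 1 unless overridden, so the blood-normalized
    migration ratio estimates the tissue r directly.
    """
    if not isinstance(true_ratio, dict):
        true_ratio = {t: float(true_ratio) for t in tissues}
    ratios = {blood_label: 1.0, **true_ratio}
    for t, r in ratios.items():
        if r <= 0:
            raise ConfigError(f"true_ratio for {t!r} must be > 0")
    all_tissues = [blood_label] + [t for t in tissues if t != blood_label]
    if not isinstance(cells_per_gate, dict):
        cells_per_gate = {t: int(cells_per_gate) for t in all_tissues}
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(1, n_animals + 1):
        for t in all_tissues:
            n = cells_per_gate.get(t, 2000)
            r = ratios.get(t, 1.0)
            ko = rng.binomial(n, r / (1.0 + r))
            rows.append((f"animal{a:03d}", t, int(ko), int(n - ko)))
    return pd.DataFrame(rows, columns=["animal_id", "tissue", "ko_count", "control_count"])


_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype="S1")


@dataclass(frozen=True)
class ClusterSpec:
    """A helper T cell cluster with a CNS migration propensity pi in [0, 1]:
    the probability that one of its blood clones also seeds the CSF."""

    name: str
    propensity: float

    def __post_init__(self):
        if not (0.0 <= self.propensity <= 1.0):
            raise ConfigError("cluster propensity must lie in [0, 1]")


@dataclass
class CloneSimConfig:
    """Conditions for the clonotype/expression generator.

    ``genes`` maps gene name -> (intercept, slope): the per-cluster mean
    log-normalized expression is ``intercept + slope * propensity`` plus
    Gaussian cell-level noise. ``clone_size_mean`` parameterises the
    geometric clone-size distribution in blood.
    """

    n_participants: int = 4
    clusters: tuple[ClusterSpec, ...] = ()
    n_cells_blood: int = 2000
    clone_size_mean: float = 2.0
    csf_extra_mean: float = 0.5
    genes: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_noise_genes: int = 5
    expr_noise_sd: float = 0.3
    group: str = "ms"
    seed: int | None = None


def _random_cdr3(rng: np.random.Generator) -> str:
    n = int(rng.integers(8, 17))
    middle = _AA[rng.integers(0, len(_AA), size=n)].tobytes().decode()
    return f"CASS{middle}F"


def simulate_clones(config: CloneSimConfig):
    """Generate clonotype-tagged cells and a small expression matrix.

    Returns ``(cells, expression, truth)``: a CellRecord-style DataFrame
    (cell_id, participant_id, group, compartment, cluster, tcrb_cdr3aa,
    n_beta_chains), a cells x genes DataFrame of log-normalized expression,
    and a per-cluster truth table with the generating propensities.

    Blood cells are partitioned into clones with geometric sizes and unique
    CDR3beta strings per clone per participant; each blood clone seeds the
    CSF with probability equal to its cluster's propensity, contributing
    1 + Poisson(csf_extra_mean) CSF cells.
    """
    cfg = config
    if cfg.seed is None:
        raise ConfigError("CloneSimConfig.seed is mandatory")
    if not cfg.clusters:
        raise ConfigError("at least one cluster is required")
    rng = np.random.default_rng(cfg.seed)
    p_geom = 1.0 / max(cfg.clone_size_mean, 1.0)
    clusters = list(cfg.clusters)
    gene_names = list(cfg.genes) + [f"noise{i + 1}" for i in range(cfg.n_noise_genes)]

    cell_rows = []
    expr_rows = []
    cell_counter = 0
    for p in range(1, cfg.n_participants + 1):
        pid = f"P{p:02d}"
        seen_cdr3: set[str] = set()
        per_cluster = rng.multinomial(
            cfg.n_cells_blood, np.full(len(clusters), 1.0 / len(clusters))
        )
        for spec, n_cells in zip(clusters, per_cluster):
            made = 0
            while made < n_cells:
                size = min(int(rng.geometric(p_geom)), n_cells - made)
                cdr3 = _random_cdr3(rng)
                while cdr3 in seen_cdr3:
                    cdr3 = _random_cdr3(rng)
                seen_cdr3.add(cdr3)
                overlap = rng.random() < spec.propensity
                n_csf = 1 + int(rng.poisson(cfg.csf_extra_mean)) if overlap else 0
                for comp, k in (("blood", size), ("csf", n_csf)):
                    for _ in range(k):
                        cell_counter += 1
                        cell_rows.append(
                            (f"cell{cell_counter:07d}", pid, cfg.group, comp,
                             spec.name, cdr3, 1)
                        )
                        mu = np.array(
                            [cfg.genes[g][0] + cfg.genes[g][1] * spec.propensity
                             for g in cfg.genes]
                            + [1.0] * cfg.n_noise_genes
                        )
                        expr_rows.append(mu + cfg.expr_noise_sd * rng.standard_normal(len(mu)))
                made += size

    cells = pd.DataFrame(
        cell_rows,
        columns=["cell_id", "participant_id", "group", "compartment",
                 "cluster", "tcrb_cdr3aa", "n_beta_chains"],
    )
    expression = pd.DataFrame(
        np.asarray(expr_rows), index=pd.Index(cells["cell_id"], name="cell_id"),
        columns=gene_names,
    )
    truth = pd.DataFrame(
        {"cluster": [c.name for c in clusters],
         "propensity": [c.propensity for c in clusters]}
    ).set_index("cluster")
    return cells, expression, truth
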