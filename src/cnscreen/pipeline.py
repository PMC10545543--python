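"""End-to-end screen analysis runs with plain-file handoff.

``run_pipeline`` ties the stages together: read counts + metadata, filter
low-count sgRNAs, normalize, test each configured tissue comparison, build
the NT pseudo-gene null per comparison, and call essential facilitators and
brakes. Every output lands in the run directory as TSV/JSON together with a
provenance record (config hash, seed, package version); no stage mutates
its inputs, so any stage can be re-run from the saved intermediates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .counts_io import CountMatrix, read_counts, read_sample_meta
from .errors import ConfigError
from .hit_selection import call_essential
from .screen_stats import (
    build_nt_null,
    filter_low_counts,
    gene_summary,
    normalize_counts,
    sgrna_test,
    size_factors,
    write_gene_summary,
)

log = logging.getLogger("cnscreen")

DEFAULT_COMPARISONS = (
    "meninges:blood",
    "parenchyma:blood",
    "meninges:spleen",
    "parenchyma:spleen",
    "spleen:blood",
)


@dataclass
class RunConfig:
    """Configuration for one pipeline run (seed mandatory)."""

    counts_path: str
    meta_path: str
    out_dir: str
    comparisons: tuple[str, ...] = DEFAULT_COMPARISONS
    count_threshold: int = 50
    max_low_replicates: int = 2
    norm_reference: str = "all"
    norm_min_count: int = 50
    pseudocount: float = 1.0
    alpha: float = 0.25
    n_perm: int = 1000
    nt_k: int = 4
    nt_n_pseudo: int = 800
    min_goodsgrna: int = 3
    p_cut: float = 0.05
    sd_mult: float = 3.0
    min_support: int = 3
    seed: int | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def parse_comparison(comp: str) -> tuple[str, str]:
    """Split 'tissueB:tissueA' into (B, A); B is the test group."""
    parts = comp.split(":")
    if len(parts) != 2 or not all(parts):
        raise ConfigError(f"comparison must look like 'meninges:blood', got {comp!r}")
    return parts[0], parts[1]


def run_pipeline(config: RunConfig, cm: CountMatrix | None = None) -> dict:
    """Run the full analysis; returns a dict of in-memory results.

    ``cm`` may be passed directly (e.g. fresh from the simulator) to skip
    re-reading the count files.
    """
    if config.seed is None:
        raise ConfigError("RunConfig.seed is mandatory")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if cm is None:
        meta = read_sample_meta(config.meta_path)
        cm = read_counts(config.counts_path, meta=meta)
    tissues = set(cm.meta["tissue"])
    for comp in config.comparisons:
        b, a = parse_comparison(comp)
        if b not in tissues or a not in tissues:
            raise ConfigError(
                f"comparison {comp!r} references tissue(s) absent from metadata "
                f"(have {sorted(tissues)})"
            )

    n_before = len(cm.counts)
    cm_f, dropped = filter_low_counts(
        cm, threshold=config.count_threshold, max_low_replicates=config.max_low_replicates
    )
    log.info("low-count filter: %d sgRNAs in, %d dropped", n_before, len(dropped))
    pd.Series(dropped, name="sgrna_id").to_csv(out / "dropped_sgrnas.tsv", sep="\t", index=False)

    factors = size_factors(cm_f, reference=config.norm_reference, min_count=config.norm_min_count)
    factors.to_csv(out / "size_factors.tsv", sep="\t")
    norm = normalize_counts(cm_f, factors)
    nt_ids = cm_f.nt_ids()

    summaries: dict[str, pd.DataFrame] = {}
    nulls = {}
    null_rows = []
    for i, comp in enumerate(config.comparisons):
        b, a = parse_comparison(comp)
        stats = sgrna_test(
            norm, cm_f.targets,
            group_a=cm_f.samples_for(a), group_b=cm_f.samples_for(b),
            nt_ids=nt_ids, pseudocount=config.pseudocount,
        )
        summary = gene_summary(
            stats, alpha=config.alpha, n_perm=config.n_perm,
            seed=config.seed + 101 * i,
        )
        summaries[comp] = summary
        write_gene_summary(summary, out / f"gene_summary.{comp.replace(':', '_vs_')}.tsv")
        nt_lfcs = stats.loc[stats.index.isin(nt_ids), "lfc"].to_numpy()
        null = build_nt_null(
            nt_lfcs, k=config.nt_k, n_pseudo=config.nt_n_pseudo,
            seed=config.seed + 101 * i + 50,
        )
        nulls[comp] = null
        null_rows.append({"comparison": comp, "sd": null.sd, "k": null.k,
                          "n_pseudo": null.n_pseudo})
        log.info("comparison %s: %d genes, NT null sd=%.4f", comp, len(summary), null.sd)
    pd.DataFrame(null_rows).to_csv(out / "nt_null.tsv", sep="\t", index=False)

    calls = call_essential(
        summaries, nulls,
        min_goodsgrna=config.min_goodsgrna, p_cut=config.p_cut,
        sd_mult=config.sd_mult, min_support=config.min_support,
    )
    calls.to_csv(out / "essential_calls.tsv", sep="\t")

    provenance = {
        "package": "cnscreen",
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_sgrna_in": n_before,
        "n_sgrna_dropped": len(dropped),
        "comparisons": list(config.comparisons),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return {
        "counts": cm_f,
        "size_factors": factors,
        "summaries": summaries,
        "nulls": nulls,
        "calls": calls,
        "dropped": dropped,
        "provenance": provenance,
    }
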