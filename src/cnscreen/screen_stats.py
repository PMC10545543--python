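"""Core screen statistics: filtering, normalization, per-sgRNA tests,
alpha-RRA gene aggregation, and the non-targeting resampling null.

The analysis chain for one tissue comparison (B vs A, e.g. meninges vs
blood) is:

1. drop sgRNAs with persistently low counts (``filter_low_counts``),
2. median-of-ratios normalization against a per-sgRNA geometric-mean
   pseudo-reference (``size_factors`` / ``normalize_counts``),
3. a per-sgRNA negative-binomial abundance test with a mean-variance
   relation fitted on the non-targeting (NT) guides (``sgrna_test``),
4. gene-level aggregation of directional rank percentiles by modified
   robust rank aggregation with a permutation p-value (``rra_aggregate``),
5. an NT pseudo-gene resampling null whose spread calibrates effect-size
   thresholds downstream (``build_nt_null``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .counts_io import CountMatrix
from .errors import NormalizationError, NullConstructionError

__all__ = [
    "filter_low_counts",
    "size_factors",
    "normalize_counts",
    "sgrna_test",
    "rra_aggregate",
    "gene_summary",
    "build_nt_null",
    "NtNull",
    "write_gene_summary",
    "read_gene_summary",
]


def filter_low_counts(
    cm: CountMatrix,
    threshold: int = 50,
    max_low_replicates: int = 2,
) -> tuple[CountMatrix, list[str]]:
    """Globally drop sgRNAs that are persistently low in any tissue.

    An sgRNA is discarded altogether when, in at least one tissue, the number
    of replicates with a raw count strictly below ``threshold`` exceeds
    ``max_low_replicates`` (i.e. "< 50 counts in more than two replicates of
    the same tissue" with the defaults). Removal applies to every sample.
    """
    if cm.meta is None:
        raise ValueError("filter_low_counts requires sample metadata")
    low = cm.counts < threshold
    drop = pd.Series(False, index=cm.counts.index)
    for tissue, sub in cm.meta.loc[list(cm.counts.columns)].groupby("tissue"):
        n_low = low[list(sub.index)].sum(axis=1)
        drop |= n_low > max_low_replicates
    dropped = list(cm.counts.index[drop])
    kept = CountMatrix(
        counts=cm.counts.loc[~drop].copy(),
        targets=cm.targets.loc[~drop].copy(),
        meta=cm.meta,
    )
    return kept, dropped


def size_factors(
    cm: CountMatrix,
    reference: str = "all",
    min_count: int = 50,
) -> pd.Series:
    """Per-sample size factors by median-of-ratios.

    The pseudo-reference for sgRNA i is the geometric mean g_i of its counts
    across samples; the factor of sample j is the median over reference
    sgRNAs of c_ij / g_i. The reference set is restricted to sgRNAs with all
    counts >= ``min_count`` (``reference='nt'`` additionally restricts to NT
    guides).
    """
    counts = cm.counts
    ref_mask = (counts >= min_count).all(axis=1)
    if reference == "nt":
        ref_mask &= cm.targets.index.isin(cm.nt_ids())
    elif reference != "all":
        raise ValueError("reference must be 'all' or 'nt'")
    ref = counts.loc[ref_mask].to_numpy(dtype=float)
    if ref.shape[0] == 0:
        raise NormalizationError(
            f"no sgRNA has all counts >= {min_count}; lower min_count"
        )
    log_g = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_g)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


def normalize_counts(cm: CountMatrix, factors: pd.Series | None = None, **kw) -> pd.DataFrame:
    """Counts divided by their sample size factors (float-valued)."""
    if factors is None:
        factors = size_factors(cm, **kw)
    return cm.counts / factors


def _fit_mean_variance(norm: pd.DataFrame, fit_ids: pd.Index) -> tuple[float, float]:
    """Least-squares fit of log(var) = a + b * log(mean) across sgRNAs."""
    sub = norm.loc[fit_ids]
    mean = sub.mean(axis=1).to_numpy()
    var = sub.var(axis=1, ddof=1).to_numpy()
    ok = (mean > 0) & (var > 0)
    if ok.sum() < 3:
        # Degenerate (e.g. noiseless synthetic data): fall back to Poisson.
        return 0.0, 1.0
    b, a = np.polyfit(np.log(mean[ok]), np.log(var[ok]), 1)
    return a, b


def sgrna_test(
    norm: pd.DataFrame,
    targets: pd.Series,
    group_a: list[str],
    group_b: list[str],
    nt_ids: list[str] | None = None,
    pseudocount: float = 1.0,
    min_nt_for_fit: int = 30,
) -> pd.DataFrame:
    """Per-sgRNA differential abundance between sample groups (B vs A).

    Returns a DataFrame indexed by sgrna_id with columns ``target_id``,
    ``mean_a``, ``mean_b``, ``lfc`` (log2((mean_b+pc)/(mean_a+pc))),
    one-sided ``p_low``/``p_high`` (depletion/enrichment in B), directional
    mid-rank percentiles ``rank_low``/``rank_high`` in (0, 1], and a
    ``flag_zero`` marker for sgRNAs that are all-zero in a group.

    The null model for the group-B count sum is a negative binomial centred
    on ``n_b * mean_a`` whose variance comes from a log-log mean-variance
    relation fitted on the NT guides across the comparison's samples
    (fallback: all guides when fewer than ``min_nt_for_fit`` NT guides are
    present). The modelled variance of the statistic includes the
    reference-estimation term: ``n_b * sigma^2(mu) * (1 + n_b / n_a)``.
    """
    if len(group_a) < 1 or len(group_b) < 1:
        raise ValueError("each group needs at least one sample")
    cols = list(dict.fromkeys(list(group_a) + list(group_b)))
    sub = norm[cols]
    a = norm[list(group_a)].to_numpy(dtype=float)
    b = norm[list(group_b)].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    lfc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    fit_ids = pd.Index(nt_ids or []).intersection(norm.index)
    if len(fit_ids) < min_nt_for_fit:
        fit_ids = norm.index
    a_fit, b_fit = _fit_mean_variance(sub, fit_ids)

    mu = mean_a
    p_low = np.ones(len(norm))
    p_high = np.ones(len(norm))
    ok = mu > 0
    mu_ok = mu[ok]
    var1 = np.exp(a_fit + b_fit * np.log(mu_ok))  # per-replicate count variance
    m_stat = n_b * mu_ok
    v_stat = n_b * var1 * (1.0 + n_b / n_a)
    s_b = np.rint(b.sum(axis=1)[ok]).astype(np.int64)

    nb = v_stat > m_stat * (1 + 1e-9)
    pl = np.empty(mu_ok.shape)
    ph = np.empty(mu_ok.shape)
    if nb.any():
        r = m_stat[nb] ** 2 / (v_stat[nb] - m_stat[nb])
        p_nb = r / (r + m_stat[nb])
        pl[nb] = sps.nbinom.cdf(s_b[nb], r, p_nb)
        ph[nb] = sps.nbinom.sf(s_b[nb] - 1, r, p_nb)
    if (~nb).any():
        # Modelled variance at or below the mean: Poisson tail.
        pl[~nb] = sps.poisson.cdf(s_b[~nb], m_stat[~nb])
        ph[~nb] = sps.poisson.sf(s_b[~nb] - 1, m_stat[~nb])
    p_low[ok] = pl
    p_high[ok] = ph
    p_low = np.clip(p_low, np.finfo(float).tiny, 1.0)
    p_high = np.clip(p_high, np.finfo(float).tiny, 1.0)
    # All-zero reference group: no evidence either way.
    p_low[~ok] = 1.0
    p_high[~ok] = 1.0
    flag_zero = ~ok | (mean_b == 0)

    n = len(norm)
    rank_low = sps.rankdata(p_low, method="average") / n
    rank_high = sps.rankdata(p_high, method="average") / n
    return pd.DataFrame(
        {
            "target_id": targets.reindex(norm.index).values,
            "mean_a": mean_a,
            "mean_b": mean_b,
            "lfc": lfc,
            "p_low": p_low,
            "p_high": p_high,
            "rank_low": rank_low,
            "rank_high": rank_high,
            "flag_zero": flag_zero,
        },
        index=norm.index,
    )


def _rho_from_sorted(r_sorted: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise alpha-RRA score from row-sorted percentile matrices.

    r_sorted has shape (m, n). For each row, beta_k = P[Binomial(n, r_(k))
    >= k]; the score is the minimum beta_k over the informative prefix
    (percentile <= alpha), or 1.0 if no member is informative.
    """
    m, n = r_sorted.shape
    k = np.arange(1, n + 1)
    beta = sps.binom.sf(k - 1, n, r_sorted)
    informative = r_sorted <= alpha
    beta = np.where(informative, beta, np.inf)
    rho = beta.min(axis=1)
    return np.where(np.isfinite(rho), rho, 1.0)


def rra_aggregate(
    stats: pd.DataFrame,
    direction: str = "neg",
    alpha: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
    gene_lfc: str = "median",
    exclude_targets: tuple[str, ...] | None = None,
    tie_break: str = "smoothed",
    chunk: int = 256,
) -> pd.DataFrame:
    """Aggregate per-sgRNA percentiles to gene scores by modified RRA.

    For a gene with sorted member percentiles r_(1) <= ... <= r_(n), members
    with percentile > ``alpha`` are non-informative; beta_k is the binomial
    tail P[Binomial(n, r_(k)) >= k]; the gene score rho is the minimum
    beta_k over informative k (1.0 when none). The gene p-value compares rho
    against ``n_perm`` random same-size sets of percentiles drawn (with
    replacement, independently per gene) from the full percentile pool.
    With ``tie_break='conservative'`` this is the plain permutation p-value
    ``p = (1 + #{rho' <= rho}) / (n_perm + 1)``. The default
    ``tie_break='smoothed'`` randomizes over null ties,
    ``p = (1 + #{rho' < rho} + U * #{rho' = rho}) / (n_perm + 1)`` with
    U ~ Uniform[0, 1) drawn per gene: the two coincide whenever rho is
    untied, but the score distribution has an atom at rho = 1 (genes with
    no informative member), and only the smoothed form is uniform under the
    null there. Both respect the floor ``1 / (n_perm + 1)``. ``goodsgrna``
    counts the informative members; the gene lfc is the median (or mean) of
    member sgRNA lfcs.

    ``direction='neg'`` scores depletion (uses ``rank_low``), ``'pos'``
    enrichment (``rank_high``). NT guides contribute to the percentile pool
    but NT pseudo-targets are excluded from the gene table by default.
    """
    if direction not in ("neg", "pos"):
        raise ValueError("direction must be 'neg' or 'pos'")
    from .library import NT_TARGET_ID

    if exclude_targets is None:
        exclude_targets = (NT_TARGET_ID,)
    col = "rank_low" if direction == "neg" else "rank_high"
    pool = stats[col].to_numpy()
    rng = np.random.default_rng(seed)

    work = stats.loc[~stats["target_id"].isin(exclude_targets)]
    sizes = work.groupby("target_id").size()
    out_rows = []
    reducer = np.median if gene_lfc == "median" else np.mean
    for n, genes_n in sizes.groupby(sizes):
        gene_ids = list(genes_n.index)
        sel = work.loc[work["target_id"].isin(gene_ids)]
        # (G, n) percentile matrix in gene order
        grouped = sel.groupby("target_id")
        r = np.stack([np.sort(grouped.get_group(g)[col].to_numpy()) for g in gene_ids])
        lfcs = np.array([reducer(grouped.get_group(g)["lfc"].to_numpy()) for g in gene_ids])
        rho = _rho_from_sorted(r, alpha)
        good = (r <= alpha).sum(axis=1)
        # Independent permutation null per gene, chunked to bound memory.
        n_lt = np.zeros(len(gene_ids), dtype=np.int64)
        n_eq = np.zeros(len(gene_ids), dtype=np.int64)
        for lo in range(0, len(gene_ids), chunk):
            hi = min(lo + chunk, len(gene_ids))
            draws = rng.choice(pool, size=(hi - lo, n_perm, n), replace=True)
            draws.sort(axis=2)
            rho_null = _rho_from_sorted(
                draws.reshape(-1, n), alpha
            ).reshape(hi - lo, n_perm)
            n_lt[lo:hi] = (rho_null < rho[lo:hi, None]).sum(axis=1)
            n_eq[lo:hi] = (rho_null == rho[lo:hi, None]).sum(axis=1)
        if tie_break == "smoothed":
            u = rng.random(len(gene_ids))
            p = (1.0 + n_lt + u * n_eq) / (n_perm + 1.0)
        elif tie_break == "conservative":
            p = (1.0 + n_lt + n_eq) / (n_perm + 1.0)
        else:
            raise ValueError("tie_break must be 'smoothed' or 'conservative'")
        p = np.minimum(p, 1.0)
        for i, g in enumerate(gene_ids):
            out_rows.append((g, n, rho[i], p[i], good[i], lfcs[i]))
    out = pd.DataFrame(
        out_rows, columns=["target_id", "n_sgrna", "score", "p", "goodsgrna", "lfc"]
    ).set_index("target_id")
    return out.sort_index()


def gene_summary(
    stats: pd.DataFrame,
    alpha: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
    gene_lfc: str = "median",
    tie_break: str = "smoothed",
) -> pd.DataFrame:
    """Two-directional gene summary (depletion and enrichment).

    Columns: ``num``, ``neg_score``, ``neg_p``, ``neg_goodsgrna``,
    ``neg_lfc``, and the ``pos_*`` counterparts; indexed by target_id.
    The neg and pos lfc columns both carry the gene-level lfc (median of
    member sgRNA lfcs by default).
    """
    neg = rra_aggregate(stats, "neg", alpha, n_perm, seed, gene_lfc, tie_break=tie_break)
    pos = rra_aggregate(stats, "pos", alpha, n_perm, seed + 1, gene_lfc, tie_break=tie_break)
    out = pd.DataFrame(index=neg.index)
    out["num"] = neg["n_sgrna"]
    for d, tab in (("neg", neg), ("pos", pos)):
        out[f"{d}_score"] = tab["score"]
        out[f"{d}_p"] = tab["p"]
        out[f"{d}_goodsgrna"] = tab["goodsgrna"]
        out[f"{d}_lfc"] = tab["lfc"]
    return out


_MAGECK_COLS = {
    "num": "num",
    "neg_score": "neg|score",
    "neg_p": "neg|p-value",
    "neg_lfc": "neg|lfc",
    "neg_goodsgrna": "neg|goodsgrna",
    "pos_score": "pos|score",
    "pos_p": "pos|p-value",
    "pos_lfc": "pos|lfc",
    "pos_goodsgrna": "pos|goodsgrna",
}


def write_gene_summary(summary: pd.DataFrame, path) -> None:
    """Write a gene summary TSV with MAGeCK-compatible column names."""
    out = summary.rename(columns=_MAGECK_COLS)
    out.index.name = "id"
    cols = ["num"] + [c for c in _MAGECK_COLS.values() if c != "num"]
    out[cols].to_csv(path, sep="\t")


def read_gene_summary(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id")
    df.index.name = "target_id"
    inv = {v: k for k, v in _MAGECK_COLS.items()}
    return df.rename(columns=inv)


@dataclass
class NtNull:
    """Non-targeting pseudo-gene resampling null.

    ``pseudo_lfcs`` holds ``n_pseudo`` pseudo-gene lfc values, each the mean
    of ``k`` NT sgRNA lfcs drawn with replacement; ``sd`` is their pooled
    standard deviation, the scale behind "3 x SD of the NT lfcs" effect-size
    thresholds.
    """

    pseudo_lfcs: np.ndarray
    k: int
    n_pseudo: int
    sd: float
    seed: int


def build_nt_null(
    nt_lfcs,
    k: int = 4,
    n_pseudo: int = 800,
    seed: int = 0,
) -> NtNull:
    """Resample NT sgRNA lfcs into pseudo-gene lfcs.

    Draws ``k`` NT lfc values with replacement and averages them, ``n_pseudo``
    times; deterministic for a fixed seed.
    """
    nt_lfcs = np.asarray(nt_lfcs, dtype=float)
    if nt_lfcs.size < k:
        raise NullConstructionError(
            f"need at least k={k} NT lfc values, got {nt_lfcs.size}"
        )
    rng = np.random.default_rng(seed)
    draws = rng.choice(nt_lfcs, size=(n_pseudo, k), replace=True)
    pseudo = draws.mean(axis=1)
    sd = float(pseudo.std(ddof=1)) if n_pseudo > 1 else 0.0
    return NtNull(pseudo_lfcs=pseudo, k=k, n_pseudo=n_pseudo, sd=sd, seed=seed)
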