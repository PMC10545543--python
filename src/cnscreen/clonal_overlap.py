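"""TCR-based blood-CSF clonal overlap and migration-propensity statistics.

Single T cells carry their TCRbeta CDR3 amino-acid sequence as a clonal
tag. A cell is *overlapping* when its clonotype occurs in both the blood
and the CSF of the same participant; overlapping clones seen at least three
times in total are *expanded*. The per-cluster "CNS migration propensity"
is the percentage of a cluster's blood cells that are overlapping, and is
correlated (Pearson) with per-cluster regulator expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import UndefinedCorrelationError

__all__ = [
    "restrict_cells",
    "flag_overlap",
    "cluster_overlap",
    "correlate_propensity",
    "CorrelationResult",
    "flag_significant_genes",
]

CELL_COLUMNS = [
    "cell_id", "participant_id", "group", "compartment", "cluster",
    "tcrb_cdr3aa", "n_beta_chains",
]

EXPANDED_MIN_TOTAL = 3


def restrict_cells(cells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Keep cells with exactly one beta chain and a non-empty CDR3.

    Returns the analysis set and a report of how many cells were excluded
    for each reason (nothing is dropped silently).
    """
    missing = [c for c in CELL_COLUMNS if c not in cells.columns]
    if missing:
        raise ValueError(f"cell table missing columns: {missing}")
    multi = cells["n_beta_chains"] != 1
    empty = cells["tcrb_cdr3aa"].isna() | (cells["tcrb_cdr3aa"].astype(str) == "")
    keep = ~(multi | empty)
    report = {
        "n_input": len(cells),
        "n_multi_beta": int(multi.sum()),
        "n_empty_cdr3": int((empty & ~multi).sum()),
        "n_kept": int(keep.sum()),
    }
    return cells.loc[keep].copy(), report


def flag_overlap(
    cells: pd.DataFrame,
    clonotype_cols: tuple[str, ...] = ("tcrb_cdr3aa",),
) -> pd.DataFrame:
    """Add ``is_overlapping`` and ``is_expanded`` flags.

    The clonotype key is (participant_id, *clonotype_cols); by default the
    CDR3beta amino-acid sequence alone (add V/J columns via
    ``clonotype_cols`` to sharpen the key). A clone is overlapping when its
    key occurs in both compartments of the same participant; expanded when
    overlapping and seen >= 3 times in total across both compartments.
    """
    cells, _ = restrict_cells(cells)
    key_cols = ["participant_id", *clonotype_cols]
    grp = cells.groupby(key_cols)["compartment"]
    n_comp = grp.transform("nunique")
    total = grp.transform("size")
    cells = cells.copy()
    cells["is_overlapping"] = (n_comp >= 2).to_numpy()
    cells["is_expanded"] = cells["is_overlapping"] & (total >= EXPANDED_MIN_TOTAL).to_numpy()
    return cells


def cluster_overlap(
    cells: pd.DataFrame,
    expression: pd.DataFrame | None = None,
    genes: tuple[str, ...] = (),
    expr_stat: str = "mean",
) -> pd.DataFrame:
    """Per-cluster, per-group overlap fractions among blood cells.

    ``pct_overlapping = 100 * n_overlapping / n_cells_blood`` where both
    counts are over the cluster's blood cells of the group. If an
    expression matrix (cells x genes, log-normalized) is given, the mean
    (or median) expression of each queried gene over those same blood cells
    is appended. Clusters with zero blood cells in a group are flagged
    (``undefined = True``) rather than dropped.
    """
    if "is_overlapping" not in cells.columns:
        cells = flag_overlap(cells)
    blood = cells.loc[cells["compartment"] == "blood"]
    reducer = "median" if expr_stat == "median" else "mean"
    rows = []
    for (cluster, group), sub in blood.groupby(["cluster", "group"], observed=True):
        n = len(sub)
        n_ov = int(sub["is_overlapping"].sum())
        pct = 100.0 * n_ov / n if n else np.nan
        row = {"cluster": cluster, "group": group, "n_cells_blood": n,
               "n_overlapping": n_ov, "pct_overlapping": pct, "undefined": n == 0}
        if expression is not None:
            sub_expr = expression.reindex(sub["cell_id"])
            for g in genes:
                row[f"mean_expr_{g}"] = getattr(sub_expr[g], reducer)()
        rows.append(row)
    # groups with clusters entirely absent from blood are also flagged
    all_pairs = {(c, g) for c in cells["cluster"].unique() for g in cells["group"].unique()}
    seen = {(r["cluster"], r["group"]) for r in rows}
    for cluster, group in sorted(all_pairs - seen):
        if ((cells["cluster"] == cluster) & (cells["group"] == group)).any():
            row = {"cluster": cluster, "group": group, "n_cells_blood": 0,
                   "n_overlapping": 0, "pct_overlapping": np.nan, "undefined": True}
            for g in genes:
                row[f"mean_expr_{g}"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows).sort_values(["group", "cluster"]).reset_index(drop=True)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n_clusters: int


def correlate_propensity(
    overlap: pd.DataFrame,
    values,
) -> CorrelationResult:
    """Pearson correlation between per-cluster overlap and a quantity.

    ``values`` is either a gene name (the ``mean_expr_<gene>`` column of the
    overlap table) or a Series indexed by cluster (e.g. an externally
    supplied MS-vs-control expression lfc per cluster). Clusters with
    undefined propensity are dropped; at least 3 must remain. The p-value
    comes from the t transform on n - 2 degrees of freedom.
    """
    tab = overlap.loc[~overlap["undefined"]]
    if isinstance(values, str):
        col = f"mean_expr_{values}"
        if col not in tab.columns:
            raise KeyError(f"no expression column for gene {values!r}")
        y = tab[col].to_numpy(dtype=float)
        x = tab["pct_overlapping"].to_numpy(dtype=float)
    else:
        values = pd.Series(values)
        tab = tab.set_index("cluster")
        common = tab.index.intersection(values.index)
        tab = tab.loc[common]
        x = tab["pct_overlapping"].to_numpy(dtype=float)
        y = values.loc[common].to_numpy(dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need at least 3 clusters with defined propensity")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in correlation input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(float(res.statistic), float(res.pvalue), len(x))


def flag_significant_genes(
    de: pd.DataFrame,
    sd_mult: float = 3.0,
    p_col: str = "p_adj",
    lfc_col: str = "lfc",
) -> pd.Series:
    """Flag differentially expressed genes by adjusted p and effect size.

    A gene is flagged when ``p_adj < 0.05`` and ``|lfc|`` strictly exceeds
    ``sd_mult`` times the standard deviation of all lfcs in the table (the
    sample's own spread sets the effect-size bar).
    """
    lfcs = de[lfc_col].to_numpy(dtype=float)
    sd = float(np.std(lfcs, ddof=1)) if len(lfcs) > 1 else 0.0
    flags = (de[p_col] < 0.05) & (np.abs(de[lfc_col]) > sd_mult * sd)
    return pd.Series(flags.to_numpy(), index=de.index, name="significant")
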