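"""Flow-cytometry co-transfer statistics.

In a co-transfer experiment a knockout (KO) population and a control
population are injected into the same animal; the readout per tissue is the
KO/control cell-count ratio normalized to the same animal's blood ratio, so
1 means "no migration effect". Ratios are tested against 1 with a one-sample
location test (t when Shapiro-Wilk accepts normality, Wilcoxon signed-rank
otherwise), and families of tests are FDR-adjusted with the two-stage
linear step-up procedure of Benjamini, Krieger and Yekutieli (BKY).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateInputError

__all__ = [
    "migration_ratio",
    "one_sample_location_test",
    "TestResult",
    "adjust_bky",
]

MIN_CELLS = 100


def migration_ratio(
    flow: pd.DataFrame,
    blood_label: str = "blood",
    min_cells: int = MIN_CELLS,
) -> pd.DataFrame:
    """Blood-normalized KO/control ratios per animal and tissue.

    ``flow`` has columns ``animal_id, tissue, ko_count, control_count``.
    The ratio for tissue t of animal a is
    ``(ko_t / control_t) / (ko_blood / control_blood)``. An animal-tissue
    record is excluded (with a reason) when any of the four referenced
    populations has fewer than ``min_cells`` cells, or when the animal has
    no blood row. Blood rows themselves are not returned.
    """
    required = {"animal_id", "tissue", "ko_count", "control_count"}
    missing = required - set(flow.columns)
    if missing:
        raise ValueError(f"flow table missing columns: {sorted(missing)}")
    rows = []
    for animal, sub in flow.groupby("animal_id", sort=False):
        blood = sub.loc[sub["tissue"] == blood_label]
        has_blood = len(blood) == 1
        if has_blood:
            b_ko = float(blood["ko_count"].iloc[0])
            b_ctl = float(blood["control_count"].iloc[0])
        for _, r in sub.loc[sub["tissue"] != blood_label].iterrows():
            ko, ctl = float(r["ko_count"]), float(r["control_count"])
            if not has_blood:
                rows.append((animal, r["tissue"], ko, ctl, np.nan, True, "missing blood row"))
                continue
            pops = {"tissue KO": ko, "tissue control": ctl,
                    "blood KO": b_ko, "blood control": b_ctl}
            low = [name for name, v in pops.items() if v < min_cells]
            if low:
                rows.append((animal, r["tissue"], ko, ctl, np.nan, True,
                             f"<{min_cells} cells in {', '.join(low)}"))
                continue
            ratio = (ko / ctl) / (b_ko / b_ctl)
            rows.append((animal, r["tissue"], ko, ctl, ratio, False, ""))
    return pd.DataFrame(
        rows,
        columns=["animal_id", "tissue", "ko_count", "control_count",
                 "normalized_ratio", "excluded", "reason"],
    )


@dataclass(frozen=True)
class TestResult:
    """One-sample location test outcome against a hypothetical mean."""

    method: str  # 't' or 'wilcoxon'
    statistic: float
    p_two_sided: float
    n: int
    mean: float
    sd: float


def one_sample_location_test(
    values=None,
    mean: float | None = None,
    sd: float | None = None,
    n: int | None = None,
    mu: float = 1.0,
    gate_alpha: float = 0.05,
) -> TestResult:
    """Test whether a sample's location differs from ``mu`` (two-sided).

    With raw ``values``, a Shapiro-Wilk test at ``gate_alpha`` gates the
    choice: one-sample t-test when normality is not rejected, Wilcoxon
    signed-rank otherwise (exact null for n <= 25 without ties, normal
    approximation with continuity correction above). With summary
    statistics (``mean``, ``sd``, ``n``) only the t-test is possible:
    ``t = (mean - mu) / (sd / sqrt(n))`` on n - 1 degrees of freedom.
    """
    if values is not None:
        values = np.asarray(values, dtype=float)
        n = len(values)
        if n < 2:
            raise DegenerateInputError("need at least 2 observations")
        m, s = float(values.mean()), float(values.std(ddof=1))
        if s == 0.0:
            if m == mu:
                return TestResult("t", 0.0, 1.0, n, m, s)
            raise DegenerateInputError(
                "zero variance with mean != mu: location test undefined"
            )
        normal = True
        if n >= 3:
            normal = sps.shapiro(values).pvalue >= gate_alpha
        if normal:
            t, p = sps.ttest_1samp(values, mu)
            return TestResult("t", float(t), float(p), n, m, s)
        diffs = values - mu
        method = "exact" if n <= 25 and len(np.unique(np.abs(diffs))) == n else "approx"
        res = sps.wilcoxon(diffs, method=method, correction=True)
        return TestResult("wilcoxon", float(res.statistic), float(res.pvalue), n, m, s)
    if mean is None or sd is None or n is None:
        raise ValueError("provide either values or (mean, sd, n)")
    if n < 2:
        raise DegenerateInputError("summary t-test needs n >= 2")
    if sd == 0.0:
        if mean == mu:
            return TestResult("t", 0.0, 1.0, n, mean, sd)
        raise DegenerateInputError("zero sd with mean != mu")
    t = (mean - mu) / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult("t", float(t), float(p), int(n), float(mean), float(sd))


def adjust_bky(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Two-stage linear step-up FDR control (BKY 2006, Definition 6).

    Stage 1 runs Benjamini-Hochberg at q' = q / (1 + q) to estimate the
    number of true nulls m0 = m - r1; stage 2 re-runs the step-up with
    critical values i * q' / m0. Returns ``(reject, adjusted)`` where
    ``adjusted <= q`` if and only if rejected; flags are monotone in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    qp = q / (1.0 + q)
    order = np.argsort(p, kind="stable")
    ps = p[order]
    i = np.arange(1, m + 1)

    r1 = _stepup_count(ps, i * qp / m)
    if r1 == 0:
        reject = np.zeros(m, dtype=bool)
        m0 = m
    elif r1 == m:
        reject = np.ones(m, dtype=bool)
        m0 = m  # adjusted values below still well-defined
    else:
        m0 = m - r1
        r2 = _stepup_count(ps, i * qp / m0)
        reject = np.zeros(m, dtype=bool)
        reject[order[:r2]] = True
        # adjusted defined against the stage-2 critical line
    if r1 in (0, m):
        m0_adj = m if r1 == 0 else max(m - r1, 1)
    else:
        m0_adj = m0
    raw_adj = (1.0 + q) * m0_adj * ps / i
    adj_sorted = np.minimum.accumulate(raw_adj[::-1])[::-1]
    adj_sorted = np.clip(adj_sorted, 0.0, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    if r1 == m:
        reject = np.ones(m, dtype=bool)
    elif r1 == 0:
        reject = np.zeros(m, dtype=bool)
    return reject, adjusted


def _stepup_count(ps_sorted: np.ndarray, crit: np.ndarray) -> int:
    """Number of rejections of a linear step-up rule given sorted p-values."""
    below = ps_sorted <= crit
    if not below.any():
        return 0
    return int(np.max(np.nonzero(below)[0]) + 1)
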