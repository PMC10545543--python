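"""Candidate selection tiers and essentiality calling.

Two decision layers sit on top of the per-comparison gene summaries:

``select_candidates``
    The genome-wide -> validation funnel. CNS-versus-blood comparisons
    admit any gene with |lfc| > 0.5; the remaining comparisons admit genes
    with |lfc| > 1 and >= 2 directional goodsgrna, or |lfc| > 0.6 and > 2
    goodsgrna in either direction. Genes not expressed in T cells are then
    dropped unless a CNS-versus-blood comparison carried them with
    |lfc| > 0.85; externally supplied gene sets (GO-derived expansions) are
    unioned in verbatim.

``call_essential``
    The validation-screen facilitator/brake call: a gene is a facilitator
    in a comparison when its depletion lfc is below -3 standard deviations
    of the NT pseudo-gene lfc null, with >= 3 supporting sgRNAs and a
    depletion p-value < 0.05; brakes use the mirrored enrichment rule. The
    aggregate "essential" flag requires the same directional call in at
    least three pairwise tissue comparisons.

All inequalities are implemented exactly as stated (strict vs non-strict),
table-driven and unit-tested at the boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CallingError, ConfigError
from .screen_stats import NtNull

__all__ = ["SelectionConfig", "select_candidates", "call_essential"]

CNS_VS_BLOOD = ("meninges:blood", "parenchyma:blood")
OTHER_COMPARISONS = ("meninges:spleen", "parenchyma:spleen", "spleen:blood")


@dataclass
class SelectionConfig:
    """Thresholds and auxiliary gene lists for candidate selection.

    The defaults are the published funnel: 0.5 (CNS-vs-blood lfc), 1 and
    0.6 (other-comparison lfc tiers), 0.85 (expression-filter rescue), 2
    (goodsgrna cutoffs, ">= 2" for the strong tier and "> 2" for the weak
    tier). ``expressed_genes=None`` disables the expression filter.
    ``directional_weak_tier=True`` restricts the weak tier's goodsgrna to
    the lfc's own direction instead of accepting either direction.
    """

    cns_lfc: float = 0.5
    other_lfc_strong: float = 1.0
    other_goodsgrna_strong: int = 2
    other_lfc_weak: float = 0.6
    other_goodsgrna_weak: int = 2
    rescue_lfc: float = 0.85
    expressed_genes: set | None = None
    extra_lists: dict[str, set] = field(default_factory=dict)
    cns_comparisons: tuple[str, ...] = CNS_VS_BLOOD
    other_comparisons: tuple[str, ...] = OTHER_COMPARISONS
    directional_weak_tier: bool = False

    def __post_init__(self):
        for name in ("cns_lfc", "other_lfc_strong", "other_lfc_weak", "rescue_lfc"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")


def _gene_lfc(row) -> float:
    # neg_lfc and pos_lfc carry the same gene-level value; neg_lfc is canonical.
    return row["neg_lfc"]


def select_candidates(
    summaries: dict[str, pd.DataFrame],
    config: SelectionConfig,
) -> tuple[set, pd.DataFrame]:
    """Apply the tiered selection funnel across comparisons.

    ``summaries`` maps comparison name ('tissueB:tissueA') to a gene
    summary (as from :func:`cnscreen.screen_stats.gene_summary`). Returns
    the selected gene set and a provenance table recording which rule
    admitted each gene in which comparison.
    """
    known = set(config.cns_comparisons) | set(config.other_comparisons)
    unknown = set(summaries) - known
    if unknown:
        raise ConfigError(
            f"unknown comparison name(s): {sorted(unknown)}; expected from {sorted(known)}"
        )
    prov_rows = []
    for comp, summary in summaries.items():
        is_cns = comp in config.cns_comparisons
        for gene, row in summary.iterrows():
            lfc = _gene_lfc(row)
            alfc = abs(lfc)
            if is_cns:
                if alfc > config.cns_lfc:
                    prov_rows.append((gene, comp, "cns_lfc", lfc, alfc > config.rescue_lfc))
            else:
                good_dir = row["neg_goodsgrna"] if lfc < 0 else row["pos_goodsgrna"]
                strong = alfc > config.other_lfc_strong and good_dir >= config.other_goodsgrna_strong
                if config.directional_weak_tier:
                    good_weak = good_dir
                else:
                    good_weak = max(row["neg_goodsgrna"], row["pos_goodsgrna"])
                weak = alfc > config.other_lfc_weak and good_weak > config.other_goodsgrna_weak
                if strong:
                    prov_rows.append((gene, comp, "other_strong", lfc, False))
                elif weak:
                    prov_rows.append((gene, comp, "other_weak", lfc, False))
    prov = pd.DataFrame(
        prov_rows, columns=["gene", "comparison", "rule", "lfc", "rescues_expression"]
    )

    if config.expressed_genes is not None:
        expressed = set(config.expressed_genes)
        keep = prov["gene"].isin(expressed) | prov.groupby("gene")[
            "rescues_expression"
        ].transform("any")
        dropped = prov.loc[~keep, ["gene", "comparison", "lfc"]].assign(
            rule="dropped_not_expressed", rescues_expression=False
        )
        prov = pd.concat([prov.loc[keep], dropped], ignore_index=True)
        selected = set(prov.loc[prov["rule"] != "dropped_not_expressed", "gene"])
    else:
        selected = set(prov["gene"])

    for name, genes in config.extra_lists.items():
        new = set(genes)
        prov = pd.concat(
            [prov, pd.DataFrame({
                "gene": sorted(new), "comparison": "",
                "rule": f"extra_list:{name}", "lfc": np.nan,
                "rescues_expression": False,
            })],
            ignore_index=True,
        )
        selected |= new
    return selected, prov


def call_essential(
    summaries: dict[str, pd.DataFrame],
    nt_nulls: dict[str, NtNull],
    min_goodsgrna: int = 3,
    p_cut: float = 0.05,
    sd_mult: float = 3.0,
    min_support: int = 3,
) -> pd.DataFrame:
    """Facilitator/brake calls per gene per comparison, plus aggregates.

    Facilitator in a comparison: ``neg_lfc < -sd_mult * sd_NT`` and
    ``neg_goodsgrna >= min_goodsgrna`` and ``neg_p < p_cut``; brake is the
    mirrored ``pos_*`` rule. Per comparison the two calls are mutually
    exclusive (the lfc sign decides the direction). The returned table is
    indexed by gene with boolean columns ``facilitator|<comp>`` /
    ``brake|<comp>`` and aggregate columns ``essential_facilitator`` /
    ``essential_brake`` requiring >= ``min_support`` supporting comparisons.
    """
    missing = set(summaries) - set(nt_nulls)
    if missing:
        raise CallingError(f"missing NT null for comparison(s): {sorted(missing)}")
    genes = sorted(set().union(*(set(s.index) for s in summaries.values())))
    out = pd.DataFrame(index=pd.Index(genes, name="target_id"))
    for comp, summary in summaries.items():
        sd = nt_nulls[comp].sd
        fac = (
            (summary["neg_lfc"] < -sd_mult * sd)
            & (summary["neg_goodsgrna"] >= min_goodsgrna)
            & (summary["neg_p"] < p_cut)
        )
        brk = (
            (summary["pos_lfc"] > sd_mult * sd)
            & (summary["pos_goodsgrna"] >= min_goodsgrna)
            & (summary["pos_p"] < p_cut)
        )
        out[f"facilitator|{comp}"] = fac.reindex(out.index, fill_value=False)
        out[f"brake|{comp}"] = brk.reindex(out.index, fill_value=False)
    fac_cols = [c for c in out.columns if c.startswith("facilitator|")]
    brk_cols = [c for c in out.columns if c.startswith("brake|")]
    out["n_facilitator_support"] = out[fac_cols].sum(axis=1)
    out["n_brake_support"] = out[brk_cols].sum(axis=1)
    out["essential_facilitator"] = out["n_facilitator_support"] >= min_support
    out["essential_brake"] = out["n_brake_support"] >= min_support
    return out
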