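import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cnscreen.counts_io import CountMatrix
from cnscreen.errors import NormalizationError, NullConstructionError
from cnscreen.library import NT_TARGET_ID
from cnscreen.screen_stats import (
    build_nt_null,
    filter_low_counts,
    gene_summary,
    normalize_counts,
    read_gene_summary,
    rra_aggregate,
    sgrna_test,
    size_factors,
    write_gene_summary,
)


def _cm(counts: pd.DataFrame, targets=None, meta=None) -> CountMatrix:
    if targets is None:
        targets = pd.Series("geneX", index=counts.index)
    return CountMatrix(counts=counts, targets=targets, meta=meta)


def _meta(samples, tissues, reps):
    return pd.DataFrame(
        {"sample_id": samples, "tissue": tissues, "replicate": reps}
    ).set_index("sample_id")


class TestFilterLowCounts:
    @pytest.mark.parametrize(
        "blood_counts,expect_dropped",
        [
            ((49, 49, 49), True),   # three low replicates: > 2
            ((49, 49, 60), False),  # only two low
            ((50, 0, 0), False),    # 50 is not < 50; two low
        ],
    )
    def test_boundary_rules(self, blood_counts, expect_dropped):
        samples = ["blood_r1", "blood_r2", "blood_r3"]
        counts = pd.DataFrame(
            [list(blood_counts), [500, 500, 500]],
            index=pd.Index(["sg1", "sg2"], name="sgRNA"),
            columns=samples, dtype=np.int64,
        )
        cm = _cm(counts, meta=_meta(samples, ["blood"] * 3, [1, 2, 3]))
        kept, dropped = filter_low_counts(cm)
        assert ("sg1" in dropped) is expect_dropped
        assert "sg2" not in dropped

    def test_removal_is_global_across_tissues(self):
        samples = ["blood_r1", "blood_r2", "blood_r3", "spleen_r1"]
        counts = pd.DataFrame(
            [[0, 0, 0, 10_000], [100, 100, 100, 100]],
            index=pd.Index(["sg1", "sg2"], name="sgRNA"),
            columns=samples, dtype=np.int64,
        )
        cm = _cm(counts, meta=_meta(samples, ["blood"] * 3 + ["spleen"], [1, 2, 3, 1]))
        kept, dropped = filter_low_counts(cm)
        assert dropped == ["sg1"]
        assert "spleen_r1" in kept.counts.columns
        assert "sg1" not in kept.counts.index


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        counts = pd.DataFrame(
            {"a": [100, 200, 300], "b": [100, 200, 300]},
            index=pd.Index(["sg1", "sg2", "sg3"], name="sgRNA"), dtype=np.int64,
        )
        f = size_factors(_cm(counts))
        assert np.allclose(f, 1.0)

    def test_doubled_column_has_factor_two(self):
        base = np.array([100, 150, 200, 400])
        counts = pd.DataFrame(
            {"a": base, "b": 2 * base},
            index=pd.Index([f"sg{i}" for i in range(4)], name="sgRNA"), dtype=np.int64,
        )
        f = size_factors(_cm(counts))
        assert f["b"] / f["a"] == pytest.approx(2.0, rel=1e-12)

    def test_matches_brute_force_median_of_ratios(self, rng):
        counts = pd.DataFrame(
            rng.integers(50, 5000, size=(200, 6)),
            index=pd.Index([f"sg{i}" for i in range(200)], name="sgRNA"),
            columns=[f"s{j}" for j in range(6)], dtype=np.int64,
        )
        f = size_factors(_cm(counts), min_count=50)
        # Brute-force oracle: direct enumeration with scalar arithmetic.
        mat = counts.to_numpy(dtype=float)
        ref_rows = [i for i in range(200) if all(mat[i] >= 50)]
        for j, col in enumerate(counts.columns):
            ratios = []
            for i in ref_rows:
                g = np.exp(np.mean([np.log(x) for x in mat[i]]))
                ratios.append(mat[i, j] / g)
            assert f[col] == pytest.approx(np.median(ratios), abs=1e-12)

    def test_scale_equivariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(60, 3000, size=(80, 4)),
            index=pd.Index([f"sg{i}" for i in range(80)], name="sgRNA"),
            columns=list("abcd"), dtype=np.int64,
        )
        f0 = size_factors(_cm(counts))
        scaled = counts.copy()
        scaled["c"] = scaled["c"] * 3
        f1 = size_factors(_cm(scaled))
        # Size factors are defined up to one overall scale convention, so the
        # equivariance is exact at the ratio level: the scaled sample's factor
        # gains the factor 3 relative to every other sample, and normalized
        # counts change only by one common constant.
        for other in "abd":
            assert f1["c"] / f1[other] == pytest.approx(3 * f0["c"] / f0[other], rel=1e-10)
        n0 = normalize_counts(_cm(counts), f0)
        n1 = normalize_counts(_cm(scaled), f1)
        ratio = (n1 / n0).to_numpy()
        assert np.allclose(ratio, ratio[0, 0], rtol=1e-10)

    def test_empty_reference_set_raises(self):
        counts = pd.DataFrame(
            {"a": [10, 20], "b": [30, 5]},
            index=pd.Index(["sg1", "sg2"], name="sgRNA"), dtype=np.int64,
        )
        with pytest.raises(NormalizationError, match="min_count"):
            size_factors(_cm(counts), min_count=50)


class TestSgrnaTest:
    def test_self_comparison_is_null(self, null_screen):
        _, cm, _ = null_screen
        norm = normalize_counts(cm, size_factors(cm))
        samples = cm.samples_for("blood")
        stats = sgrna_test(norm, cm.targets, samples, samples, nt_ids=cm.nt_ids())
        assert np.allclose(stats["lfc"], 0.0)
        assert (stats["p_low"] >= 0.45).all()
        assert (stats["p_high"] >= 0.45).all()

    def test_planted_depletion_detected(self, rng):
        # 100 depleted sgRNAs at 8-fold, high counts, NB noise.
        n_null, n_dep = 900, 100
        mean = 800.0
        disp = 0.01

        def nb(mu, size):
            return rng.poisson(rng.gamma(1 / disp, disp * mu, size=size))

        rows_a = nb(mean, (n_null + n_dep, 3))
        rows_b = np.vstack([
            nb(mean, (n_null, 3)),
            nb(mean / 8, (n_dep, 3)),
        ])
        idx = pd.Index([f"sg{i}" for i in range(n_null + n_dep)], name="sgRNA")
        norm = pd.DataFrame(
            np.hstack([rows_a, rows_b]).astype(float), index=idx,
            columns=["a1", "a2", "a3", "b1", "b2", "b3"],
        )
        targets = pd.Series(NT_TARGET_ID, index=idx)
        stats = sgrna_test(
            norm, targets, ["a1", "a2", "a3"], ["b1", "b2", "b3"],
            nt_ids=list(idx[:n_null]),
        )
        dep = stats.iloc[n_null:]
        assert (dep["p_low"] < 0.01).mean() >= 0.95
        assert dep["lfc"].mean() == pytest.approx(-3.0, abs=0.3)

    def test_null_nt_pvalues_uniform(self, null_screen):
        _, cm, _ = null_screen
        cmf, _ = filter_low_counts(cm)
        norm = normalize_counts(cmf, size_factors(cmf))
        nt = cmf.nt_ids()
        stats = sgrna_test(
            norm, cmf.targets, cmf.samples_for("blood"),
            cmf.samples_for("spleen"), nt_ids=nt,
        )
        ks = sps.kstest(stats.loc[stats.index.isin(nt), "p_low"], "uniform").statistic
        assert ks < 0.08

    def test_all_zero_reference_flagged_p_one(self):
        idx = pd.Index([f"sg{i}" for i in range(40)], name="sgRNA")
        norm = pd.DataFrame(
            np.full((40, 4), 100.0), index=idx, columns=["a1", "a2", "b1", "b2"]
        )
        norm.iloc[0, :2] = 0.0
        stats = sgrna_test(norm, pd.Series("g", index=idx), ["a1", "a2"], ["b1", "b2"])
        assert stats["flag_zero"].iloc[0]
        assert stats["p_low"].iloc[0] == 1.0 and stats["p_high"].iloc[0] == 1.0


def _rra_rho_oracle(percentiles, alpha=0.25):
    """Exhaustive binomial-tail score for one gene (scalar arithmetic)."""
    import math

    r = sorted(percentiles)
    n = len(r)
    best = 1.0
    any_informative = False
    for k, rk in enumerate(r, start=1):
        if rk <= alpha:
            any_informative = True
            # P[Binomial(n, rk) >= k] by direct summation
            tail = sum(
                math.comb(n, j) * rk**j * (1 - rk) ** (n - j)
                for j in range(k, n + 1)
            )
            best = min(best, tail)
    return best if any_informative else 1.0


def _stats_frame(percentiles_by_gene, pool_extra=()):
    """Build a minimal SgrnaStats frame whose rank_low values are exact."""
    rows = []
    for g, rs in percentiles_by_gene.items():
        for i, r in enumerate(rs):
            rows.append((f"{g}_sg{i}", g, r))
    for i, r in enumerate(pool_extra):
        rows.append((f"nt_sg{i}", NT_TARGET_ID, r))
    df = pd.DataFrame(rows, columns=["sgrna_id", "target_id", "rank_low"])
    df["rank_high"] = 1.0 - df["rank_low"] + 1e-9
    df["lfc"] = -df["rank_low"]
    df["p_low"] = df["rank_low"]
    df["p_high"] = df["rank_high"]
    return df.set_index("sgrna_id")


class TestRraAggregate:
    def test_rho_matches_closed_form_example(self):
        stats = _stats_frame({"geneA": [0.01, 0.02, 0.03, 0.04]})
        out = rra_aggregate(stats, "neg", alpha=0.25, n_perm=100, seed=0)
        rho = out.loc["geneA", "score"]
        oracle = _rra_rho_oracle([0.01, 0.02, 0.03, 0.04])
        assert rho == pytest.approx(oracle, abs=1e-10)
        # beta_4 term alone is 0.04^4
        assert rho <= 0.04**4 + 1e-12 or rho == pytest.approx(oracle)
        assert out.loc["geneA", "goodsgrna"] == 4

    def test_rho_matches_oracle_random_genes(self, rng):
        genes = {
            f"g{i}": list(rng.random(int(rng.integers(1, 6))))
            for i in range(30)
        }
        stats = _stats_frame(genes)
        out = rra_aggregate(stats, "neg", alpha=0.25, n_perm=10, seed=0)
        for g, rs in genes.items():
            assert out.loc[g, "score"] == pytest.approx(
                _rra_rho_oracle(rs), abs=1e-10
            ), g

    def test_all_above_alpha_gives_rho_one(self):
        stats = _stats_frame({"geneA": [0.3, 0.5, 0.7, 0.9]})
        out = rra_aggregate(stats, "neg", alpha=0.25, n_perm=50, seed=0)
        assert out.loc["geneA", "score"] == 1.0
        assert out.loc["geneA", "goodsgrna"] == 0

    def test_score_monotone_in_percentiles(self):
        base = [0.05, 0.10, 0.20, 0.40]
        improved = [0.01, 0.10, 0.20, 0.40]
        s_base = rra_aggregate(_stats_frame({"g": base}), "neg", n_perm=10, seed=0)
        s_impr = rra_aggregate(_stats_frame({"g": improved}), "neg", n_perm=10, seed=0)
        assert s_impr.loc["g", "score"] <= s_base.loc["g", "score"]

    def test_null_gene_pvalues_uniform(self, rng):
        # 2,000 genes x 4 iid uniform percentiles: permutation self-consistency.
        genes = {f"g{i}": list(rng.random(4)) for i in range(2000)}
        stats = _stats_frame(genes)
        out = rra_aggregate(stats, "neg", alpha=0.25, n_perm=1000, seed=1)
        ks = sps.kstest(out["p"], "uniform").statistic
        assert ks < 0.05

    def test_pvalue_floor_and_goodsgrna_bound(self, rng):
        genes = {f"g{i}": list(rng.random(4) * 0.01) for i in range(20)}
        stats = _stats_frame(genes, pool_extra=rng.random(200))
        out = rra_aggregate(stats, "neg", alpha=0.25, n_perm=200, seed=2)
        assert (out["p"] >= 1 / 201).all()
        assert (out["goodsgrna"] <= out["n_sgrna"]).all()
        assert (out["score"] > 0).all() and (out["score"] <= 1).all()

    def test_summary_round_trip(self, tmp_path, rng):
        genes = {f"g{i}": list(rng.random(4)) for i in range(5)}
        stats = _stats_frame(genes)
        gs = gene_summary(stats, n_perm=50, seed=0)
        path = tmp_path / "gs.tsv"
        write_gene_summary(gs, path)
        header = path.read_text().splitlines()[0].split("\t")
        assert "neg|lfc" in header and "pos|goodsgrna" in header
        back = read_gene_summary(path)
        pd.testing.assert_frame_equal(back, gs[back.columns], check_dtype=False)


class TestNtNull:
    def test_all_zero_lfcs(self):
        null = build_nt_null(np.zeros(100), seed=0)
        assert np.allclose(null.pseudo_lfcs, 0.0)
        assert null.sd == 0.0

    def test_default_emits_800_pseudo_genes_of_4(self):
        null = build_nt_null(np.random.default_rng(0).normal(size=300), seed=1)
        assert null.n_pseudo == 800
        assert null.k == 4
        assert len(null.pseudo_lfcs) == 800

    def test_sd_shrinks_by_sqrt_k(self):
        # CLT oracle: averaging k=4 iid draws halves the SD.
        rng = np.random.default_rng(5)
        sigma = 0.8
        ratios = []
        for seed in range(50):
            lfcs = rng.normal(0, sigma, size=800)
            null = build_nt_null(lfcs, seed=seed)
            ratios.append(null.sd / lfcs.std(ddof=1))
        ratios = np.array(ratios)
        assert ((ratios >= 0.45) & (ratios <= 0.55)).all()

    def test_deterministic_and_requires_k_values(self):
        lfcs = np.random.default_rng(2).normal(size=50)
        a = build_nt_null(lfcs, seed=9)
        b = build_nt_null(lfcs, seed=9)
        assert np.array_equal(a.pseudo_lfcs, b.pseudo_lfcs)
        with pytest.raises(NullConstructionError):
            build_nt_null([0.1, 0.2, 0.3], k=4)
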