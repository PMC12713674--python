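"""Filtering and CMH differentiation testing."""

import numpy as np
import pandas as pd
import pytest

from poolage import sim
from poolage.variants import (
    PoolCounts,
    bonferroni_threshold,
    cmh_from_tables,
    cmh_test,
    extract_candidates,
    filter_variants,
    differentiation_test,
)

from conftest import make_null_pool


def _pool_from_arrays(ad, dp, n_pairs):
    n_var = ad.shape[0]
    samples = []
    for p in range(n_pairs):
        samples.append({"sample": f"R{p+1:02d}_young", "pair": p + 1, "cohort": "young"})
        samples.append({"sample": f"R{p+1:02d}_aged", "pair": p + 1, "cohort": "aged"})
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_var + 1) * 10,
            "ref": "A",
            "alt": "G",
            "variant_class": "SNP",
        }
    )
    return PoolCounts(variants, ad, dp, pd.DataFrame(samples))


class TestFilterVariants:
    def make_pool(self, dp_rows, maf_rows=None):
        dp = np.asarray(dp_rows)
        if maf_rows is None:
            ad = (dp * 0.5).astype(np.int64)
        else:
            ad = np.asarray(maf_rows)
        return _pool_from_arrays(ad.astype(np.int64), dp.astype(np.int64), dp.shape[1] // 2)

    def test_coverage_bounds_inclusive(self):
        base = np.full((3, 4), 100)
        base[0, 2] = 19  # one sample below the floor
        base[1, 1] = 1001  # one sample above the ceiling
        pool = self.make_pool(base)
        out = filter_variants(pool, 20, 1000, 0.0)
        assert list(out.variants["pos"]) == [30]

    def test_maf_boundary_inclusive(self):
        dp = np.full((2, 4), 100)
        ad = np.zeros((2, 4), dtype=int)
        ad[0] = [5, 5, 5, 5]  # pooled MAF exactly 0.05
        ad[1] = [5, 5, 5, 4]  # pooled MAF 0.0475
        pool = self.make_pool(dp, ad)
        out = filter_variants(pool, 20, 1000, 0.05)
        assert list(out.variants["pos"]) == [10]

    def test_identity_and_idempotence(self):
        pool = make_null_pool(50, 4, coverage=100, seed=1)
        once = filter_variants(pool)
        twice = filter_variants(once)
        assert once.variants.equals(twice.variants)
        assert np.array_equal(once.ad, twice.ad)

    def test_empty_result_warns(self):
        pool = self.make_pool(np.full((2, 4), 5))
        with pytest.warns(UserWarning):
            out = filter_variants(pool, 20, 1000, 0.05)
        assert out.n_variants == 0


class TestCMH:
    def test_hand_computed_single_stratum(self):
        # young 10/100 alt vs aged 30/100 alt: E=20, V~8.0402
        stat, p = cmh_from_tables(np.array([[[10, 90], [30, 70]]]))
        assert stat == pytest.approx(12.437, abs=1e-3)
        assert p == pytest.approx(4.2e-4, rel=0.02)

    def test_additivity_over_identical_strata(self):
        t = np.repeat(np.array([[[10, 90], [30, 70]]]), 12, axis=0)
        stat, _ = cmh_from_tables(t)
        assert stat == pytest.approx(120**2 / (12 * (100 * 100 * 40 * 160) / (200**2 * 199)), rel=1e-9)
        assert stat == pytest.approx(149.25, abs=0.01)

    def test_identical_proportions_give_null(self):
        t = np.repeat(np.array([[[20, 80], [20, 80]]]), 12, axis=0)
        stat, p = cmh_from_tables(t)
        assert stat == 0.0 and p == 1.0

    def test_monomorphic_strata_contribute_nothing(self):
        informative = np.array([[[10, 90], [30, 70]]])
        padded = np.concatenate([informative, np.array([[[0, 50], [0, 50]]])])
        assert cmh_from_tables(padded) == cmh_from_tables(informative)

    def test_all_degenerate_gives_p_one(self):
        stat, p = cmh_from_tables(np.array([[[0, 50], [0, 50]]]))
        assert stat == 0.0 and p == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_single_stratum_equals_score_chi2(self, seed):
        """Single-stratum CMH is the classical 2x2 score chi-square."""
        rng = np.random.default_rng(seed)
        t = rng.integers(1, 80, size=(1, 2, 2)).astype(float)
        stat, _ = cmh_from_tables(t)
        # brute-force score chi-square: sum (O-E)^2/E times (T-1)/T
        T = t[0].sum()
        row = t[0].sum(axis=1)
        col = t[0].sum(axis=0)
        E = np.outer(row, col) / T
        pearson = ((t[0] - E) ** 2 / E).sum()
        assert stat == pytest.approx(pearson * (T - 1) / T, rel=1e-10)

    def test_vectorized_matches_scalar(self):
        rng = np.random.default_rng(9)
        K, n_var = 12, 40
        dy = rng.integers(40, 120, size=(n_var, K))
        da = rng.integers(40, 120, size=(n_var, K))
        ay = rng.binomial(dy, 0.3)
        aa = rng.binomial(da, 0.35)
        res = cmh_test(ay, dy, aa, da)
        for i in range(0, n_var, 7):
            tabs = np.stack(
                [
                    np.array([[ay[i, k], dy[i, k] - ay[i, k]], [aa[i, k], da[i, k] - aa[i, k]]])
                    for k in range(K)
                ]
            )
            stat, p = cmh_from_tables(tabs)
            assert res["statistic"][i] == pytest.approx(stat, rel=1e-12)

    def test_statsmodels_cross_check(self):
        """Independent route: statsmodels' stratified-table CMH statistic."""
        from statsmodels.stats.contingency_tables import StratifiedTable

        rng = np.random.default_rng(4)
        tabs = rng.integers(5, 60, size=(12, 2, 2)).astype(float)
        stat, _ = cmh_from_tables(tabs)
        st = StratifiedTable(np.transpose(tabs, (1, 2, 0)))
        ref = st.test_null_odds(correction=False)
        assert stat == pytest.approx(ref.statistic, rel=1e-8)


class TestBonferroni:
    def test_trivial_single_test(self):
        cutoff, nlp = bonferroni_threshold(1, 0.05)
        assert cutoff == 0.05

    def test_published_snp_count(self):
        cutoff, nlp = bonferroni_threshold(67_049, 0.05)
        assert cutoff == pytest.approx(7.458e-7, rel=1e-3)
        assert nlp == pytest.approx(6.127, abs=1e-3)

    def test_published_indel_count(self):
        cutoff, _ = bonferroni_threshold(5_129, 0.05)
        assert cutoff == pytest.approx(9.749e-6, rel=1e-3)

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestTypeIErrorAndPower:
    def test_null_rejection_rate_near_nominal(self):
        pool = make_null_pool(2000, 12, coverage=100, seed=1)
        res = differentiation_test(pool, alpha=0.05)
        frac = (res["p_value"] < 0.05).mean()
        half_band = 2.576 * np.sqrt(0.05 * 0.95 / 2000)
        assert abs(frac - 0.05) < half_band

    def test_power_monotone_in_s_and_coverage(self):
        """Rejection at a causal site grows with s and with depth."""

        def reject_rate(s, cov, n_rep=300, seed=10):
            rng = np.random.default_rng(seed)
            f = np.full((n_rep, 1), 0.5)
            f_aged = f * (1 + s) / (1 + s * f)
            ps = []
            ay = np.zeros((n_rep, 12), dtype=int)
            dy = np.zeros_like(ay)
            aa = np.zeros_like(ay)
            da = np.zeros_like(ay)
            for p in range(12):
                a1, d1 = sim.simulate_pool_reads(f[:, 0], cov, seed=int(rng.integers(2**31 - 1)))
                a2, d2 = sim.simulate_pool_reads(f_aged[:, 0], cov, seed=int(rng.integers(2**31 - 1)))
                ay[:, p], dy[:, p], aa[:, p], da[:, p] = a1, d1, a2, d2
            res = cmh_test(ay, dy, aa, da)
            return (res["p_value"] < 7.5e-7).mean()

        rates_s = [reject_rate(s, 100) for s in (0.1, 0.3, 0.5)]
        assert rates_s == sorted(rates_s)
        assert reject_rate(0.3, 200) >= reject_rate(0.3, 50)


class TestExtractCandidates:
    @pytest.fixture
    def results(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1"] * 3,
                "pos": [100, 5_000, 90_000],
                "variant_class": ["SNP"] * 3,
                "p_value": [1e-9, 1e-9, 0.5],
                "significant": [True, True, False],
            }
        )
        return df

    @pytest.fixture
    def genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["gA"],
                "chrom": ["chr1"],
                "start": [100],
                "end": [1_000],
                "strand": ["+"],
                "coding": [True],
            }
        )

    def test_gene_boundary_inclusive(self, results, genes):
        candidates, sig, hit = extract_candidates(results, genes)
        assert list(candidates["pos"]) == [100]
        assert hit == ["gA"]

    def test_intergenic_significant_excluded_from_candidates(self, results, genes):
        candidates, sig, _ = extract_candidates(results, genes)
        assert 5_000 in set(sig["pos"])
        assert 5_000 not in set(candidates["pos"])

    def test_no_significant_variants(self, genes):
        df = pd.DataFrame(
            {"chrom": ["chr1"], "pos": [10], "significant": [False], "p_value": [0.9]}
        )
        candidates, sig, hit = extract_candidates(df, genes)
        assert len(candidates) == 0 and len(sig) == 0 and hit == []


class TestPerClassThresholds:
    def test_separate_cutoffs_for_snps_and_indels(self):
        pool = make_null_pool(100, 4, coverage=100, seed=2)
        vc = np.array(["SNP"] * 80 + ["indel"] * 20)
        pool.variants["variant_class"] = vc
        res = differentiation_test(pool, alpha=0.05)
        snp_cut = res.loc[res["variant_class"] == "SNP", "p_cutoff"].unique()
        ind_cut = res.loc[res["variant_class"] == "indel", "p_cutoff"].unique()
        assert snp_cut == pytest.approx(0.05 / 80)
        assert ind_cut == pytest.approx(0.05 / 20)
        joint = differentiation_test(pool, alpha=0.05, joint_threshold=True)
        assert joint["p_cutoff"].unique() == pytest.approx(0.05 / 100)
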