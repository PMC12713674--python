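"""Window construction, simplex-constrained estimation, D statistic, peaks."""

import itertools

import numpy as np
import pandas as pd
import pytest

from poolage import sim
from poolage.haplotypes import (
    d_statistic,
    estimate_haplotype_freqs,
    estimate_windows,
    flag_divergent_windows,
    window_d_table,
    window_snps,
)


def simplex_grid_argmin(y, A, step=0.02):
    """Independent oracle: dense grid search over the founder simplex.

    Enumerates all compositions of 1 at the given resolution, evaluates
    ||A f - y||, and refines locally at 1/4 of the step.
    """

    def best_on(points):
        pts = np.asarray(points)
        resid = np.linalg.norm(pts @ A.T - y, axis=1)
        return pts[np.argmin(resid)], resid.min()

    k = A.shape[1]
    m = int(round(1 / step))
    coarse = [
        np.array(c) / m
        for c in itertools.product(range(m + 1), repeat=k - 1)
        if sum(c) <= m
    ]
    coarse = [np.append(c, 1 - c.sum()) for c in coarse]
    f0, _ = best_on(coarse)
    fine_step = step / 4
    offsets = itertools.product(np.arange(-4, 5) * fine_step, repeat=k - 1)
    fine = []
    for off in offsets:
        f = f0[:-1] + np.array(off)
        if (f >= -1e-12).all() and f.sum() <= 1 + 1e-12:
            fine.append(np.append(np.clip(f, 0, 1), max(1 - f.sum(), 0)))
    f1, _ = best_on(fine)
    return f1


class TestWindowSnps:
    def test_starts_follow_step_from_first_snp(self):
        pos = np.arange(1, 10_001)
        w = window_snps(np.repeat("c", pos.size), pos)
        assert list(w["start"][:3]) == [1, 2001, 4001]

    def test_membership_half_open(self):
        pos = np.array([1, 5000, 5001])
        w = window_snps(np.repeat("c", 3), pos, 5000, 2000, min_snps=1)
        first = w.iloc[0]
        members = pos[np.asarray(first["snp_indices"])]
        assert 5000 in members and 5001 not in members

    def test_sparse_window_flagged_unestimable(self):
        pos = np.array([10, 20])
        w = window_snps(np.repeat("c", 2), pos, 5000, 2000, min_snps=3)
        assert not w.iloc[0]["estimable"]

    def test_empty_chromosome_no_windows(self):
        w = window_snps(np.array([]), np.array([]))
        assert len(w) == 0


class TestEstimateHaplotypeFreqs:
    def test_pure_founder_recovered_exactly(self):
        rng = np.random.default_rng(0)
        G = rng.integers(0, 2, size=(4, 30)).astype(float)
        G[1] = 1 - G[0]  # make founders distinct enough
        y = G[1].copy()
        f, resid, degen = estimate_haplotype_freqs(y, G)
        assert not degen
        assert np.argmax(f) == 1
        assert resid == pytest.approx(0.0, abs=1e-6)
        assert f[1] == pytest.approx(1.0, abs=1e-6)

    def test_identical_founders_pooled_with_flag(self):
        rng = np.random.default_rng(1)
        G = rng.integers(0, 2, size=(4, 25)).astype(float)
        G[1] = G[0]  # founders 1 and 2 indistinguishable
        truth = np.array([0.2, 0.3, 0.4, 0.1])
        y = truth @ G
        f, resid, degen = estimate_haplotype_freqs(y, G)
        assert degen
        assert f[0] == pytest.approx(f[1])  # pooled group split equally
        assert f[0] + f[1] == pytest.approx(0.5, abs=1e-5)
        assert f.sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_founders_identical_unestimable(self):
        G = np.ones((4, 10))
        f, resid, degen = estimate_haplotype_freqs(np.ones(10), G)
        assert f is None and degen

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noise_free_recovery_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.integers(0, 2, size=(4, 40)).astype(float)
        while len({r.tobytes() for r in G.astype(np.int8)}) < 4:
            G = rng.integers(0, 2, size=(4, 40)).astype(float)
        truth = rng.dirichlet(np.ones(4))
        y = truth @ G
        f, resid, _ = estimate_haplotype_freqs(y, G)
        assert np.abs(f - truth).max() < 1e-6
        oracle = simplex_grid_argmin(y, G.T)
        assert np.abs(f - oracle).max() < 0.01  # grid resolution

    def test_noisy_solution_beats_or_matches_grid_oracle(self):
        rng = np.random.default_rng(5)
        G = rng.integers(0, 2, size=(4, 40)).astype(float)
        y = np.clip(rng.dirichlet(np.ones(4)) @ G + rng.normal(0, 0.05, 40), 0, 1)
        f, resid, _ = estimate_haplotype_freqs(y, G)
        oracle = simplex_grid_argmin(y, G.T)
        assert resid <= np.linalg.norm(G.T @ oracle - y) + 1e-9

    def test_simplex_constraints_always_hold(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            G = rng.integers(0, 2, size=(4, 15)).astype(float)
            y = rng.uniform(size=15)
            f, _, _ = estimate_haplotype_freqs(y, G)
            if f is not None:
                assert (f >= -1e-12).all()
                assert f.sum() == pytest.approx(1.0, abs=1e-6)


class TestDStatistic:
    def test_identical_cohorts_zero(self):
        x = np.tile(np.array([0.25, 0.25, 0.25, 0.25]), (12, 1))
        d_h, d_mean = d_statistic(x, x)
        assert (d_h == 0).all() and d_mean == 0

    def test_single_replicate_difference(self):
        young = np.array([[0.2, 0.8, 0.0, 0.0]])
        aged = np.array([[0.5, 0.5, 0.0, 0.0]])
        d_h, _ = d_statistic(young, aged)
        assert d_h[0] == pytest.approx(0.3)

    def test_mean_over_replicates(self):
        young = np.array([[0.2, 0.8], [0.2, 0.8]])
        aged = np.array([[0.3, 0.7], [0.5, 0.5]])
        d_h, d_mean = d_statistic(young, aged)
        assert d_h[0] == pytest.approx(0.2)  # (0.1 + 0.3)/2
        assert d_mean == pytest.approx(0.2)

    def test_missing_pair_skipped_with_warning(self):
        young = np.array([[0.2, 0.8], [np.nan, np.nan]])
        aged = np.array([[0.4, 0.6], [0.5, 0.5]])
        with pytest.warns(UserWarning, match="missing"):
            d_h, _ = d_statistic(young, aged)
        assert d_h[0] == pytest.approx(0.2)


class TestFlagDivergentWindows:
    def make_table(self, d_values):
        n = len(d_values)
        return pd.DataFrame(
            {
                "chrom": "c",
                "start": 1 + 2000 * np.arange(n),
                "end": 5000 + 2000 * np.arange(n),
                "n_snps": 50,
                "estimable": True,
                "mean_D": d_values,
            }
        )

    def test_constant_divergence_no_flags(self):
        out, peaks, _ = flag_divergent_windows(self.make_table([0.01] * 40))
        assert not out["flagged"].any() and len(peaks) == 0

    def test_injected_window_is_the_only_peak(self):
        rng = np.random.default_rng(3)
        d = list(rng.normal(0.01, 0.001, 60))
        d[25] = 0.5
        out, peaks, _ = flag_divergent_windows(self.make_table(d), quantile=0.999)
        assert len(peaks) == 1
        assert peaks.iloc[0]["start"] == 1 + 2000 * 25

    def test_adjacent_flagged_windows_merge(self):
        rng = np.random.default_rng(4)
        d = list(rng.normal(0.01, 0.001, 60))
        d[30], d[31] = 0.5, 0.45
        out, peaks, _ = flag_divergent_windows(self.make_table(d), quantile=0.95)
        # the two adjacent super-threshold windows report as one merged peak
        top = peaks.iloc[0]
        assert top["n_windows"] == 2
        assert top["start"] == 1 + 2000 * 30
        assert top["end"] == 5000 + 2000 * 31

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            flag_divergent_windows(self.make_table([0.01] * 5))


class TestRecoveryFromSimulatedPools:
    def test_noise_free_window_estimates_match_truth(self, small_panel):
        windows = window_snps(small_panel.chrom, small_panel.pos, min_snps=3)
        H = sim.simulate_individuals(small_panel, 400, 3.0, seed=21)
        truth = sim.window_founder_freqs(small_panel, H, windows)
        freqs = sim.pool_freqs_from_individuals(small_panel, H)[:, None]
        est = estimate_windows(small_panel.G, windows, freqs)
        ok = np.isfinite(est[:, 0]).all(axis=1) & np.isfinite(truth).all(axis=1)
        assert ok.sum() >= 10
        assert np.abs(est[ok, 0] - truth[ok]).mean() < 0.02

    def test_mean_d_decreases_with_coverage_under_no_selection(self, small_panel):
        windows = window_snps(small_panel.chrom, small_panel.pos, min_snps=3)
        samples = pd.DataFrame(
            [
                {"sample": f"R{p:02d}_{c}", "pair": p, "cohort": c}
                for p in range(1, 5)
                for c in ("young", "aged")
            ]
        )
        means = {}
        rng = np.random.default_rng(6)
        for cov in (30, 300):
            freqs = np.zeros((small_panel.n_sites, 8))
            for p in range(4):
                H = sim.simulate_individuals(small_panel, 400, 3.0, seed=50 + p)
                f = sim.pool_freqs_from_individuals(small_panel, H)
                for k in range(2):
                    ad, dp = sim.simulate_pool_reads(
                        f, cov, seed=int(rng.integers(2**31 - 1))
                    )
                    freqs[:, 2 * p + k] = np.where(dp > 0, ad / np.maximum(dp, 1), 0)
            est = estimate_windows(small_panel.G, windows, freqs)
            dt = window_d_table(windows, est, samples, small_panel.founder_ids)
            means[cov] = np.nanmean(dt["mean_D"])
        assert means[300] < means[30]
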