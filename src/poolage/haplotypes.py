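"""Founder-haplotype frequency estimation in sliding windows, and the D statistic.

Given pooled alternate-allele frequencies y at the SNPs of a genomic
window and the founder genotype matrix G over those SNPs, the local
founder composition f of the pool is estimated by simplex-constrained
least squares

    f = argmin || G' f - y ||^2   s.t.  f >= 0, sum f = 1 ,

one window (5 kb, stepping 2 kb) at a time.  The divergence statistic D
for founder h is the mean absolute young-vs-aged difference in its
estimated frequency, averaged over replicate pairs; a window's mean D
averages over founders.  Windows with unusually high mean D are flagged
against an empirical genome-wide quantile and merged into peaks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "window_snps",
    "estimate_haplotype_freqs",
    "estimate_windows",
    "d_statistic",
    "window_d_table",
    "flag_divergent_windows",
]


def window_snps(
    chrom: np.ndarray,
    pos: np.ndarray,
    window_size: int = 5000,
    step: int = 2000,
    min_snps: int = 3,
) -> pd.DataFrame:
    """Tile each chromosome with sliding windows anchored at its first SNP.

    Window membership is half-open: a SNP belongs to a window starting at
    s iff s <= pos < s + window_size.  Returns a frame with chrom, start,
    end (inclusive, = start + window_size - 1), member SNP indices into
    the input arrays, n_snps, and an ``estimable`` flag (n_snps >=
    min_snps).
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    chrom = np.asarray(chrom)
    pos = np.asarray(pos)
    rows = []
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        if idx.size == 0:
            continue
        p = pos[idx]
        if not (np.diff(p) > 0).all():
            raise ValueError(f"positions not sorted on {c}")
        start = int(p[0])
        last = int(p[-1])
        while start <= last:
            lo = np.searchsorted(p, start, side="left")
            hi = np.searchsorted(p, start + window_size, side="left")
            members = idx[lo:hi]
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": start + window_size - 1,
                    "snp_indices": members,
                    "n_snps": members.size,
                    "estimable": members.size >= min_snps,
                }
            )
            start += step
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "snp_indices", "n_snps", "estimable"]
    )


def _founder_groups(G_win: np.ndarray) -> list[list[int]]:
    """Group founders indistinguishable (identical genotypes) over the window."""
    groups: dict[bytes, list[int]] = {}
    for i, row in enumerate(np.asarray(G_win, dtype=np.int8)):
        groups.setdefault(row.tobytes(), []).append(i)
    return list(groups.values())


def estimate_haplotype_freqs(
    y: np.ndarray, G_win: np.ndarray, min_snps: int = 3
) -> tuple[np.ndarray | None, float, bool]:
    """Estimate the founder-frequency simplex for one window and sample.

    Parameters
    ----------
    y : observed pooled alternate-allele frequencies at the window SNPs.
    G_win : (n_founders, n_snps) founder genotype submatrix.

    Returns (f, residual, degenerate).  Founders with identical genotypes
    across the window cannot be separated: the fit is done on one
    representative per group, the group's frequency is split equally
    among its members, and ``degenerate`` is set.  If *all* founders are
    identical over the window (or there are too few SNPs) the window is
    unestimated and f is None.
    """
    y = np.asarray(y, dtype=float)
    G_win = np.asarray(G_win, dtype=float)
    nf, ns = G_win.shape
    if ns != y.size:
        raise ValueError("y length must match the number of window SNPs")
    if ns < min_snps:
        return None, np.nan, False
    if ((y < -1e-9) | (y > 1 + 1e-9)).any():
        raise ValueError("observed frequencies must lie in [0, 1]")
    y = np.clip(y, 0.0, 1.0)
    groups = _founder_groups(G_win)
    degenerate = len(groups) < nf
    if len(groups) < 2:
        return None, np.nan, True  # rank-0 contrast: founders indistinguishable
    A = np.stack([G_win[g[0]] for g in groups], axis=1)  # (n_snps, n_groups)
    k = A.shape[1]

    def obj(f):
        r = A @ f - y
        return 0.5 * r @ r

    def grad(f):
        return A.T @ (A @ f - y)

    x0 = np.full(k, 1.0 / k)
    res = optimize.minimize(
        obj,
        x0,
        jac=grad,
        method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda f: f.sum() - 1.0,
                      "jac": lambda f: np.ones_like(f)}],
        options={"maxiter": 200, "ftol": 1e-14},
    )
    fg = np.clip(res.x, 0.0, None)
    fg /= fg.sum()
    resid = float(np.linalg.norm(A @ fg - y))
    f = np.zeros(nf)
    for g, val in zip(groups, fg):
        for member in g:
            f[member] = val / len(g)
    return f, resid, degenerate


def estimate_windows(
    G: np.ndarray,
    windows: pd.DataFrame,
    freqs: np.ndarray,
    min_snps: int = 3,
) -> np.ndarray:
    """Estimate founder simplexes for every window and sample.

    ``freqs`` is (n_sites, n_samples) pooled alternate-allele frequency;
    ``G`` is the full (n_founders, n_sites) founder panel.  Returns an
    (n_windows, n_samples, n_founders) array with NaN for unestimated
    windows.
    """
    n_samples = freqs.shape[1]
    nf = G.shape[0]
    out = np.full((len(windows), n_samples, nf), np.nan)
    for wi, row in enumerate(windows.itertuples(index=False)):
        if not row.estimable:
            continue
        cols = np.asarray(row.snp_indices)
        G_win = G[:, cols]
        for s in range(n_samples):
            f, _, _ = estimate_haplotype_freqs(freqs[cols, s], G_win, min_snps)
            if f is not None:
                out[wi, s] = f
    return out


def d_statistic(
    young: np.ndarray, aged: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-founder D and the window mean D.

    ``young``/``aged`` are (n_replicates, n_founders) simplexes for one
    window.  D_h = mean_r |f_aged - f_young|; replicate pairs in which
    either cohort is missing (NaN) are skipped with a warning.
    """
    young = np.atleast_2d(np.asarray(young, float))
    aged = np.atleast_2d(np.asarray(aged, float))
    if young.shape != aged.shape:
        raise ValueError("young and aged replicate arrays must have equal shape")
    valid = ~(np.isnan(young).any(axis=1) | np.isnan(aged).any(axis=1))
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} replicate pair(s) missing a cohort estimate; skipped"
        )
    if not valid.any():
        return np.full(young.shape[1], np.nan), np.nan
    diff = np.abs(aged[valid] - young[valid])
    d_h = diff.mean(axis=0)
    return d_h, float(d_h.mean())


def window_d_table(
    windows: pd.DataFrame,
    estimates: np.ndarray,
    samples: pd.DataFrame,
    founder_ids: list[str],
) -> pd.DataFrame:
    """Assemble the per-window D table from cohort-wise simplex estimates.

    ``estimates`` is the (n_windows, n_samples, n_founders) output of
    :func:`estimate_windows`; ``samples`` maps columns to (pair, cohort).
    """
    pairs = sorted(samples["pair"].unique())
    yi, ai = [], []
    for p in pairs:
        sub = samples[samples["pair"] == p]
        yi.append(sub.index[sub["cohort"] == "young"][0])
        ai.append(sub.index[sub["cohort"] == "aged"][0])
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for wi, row in enumerate(windows.itertuples(index=False)):
            young = estimates[wi, yi]
            aged = estimates[wi, ai]
            d_h, d_mean = d_statistic(young, aged)
            rec = {
                "chrom": row.chrom,
                "start": row.start,
                "end": row.end,
                "n_snps": row.n_snps,
                "estimable": row.estimable,
                "mean_D": d_mean,
            }
            for h, fid in enumerate(founder_ids):
                rec[f"D_{fid}"] = d_h[h]
                rec[f"dfreq_{fid}"] = float(
                    np.nanmean(aged[:, h] - young[:, h])
                ) if np.isfinite(d_mean) else np.nan
            rows.append(rec)
    return pd.DataFrame(rows)


def flag_divergent_windows(
    d_table: pd.DataFrame,
    quantile: float = 0.999,
    min_windows: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Flag windows of unusually high divergence and merge them into peaks.

    Mean-D values are standardized genome-wide and compared against a
    theoretical normal quantile table (for inspection) and flagged when
    they reach the configured empirical quantile.  Adjacent or
    overlapping flagged windows on the same chromosome merge into one
    peak.  Returns (flagged d_table copy, peaks, quantile report).
    """
    if not 0 < quantile < 1:
        raise ValueError("quantile must lie in (0, 1)")
    est = d_table[np.isfinite(d_table["mean_D"])]
    if len(est) < min_windows:
        raise ValueError(
            f"need at least {min_windows} estimated windows, got {len(est)}"
        )
    d = est["mean_D"].to_numpy()
    mu, sd = d.mean(), d.std(ddof=1)
    out = d_table.copy()
    out["z_D"] = (out["mean_D"] - mu) / sd if sd > 0 else 0.0
    if sd > 0:
        thr = float(np.quantile(d, quantile))
        out["flagged"] = np.isfinite(out["mean_D"]) & (out["mean_D"] >= thr)
    else:
        out["flagged"] = False  # constant divergence: nothing is unusual

    # theoretical-normal vs empirical quantile report (QQ table)
    from scipy import stats as _st

    qs = np.concatenate([np.linspace(0.01, 0.99, 50), [quantile]])
    report = pd.DataFrame(
        {
            "prob": qs,
            "theoretical": mu + sd * _st.norm.ppf(qs),
            "empirical": np.quantile(d, qs),
        }
    )

    peaks = []
    for c, grp in out[out["flagged"]].groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and row.start <= cur["end"] + 1:
                cur["end"] = max(cur["end"], row.end)
                cur["max_D"] = max(cur["max_D"], row.mean_D)
                cur["n_windows"] += 1
            else:
                if cur is not None:
                    peaks.append(cur)
                cur = {
                    "chrom": c,
                    "start": row.start,
                    "end": row.end,
                    "max_D": row.mean_D,
                    "n_windows": 1,
                }
        if cur is not None:
            peaks.append(cur)
    peaks_df = pd.DataFrame(peaks, columns=["chrom", "start", "end", "max_D", "n_windows"])
    if len(peaks_df):
        peaks_df = peaks_df.sort_values("max_D", ascending=False).reset_index(drop=True)
    return out, peaks_df, report
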