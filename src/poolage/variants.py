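"""Pooled allele-frequency differentiation between young and aged cohorts.

Each variant is tested with a Cochran–Mantel–Haenszel (CMH) test in
which every replicate pair is a stratum holding a 2x2 table of
(alternate, reference) read counts by cohort (young, aged).  The
statistic is the classical Mantel–Haenszel chi-square without continuity
correction,

    X^2 = (sum_k (a_k - E_k))^2 / sum_k V_k ,

with a_k the young-cohort alternate count and E_k, V_k the mean and
variance of the central hypergeometric for stratum k's margins; p-values
come from the chi-square distribution with 1 df.  Genome-wide
significance uses Bonferroni cutoffs computed separately for SNPs and
indels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sim import validate_gene_models

__all__ = [
    "PoolCounts",
    "filter_variants",
    "cmh_from_tables",
    "cmh_test",
    "bonferroni_threshold",
    "differentiation_test",
    "extract_candidates",
]

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "variant_class"]


@dataclass
class PoolCounts:
    """Per-variant, per-sample pooled read counts.

    ``variants`` holds one row per biallelic variant (chrom, pos, ref,
    alt, variant_class, optional annotation).  ``ad``/``dp`` are
    (n_variants, n_samples) alternate and total depths aligned with
    ``samples`` (columns: sample, pair, cohort).
    """

    variants: pd.DataFrame
    ad: np.ndarray
    dp: np.ndarray
    samples: pd.DataFrame

    def validate(self) -> None:
        n_var, n_samp = self.ad.shape
        if self.dp.shape != (n_var, n_samp) or len(self.variants) != n_var:
            raise ValueError("AD/DP/variant table shapes disagree")
        if len(self.samples) != n_samp:
            raise ValueError("sample sheet does not match count columns")
        if (self.ad < 0).any() or (self.ad > self.dp).any():
            raise ValueError("require 0 <= AD <= DP for every record")
        for col in ("sample", "pair", "cohort"):
            if col not in self.samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        counts = self.samples.groupby("pair")["cohort"].apply(
            lambda s: sorted(s) == ["aged", "young"]
        )
        if not counts.all():
            raise ValueError("each pair must have exactly one young and one aged sample")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, mask: np.ndarray) -> "PoolCounts":
        mask = np.asarray(mask)
        return PoolCounts(
            self.variants.loc[mask].reset_index(drop=True),
            self.ad[mask],
            self.dp[mask],
            self.samples,
        )

    def cohort_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """(AD, DP) split by cohort, ordered by pair: young first, then aged."""
        pairs = sorted(self.samples["pair"].unique())
        yi, ai = [], []
        for p in pairs:
            sub = self.samples[self.samples["pair"] == p]
            yi.append(sub.index[sub["cohort"] == "young"][0])
            ai.append(sub.index[sub["cohort"] == "aged"][0])
        return self.ad[:, yi], self.dp[:, yi], self.ad[:, ai], self.dp[:, ai]


def filter_variants(
    pool: PoolCounts,
    min_cov: int = 20,
    max_cov: int = 1000,
    min_maf: float = 0.05,
) -> PoolCounts:
    """Apply the coverage and minor-allele-frequency filters.

    A variant is retained iff its total depth lies in [min_cov, max_cov]
    in *every* replicate-cohort sample and its dataset-wide pooled
    minor-allele frequency (read counts summed over all samples) is at
    least ``min_maf``; both bounds are inclusive.  Input order is
    preserved, so the filter is idempotent.
    """
    if min_cov <= 0 or max_cov <= 0 or min_cov > max_cov:
        raise ValueError("require 0 < min_cov <= max_cov")
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must lie in [0, 0.5]")
    cov_ok = ((pool.dp >= min_cov) & (pool.dp <= max_cov)).all(axis=1)
    tot_dp = pool.dp.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(tot_dp > 0, pool.ad.sum(axis=1) / tot_dp, 0.0)
    maf = np.minimum(p, 1.0 - p)
    keep = cov_ok & (maf >= min_maf)
    if not keep.any():
        warnings.warn("no variants pass the coverage/MAF filters")
    return pool.subset(keep)


def cmh_from_tables(tables: np.ndarray) -> tuple[float, float]:
    """CMH statistic and p for one variant given explicit strata.

    ``tables`` has shape (K, 2, 2) with rows (young, aged) and columns
    (alt, ref) per stratum.  Strata whose alt (or ref) margin is zero,
    or with total < 2, contribute nothing to numerator or variance.
    """
    t = np.asarray(tables, dtype=float)
    if t.ndim != 3 or t.shape[1:] != (2, 2):
        raise ValueError("tables must have shape (K, 2, 2)")
    if t.shape[0] < 1:
        raise ValueError("need at least one stratum")
    a = t[:, 0, 0]
    n1 = t[:, 0, :].sum(axis=1)  # young total
    n2 = t[:, 1, :].sum(axis=1)  # aged total
    m1 = t[:, :, 0].sum(axis=1)  # alt margin
    T = n1 + n2
    if (T <= 0).any():
        raise ValueError("every stratum must have positive total")
    ok = (T >= 2) & (m1 > 0) & (m1 < T)
    num = np.where(ok, a - n1 * m1 / np.where(T > 0, T, 1), 0.0).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        v = n1 * n2 * m1 * (T - m1) / (T**2 * (T - 1))
    var = np.where(ok, v, 0.0).sum()
    if var <= 0:
        return 0.0, 1.0
    stat = num**2 / var
    return float(stat), float(stats.chi2.sf(stat, df=1))


def cmh_test(
    ad_young: np.ndarray,
    dp_young: np.ndarray,
    ad_aged: np.ndarray,
    dp_aged: np.ndarray,
) -> pd.DataFrame:
    """Vectorized CMH test over many variants.

    Inputs are (n_variants, n_pairs) arrays of alternate and total
    depths for each cohort; each replicate pair is one stratum.  Returns
    a frame with ``statistic``, ``p_value``, ``neg_log10_p`` and a
    ``degenerate`` flag for variants in which every stratum was
    uninformative (those get p = 1).
    """
    ay, dy = np.asarray(ad_young, float), np.asarray(dp_young, float)
    aa, da = np.asarray(ad_aged, float), np.asarray(dp_aged, float)
    m1 = ay + aa
    T = dy + da
    ok = (T >= 2) & (m1 > 0) & (m1 < T)
    Ts = np.where(T > 0, T, 1.0)
    num = np.where(ok, ay - dy * m1 / Ts, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        v = dy * da * m1 * (T - m1) / (Ts**2 * (Ts - 1))
    var = np.where(ok, v, 0.0).sum(axis=1)
    degenerate = var <= 0
    stat = np.where(degenerate, 0.0, num**2 / np.where(degenerate, 1.0, var))
    p = np.where(degenerate, 1.0, stats.chi2.sf(stat, df=1))
    with np.errstate(divide="ignore"):
        nlp = -np.log10(p)
    return pd.DataFrame(
        {"statistic": stat, "p_value": p, "neg_log10_p": nlp, "degenerate": degenerate}
    )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> tuple[float, float]:
    """Genome-wide Bonferroni cutoff: (per-test p cutoff, -log10 cutoff)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    cutoff = alpha / n_tests
    return cutoff, float(-np.log10(cutoff))


def differentiation_test(
    pool: PoolCounts,
    alpha: float = 0.05,
    joint_threshold: bool = False,
) -> pd.DataFrame:
    """Run the CMH test on every variant and flag genome-wide significance.

    By default Bonferroni cutoffs are computed separately per variant
    class (SNPs and indels are counted, and reported, separately);
    ``joint_threshold`` pools both classes into a single cutoff.
    Returns the variant table augmented with statistic, p, -log10 p,
    the class cutoff used, and the ``significant`` flag.
    """
    pool.validate()
    ay, dy, aa, da = pool.cohort_arrays()
    res = cmh_test(ay, dy, aa, da)
    out = pd.concat([pool.variants.reset_index(drop=True), res], axis=1)
    out["p_cutoff"] = np.nan
    if joint_threshold:
        cutoff, _ = bonferroni_threshold(len(out), alpha)
        out["p_cutoff"] = cutoff
    else:
        for cls, idx in out.groupby("variant_class").groups.items():
            cutoff, _ = bonferroni_threshold(len(idx), alpha)
            out.loc[idx, "p_cutoff"] = cutoff
    out["significant"] = out["p_value"] < out["p_cutoff"]
    return out


def extract_candidates(
    results: pd.DataFrame, genes: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Extract the candidate genomic variant list.

    From the CMH result table, take the threshold-passing variants and
    keep those whose position falls inside a gene body (start <= pos <=
    end), attaching the gene id.  Returns (candidates, full significant
    set, sorted unique gene ids hit).  A variant inside two overlapping
    genes yields one candidate row per gene.
    """
    validate_gene_models(genes)
    sig = results[results["significant"]].reset_index(drop=True)
    rows = []
    by_chrom = {c: g for c, g in genes.groupby("chrom")}
    for i, row in sig.iterrows():
        g = by_chrom.get(row["chrom"])
        if g is None:
            continue
        hit = g[(g["start"] <= row["pos"]) & (row["pos"] <= g["end"])]
        for gene_id in hit["gene_id"]:
            rows.append({**row.to_dict(), "gene_id": gene_id})
    candidates = pd.DataFrame(rows, columns=list(sig.columns) + ["gene_id"])
    genes_hit = sorted(candidates["gene_id"].unique()) if len(candidates) else []
    return candidates, sig, genes_hit
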