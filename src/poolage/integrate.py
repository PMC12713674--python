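"""Integration of the genomic and transcriptomic candidate lists.

Three procedures ask whether differential expression is driven by local
(cis) variation:

1. a proximity scan counting significant variants within 10/5/1 kb of
   each differentially expressed gene, with a variant-type breakdown of
   the 10-kb set (the tally table),
2. an annotation-category contingency comparison of the candidate
   variant list against genome-wide annotations, tested with a
   simulated (Monte-Carlo) Fisher's exact test after pooling rare
   categories into "other", and
3. a permutation test of whether DE genes are more likely than random
   gene sets to lie near significant variants.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .sim import ANN_NONSYN, ANN_SYN, validate_gene_models

__all__ = [
    "variant_gene_distance",
    "proximity_scan",
    "tally_totals",
    "regroup_annotations",
    "fisher_simulated",
    "de_proximity_enrichment",
    "overlap_genes",
]

TALLY_COLUMNS = [
    "gene_id",
    "within_gene",
    "within_10kb",
    "within_5kb",
    "within_1kb",
    "nonsynonymous_snps",
    "synonymous_snps",
    "intergenic_snps",
    "indels",
]


def variant_gene_distance(pos: np.ndarray, start: int, end: int) -> np.ndarray:
    """Distance from variant positions to a gene span; 0 inside the span."""
    pos = np.asarray(pos)
    return np.where(
        pos < start, start - pos, np.where(pos > end, pos - end, 0)
    )


def _variant_type(variant_class: str, annotation: str) -> str:
    if variant_class != "SNP":
        return "indels"
    if annotation == ANN_NONSYN:
        return "nonsynonymous_snps"
    if annotation == ANN_SYN:
        return "synonymous_snps"
    return "intergenic_snps"


def proximity_scan(
    variants: pd.DataFrame,
    de_genes: pd.DataFrame,
    thresholds: tuple[int, int, int] = (10_000, 5_000, 1_000),
) -> pd.DataFrame:
    """Tally significant variants near each differentially expressed gene.

    A variant lies within distance d of a gene iff the gap between its
    position and the gene span is <= d (0 when inside).  A variant near
    two DE genes counts toward both.  Rows are emitted only for DE genes
    with at least one variant within the largest threshold; the 10-kb
    set is broken down into nonsynonymous, synonymous and intergenic
    SNPs plus indels (every non-SNP record).  ``variants`` needs
    chrom/pos/variant_class/annotation columns, ``de_genes`` is a gene
    model table restricted to the DE list.
    """
    validate_gene_models(de_genes)
    t_max, t_mid, t_min = sorted(thresholds, reverse=True)
    rows = []
    for g in de_genes.itertuples(index=False):
        if not np.isfinite(g.start) or not np.isfinite(g.end):
            warnings.warn(f"DE gene {g.gene_id} has no coordinates; skipped")
            continue
        on_chrom = variants[variants["chrom"] == g.chrom]
        if not len(on_chrom):
            continue
        d = variant_gene_distance(on_chrom["pos"].to_numpy(), g.start, g.end)
        near = on_chrom[d <= t_max]
        if not len(near):
            continue
        d_near = d[d <= t_max]
        rec = {
            "gene_id": g.gene_id,
            "within_gene": int((d_near == 0).sum()),
            "within_10kb": int(len(near)),
            "within_5kb": int((d_near <= t_mid).sum()),
            "within_1kb": int((d_near <= t_min).sum()),
            "nonsynonymous_snps": 0,
            "synonymous_snps": 0,
            "intergenic_snps": 0,
            "indels": 0,
        }
        anns = (
            near["annotation"]
            if "annotation" in near.columns
            else pd.Series(ANN_INTERGENIC, index=near.index)
        )
        for vc, ann in zip(near["variant_class"], anns):
            rec[_variant_type(vc, ann)] += 1
        rows.append(rec)
    return pd.DataFrame(rows, columns=TALLY_COLUMNS)


def tally_totals(tally: pd.DataFrame) -> pd.Series:
    """Column sums of a proximity tally (the Totals row of the table)."""
    totals = tally.drop(columns="gene_id").sum()
    totals["gene_id"] = "Totals"
    return totals[TALLY_COLUMNS]


def regroup_annotations(
    candidate_labels: pd.Series | np.ndarray,
    genome_labels: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Pool rare annotation categories into "other" in both columns.

    Any category with a count of 1 or fewer in the candidate list is
    merged into "other" — in the candidate column *and* in the
    genome-wide column — so the contingency comparison is over the same
    category set.  Returns a frame indexed by category with columns
    ``candidate`` and ``genome``.
    """
    cand = pd.Series(candidate_labels).value_counts()
    genome = pd.Series(genome_labels).value_counts()
    keep = [c for c in cand.index if cand[c] > 1]
    if not keep:
        warnings.warn(
            "every annotation category is rare in the candidate list; "
            "only 'other' remains and the enrichment test cannot run"
        )
    rows = {}
    for c in keep:
        rows[c] = {"candidate": int(cand[c]), "genome": int(genome.get(c, 0))}
    other_cand = int(cand.sum() - sum(r["candidate"] for r in rows.values()))
    other_gen = int(genome.sum() - sum(r["genome"] for r in rows.values()))
    rows["other"] = {"candidate": other_cand, "genome": other_gen}
    table = pd.DataFrame(rows).T
    table.index.name = "category"
    return table


def _log_table_prob(a: np.ndarray, row_totals: np.ndarray, n1: int) -> np.ndarray:
    """Log null probability of r x 2 tables with fixed margins.

    ``a`` holds column-1 counts per row (last axis); the probability is
    the multivariate hypergeometric prod_i C(r_i, a_i) / C(N, n1).
    """
    r = row_totals
    lg = gammaln(r + 1) - gammaln(a + 1) - gammaln(r - a + 1)
    N = int(r.sum())
    denom = gammaln(N + 1) - gammaln(n1 + 1) - gammaln(N - n1 + 1)
    return lg.sum(axis=-1) - denom


def fisher_simulated(
    table: pd.DataFrame | np.ndarray,
    n_sim: int = 100_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Monte-Carlo Fisher's exact test for an r x 2 contingency table.

    Samples ``n_sim`` tables from the fixed-margin null (multivariate
    hypergeometric) and reports
    p = (1 + #{P(simulated) <= P(observed)}) / (n_sim + 1) together with
    its binomial Monte-Carlo standard error.
    """
    T = np.asarray(table, dtype=np.int64)
    if T.ndim != 2 or T.shape[1] != 2:
        raise ValueError("table must be r x 2")
    if (T < 0).any():
        raise ValueError("counts must be non-negative")
    row_totals = T.sum(axis=1)
    if (row_totals <= 0).any():
        raise ValueError("every row total must be positive")
    if T.shape[0] < 2:
        warnings.warn("degenerate one-row table; p = 1")
        return 1.0, 0.0
    rng = np.random.default_rng(seed)
    n1 = int(T[:, 0].sum())
    obs_lp = _log_table_prob(T[:, 0].astype(float), row_totals.astype(float), n1)
    sims = rng.multivariate_hypergeometric(row_totals, n1, size=n_sim)
    sim_lp = _log_table_prob(sims.astype(float), row_totals.astype(float), n1)
    hits = int((sim_lp <= obs_lp + 1e-9).sum())
    p = (1 + hits) / (n_sim + 1)
    se = float(np.sqrt(p * (1 - p) / (n_sim + 1)))
    return float(p), se


def gene_has_nearby_variant(
    genes: pd.DataFrame, variants: pd.DataFrame, threshold: int = 10_000
) -> pd.Series:
    """Boolean per gene: does any variant lie within ``threshold`` of it."""
    validate_gene_models(genes)
    hits = []
    for g in genes.itertuples(index=False):
        on_chrom = variants[variants["chrom"] == g.chrom]
        if not len(on_chrom):
            hits.append(False)
            continue
        d = variant_gene_distance(on_chrom["pos"].to_numpy(), g.start, g.end)
        hits.append(bool((d <= threshold).any()))
    return pd.Series(hits, index=genes["gene_id"].to_numpy(), name="has_nearby_variant")


def de_proximity_enrichment(
    de_gene_ids: list[str],
    all_genes: pd.DataFrame,
    variants: pd.DataFrame,
    threshold: int = 10_000,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> dict:
    """Permutation test: are DE genes closer to significant variants than chance?

    The statistic is the fraction of DE genes with at least one
    significant variant within ``threshold``; the null redraws gene sets
    of the same size uniformly from all tested genes (the null count of
    hit genes is exactly hypergeometric, which is how it is sampled).
    One-sided p = (1 + #{null >= observed}) / (n_perm + 1).
    """
    if len(de_gene_ids) == 0:
        raise ValueError("DE gene set is empty")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    unknown = set(de_gene_ids) - set(all_genes["gene_id"])
    if unknown:
        raise ValueError(f"DE genes absent from the gene universe: {sorted(unknown)}")
    hits = gene_has_nearby_variant(all_genes, variants, threshold)
    k = len(de_gene_ids)
    observed = float(hits.loc[list(de_gene_ids)].mean())
    n_hit = int(hits.sum())
    n_tot = len(hits)
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(n_hit, n_tot - n_hit, k, size=n_perm) / k
    p = (1 + int((null >= observed - 1e-12).sum())) / (n_perm + 1)
    return {
        "observed_fraction": observed,
        "n_de_genes": k,
        "n_de_genes_hit": int(round(observed * k)),
        "null_mean": float(null.mean()),
        "p_value": float(p),
        "threshold": threshold,
        "n_perm": n_perm,
    }


def overlap_genes(
    genomic_genes: list[str] | set[str], de_genes: list[str] | set[str]
) -> pd.DataFrame:
    """Genes implicated by both the genomic and transcriptomic analyses."""
    genomic = set(genomic_genes)
    de = set(de_genes)
    both = sorted(genomic & de)
    return pd.DataFrame(
        {
            "gene_id": both,
            "in_genomic": [True] * len(both),
            "in_transcriptomic": [True] * len(both),
        }
    )
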