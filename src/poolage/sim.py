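"""Synthetic cohort generator for the pooled aging-sort study design.

Emulates the experimental design this package analyses: a recombinant
yeast population founded by four diverged haploid strains, grown and
sorted by replicative age into 12 paired young/aged replicate cohorts,
then pool-sequenced (DNA) and expression-profiled (3' RNA counts).

Every generator is deterministic given its seed, and each returns the
ground truth needed for parameter-recovery tests downstream: causal
selected sites, true founder-haplotype frequencies per window, and the
true differential-expression effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FounderPanel",
    "SimTruth",
    "simulate_founders",
    "simulate_gene_models",
    "apply_age_selection",
    "simulate_individuals",
    "pool_freqs_from_individuals",
    "window_founder_freqs",
    "simulate_recombinant_pool",
    "selection_weights",
    "simulate_pool_reads",
    "simulate_expression",
    "assign_annotations",
]

#: annotation labels the simulator can emit (SnpEff-style strings)
ANN_NONSYN = "missense_variant"
ANN_SYN = "synonymous_variant"
ANN_UPSTREAM = "upstream_gene_variant"
ANN_DOWNSTREAM = "downstream_gene_variant"
ANN_INTERGENIC = "intergenic_region"
ANN_NONCODING = "non_coding_transcript_variant"

#: SnpEff's flank for upstream/downstream gene variants, in bp
SNPEFF_FLANK = 5000


@dataclass
class FounderPanel:
    """Biallelic genotype matrix of the founder strains.

    ``G[i, j]`` is the alternate-allele state (0/1) of founder *i* at
    site *j*.  Sites are ordered by (chromosome, position) and positions
    are 1-based.
    """

    founder_ids: list[str]
    chrom: np.ndarray  # (n_sites,) str
    pos: np.ndarray  # (n_sites,) int, 1-based
    G: np.ndarray  # (n_founders, n_sites) int8 in {0, 1}

    @property
    def n_founders(self) -> int:
        return len(self.founder_ids)

    @property
    def n_sites(self) -> int:
        return self.pos.size

    def validate(self) -> None:
        if self.G.shape != (self.n_founders, self.n_sites):
            raise ValueError("G shape inconsistent with founder_ids/pos")
        if not np.isin(self.G, (0, 1)).all():
            raise ValueError("founder genotypes must be biallelic 0/1")
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if not (np.diff(p) > 0).all():
                raise ValueError(f"positions not strictly increasing on {c}")
            g = self.G[:, self.chrom == c]
            if g.size and (g == g[0]).all():
                raise ValueError(
                    f"no polymorphic site on {c}: founders are indistinguishable"
                )

    def polymorphic(self) -> np.ndarray:
        """Boolean mask of sites at which at least two founders differ."""
        return (self.G != self.G[0]).any(axis=0)

    def subset(self, mask: np.ndarray) -> "FounderPanel":
        return FounderPanel(
            self.founder_ids, self.chrom[mask], self.pos[mask], self.G[:, mask]
        )


@dataclass
class SimTruth:
    """Ground truth of one simulated study, for recovery tests."""

    seed: int
    causal_sites: list[tuple[str, int, float]] = field(default_factory=list)
    favored_founders: list[str] = field(default_factory=list)
    true_hap_freqs: dict | None = None  # sample -> (n_windows, n_founders)
    de_genes: list[tuple[str, float]] = field(default_factory=list)
    dispersion: float | np.ndarray | None = None


def _split_sites(n_sites: int, n_chroms: int) -> list[int]:
    base = n_sites // n_chroms
    extra = n_sites % n_chroms
    return [base + (1 if i < extra else 0) for i in range(n_chroms)]


def simulate_founders(
    n_founders: int = 4,
    n_sites: int = 10_000,
    divergence: float = 0.06,
    seed: int | None = None,
    *,
    n_chroms: int = 3,
    spacing: int = 10,
    founder_ids: Sequence[str] | None = None,
) -> FounderPanel:
    """Simulate a founder genotype panel.

    Each site is polymorphic among the founders with probability
    ``divergence``; polymorphic sites receive a genotype pattern drawn
    uniformly from the non-constant 0/1 patterns.  Sites are laid out
    every ``spacing`` bp across ``n_chroms`` chromosomes.
    """
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    if n_sites < 1:
        raise ValueError("need at least 1 site")
    if not 0.0 < divergence < 1.0:
        raise ValueError(f"divergence must lie in (0, 1), got {divergence}")
    rng = np.random.default_rng(seed)
    if founder_ids is None:
        founder_ids = [f"F{i + 1}" for i in range(n_founders)]
    else:
        founder_ids = list(founder_ids)
        if len(founder_ids) != n_founders:
            raise ValueError("founder_ids length must equal n_founders")

    chroms, positions = [], []
    for i, n in enumerate(_split_sites(n_sites, n_chroms)):
        chroms.append(np.repeat(f"chr{i + 1}", n))
        positions.append(spacing * np.arange(1, n + 1, dtype=np.int64))
    chrom = np.concatenate(chroms)
    pos = np.concatenate(positions)

    G = np.zeros((n_founders, n_sites), dtype=np.int8)
    poly = rng.random(n_sites) < divergence
    n_poly = int(poly.sum())
    # uniform over non-constant patterns: integers in [1, 2^n - 1)
    codes = rng.integers(1, 2**n_founders - 1, size=n_poly)
    bits = (codes[:, None] >> np.arange(n_founders)[None, :]) & 1
    G[:, poly] = bits.T.astype(np.int8)

    panel = FounderPanel(founder_ids, chrom, pos, G)
    panel.validate()
    return panel


def simulate_gene_models(
    chrom_lengths: dict[str, int],
    gene_spacing: int = 2000,
    gene_length: int = 1200,
    seed: int | None = None,
    coding_fraction: float = 0.95,
) -> pd.DataFrame:
    """Lay regularly spaced gene models along each chromosome.

    Returns a gene-model table with columns ``gene_id, chrom, start,
    end, strand, coding`` (1-based inclusive spans), mimicking the dense
    packing of the yeast genome (~1 gene per 2 kb).
    """
    if gene_length >= gene_spacing:
        raise ValueError("gene_length must be smaller than gene_spacing")
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for chrom, length in chrom_lengths.items():
        start = gene_spacing // 4
        while start + gene_length <= length:
            k += 1
            rows.append(
                {
                    "gene_id": f"G{k:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + gene_length - 1,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "coding": bool(rng.random() < coding_fraction),
                }
            )
            start += gene_spacing
    genes = pd.DataFrame(rows)
    validate_gene_models(genes)
    return genes


def validate_gene_models(genes: pd.DataFrame) -> None:
    required = {"gene_id", "chrom", "start", "end", "strand"}
    missing = required - set(genes.columns)
    if missing:
        raise ValueError(f"gene model table missing columns: {sorted(missing)}")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("gene model with start > end")
    if genes["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_ids in gene model table")


def apply_age_selection(
    base_freqs: np.ndarray,
    causal_sites: Sequence[tuple[int, float]],
) -> tuple[np.ndarray, np.ndarray]:
    """Shift allele frequencies at causal sites by one round of haploid selection.

    The young cohort keeps the base frequencies; in the aged cohort each
    causal site with coefficient *s* moves from *f* to
    ``f (1 + s) / (1 + s f)`` — the post-selection frequency when the
    alternate allele has relative fitness 1 + s.
    """
    base_freqs = np.asarray(base_freqs, dtype=float)
    if ((base_freqs < 0) | (base_freqs > 1)).any():
        raise ValueError("base frequencies must lie in [0, 1]")
    young = base_freqs.copy()
    aged = base_freqs.copy()
    for idx, s in causal_sites:
        if not np.isfinite(s) or s <= -1:
            raise ValueError(f"selection coefficient must be > -1, got {s}")
        f = aged[idx]
        aged[idx] = f * (1 + s) / (1 + s * f)
    return young, aged


def simulate_individuals(
    panel: FounderPanel,
    n_individuals: int,
    crossovers_per_chrom: float = 12.0,
    seed: int | None = None,
    founder_probs: np.ndarray | None = None,
) -> np.ndarray:
    """Draw recombinant genomes as founder-block mosaics.

    Each genome is, per chromosome, a sequence of blocks separated by a
    Poisson number of crossovers at uniform positions; the founder of
    each block is drawn independently from ``founder_probs`` (uniform by
    default).  Returns an (n_individuals, n_sites) matrix of founder
    indices.
    """
    if n_individuals < 10:
        raise ValueError("n_individuals must be >= 10")
    if crossovers_per_chrom < 0:
        raise ValueError("crossovers_per_chrom must be >= 0")
    rng = np.random.default_rng(seed)
    nf = panel.n_founders
    if founder_probs is None:
        founder_probs = np.full(nf, 1.0 / nf)
    founder_probs = np.asarray(founder_probs, dtype=float)
    founder_probs = founder_probs / founder_probs.sum()

    H = np.empty((n_individuals, panel.n_sites), dtype=np.int8)
    for c in pd.unique(panel.chrom):
        cols = np.flatnonzero(panel.chrom == c)
        p = panel.pos[cols].astype(float)
        lo, hi = p[0], p[-1] + 1
        n_x = rng.poisson(crossovers_per_chrom, size=n_individuals)
        for i in range(n_individuals):
            cuts = np.sort(rng.uniform(lo, hi, size=n_x[i]))
            block = np.searchsorted(cuts, p, side="right")
            owners = rng.choice(nf, size=n_x[i] + 1, p=founder_probs)
            H[i, cols] = owners[block]
    return H


def selection_weights(
    panel: FounderPanel,
    H: np.ndarray,
    causal_sites: Sequence[tuple[int, float]],
) -> np.ndarray:
    """Per-individual fitness weights from alleles carried at causal sites.

    An individual carrying the alternate allele at a causal site with
    coefficient *s* has its weight multiplied by 1 + s; weights are
    normalized to sum to 1.
    """
    w = np.ones(H.shape[0])
    for idx, s in causal_sites:
        if not np.isfinite(s) or s <= -1:
            raise ValueError(f"selection coefficient must be > -1, got {s}")
        allele = panel.G[H[:, idx], idx]
        w *= np.where(allele == 1, 1.0 + s, 1.0)
    return w / w.sum()


def pool_freqs_from_individuals(
    panel: FounderPanel, H: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Pool alternate-allele frequency per site: weighted mean founder allele."""
    alleles = np.take_along_axis(
        panel.G, H.astype(np.intp), axis=0
    )  # (n_ind, n_sites) via founder lookup
    if weights is None:
        return alleles.mean(axis=0)
    return weights @ alleles.astype(float)


def window_founder_freqs(
    panel: FounderPanel,
    H: np.ndarray,
    windows: pd.DataFrame,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """True founder-frequency simplex per window (weighted over individuals).

    ``windows`` must carry ``chrom, start, end`` columns (1-based,
    inclusive start, exclusive end semantics handled by the caller's
    window builder; membership here is start <= pos < start + size i.e.
    pos <= end means inclusive end).  Returns (n_windows, n_founders).
    """
    n_ind = H.shape[0]
    if weights is None:
        weights = np.full(n_ind, 1.0 / n_ind)
    nf = panel.n_founders
    out = np.full((len(windows), nf), np.nan)
    for wi, row in enumerate(windows.itertuples(index=False)):
        mask = (
            (panel.chrom == row.chrom)
            & (panel.pos >= row.start)
            & (panel.pos <= row.end)
        )
        cols = np.flatnonzero(mask)
        if cols.size == 0:
            continue
        sub = H[:, cols]  # (n_ind, n_in_window)
        counts = np.zeros(nf)
        for f in range(nf):
            counts[f] = (weights @ (sub == f)).mean()
        out[wi] = counts / counts.sum()
    return out


def simulate_recombinant_pool(
    panel: FounderPanel,
    n_individuals: int,
    crossovers_per_chrom: float = 12.0,
    seed: int | None = None,
    *,
    windows: pd.DataFrame | None = None,
    founder_probs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate one pooled cohort and return (site frequencies, window truth).

    Window truth is the founder-frequency simplex per window; ``None``
    when no windows are given.
    """
    H = simulate_individuals(
        panel, n_individuals, crossovers_per_chrom, seed, founder_probs
    )
    freqs = pool_freqs_from_individuals(panel, H)
    truth = None if windows is None else window_founder_freqs(panel, H, windows)
    return freqs, truth


def simulate_pool_reads(
    true_freqs: np.ndarray,
    coverage: float | np.ndarray = 100.0,
    seed: int | None = None,
    depth_dispersion: float = 0.15,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample pooled sequencing read counts.

    Depth per site is negative binomial around the mean ``coverage``
    (per sample), mimicking the wide coverage spread of pooled libraries;
    the alternate-allele depth is binomial given depth and the true
    frequency.  Returns (AD, DP) arrays of the same shape as
    ``true_freqs`` (sites, or sites x samples).
    """
    f = np.asarray(true_freqs, dtype=float)
    if ((f < 0) | (f > 1)).any():
        raise ValueError("true frequencies must lie in [0, 1]")
    cov = np.broadcast_to(np.asarray(coverage, dtype=float), f.shape)
    if (cov < 1).any():
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(seed)
    if depth_dispersion > 0:
        n = 1.0 / depth_dispersion
        dp = rng.negative_binomial(n, n / (n + cov))
    else:
        dp = rng.poisson(cov)
    ad = rng.binomial(dp, f)
    return ad.astype(np.int64), dp.astype(np.int64)


def simulate_expression(
    n_genes: int,
    n_pairs: int = 12,
    de_genes: Sequence[tuple[int, float]] = (),
    pair_sd: float = 0.3,
    batch_shift: float = 0.2,
    dispersion: float = 0.05,
    seed: int | None = None,
    *,
    gene_ids: Sequence[str] | None = None,
    mean_log_expr: float = 6.0,
    sd_log_expr: float = 1.5,
) -> tuple[pd.DataFrame, pd.DataFrame, SimTruth]:
    """Simulate a paired young/aged count matrix.

    Counts are negative binomial with log-mean
    ``mu_g + pair_i + batch + lfc_g * ln2 * T`` where T is 0 for young
    and 1 for aged samples: the generative twin of the paired model the
    analysis fits.  Pairs 1..n/2 form batch A, the rest batch B, and the
    additive (log-scale) ``batch_shift`` is applied to batch B.

    Returns (counts genes x samples, sample sheet, truth).  DE effects
    are given in log2 units.
    """
    if n_pairs < 2:
        raise ValueError("need at least 2 pairs")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    for g, _ in de_genes:
        if not 0 <= g < n_genes:
            raise ValueError(f"DE gene index {g} outside 0..{n_genes - 1}")
    rng = np.random.default_rng(seed)
    if gene_ids is None:
        gene_ids = [f"G{i + 1:04d}" for i in range(n_genes)]
    gene_ids = list(gene_ids)

    lfc = np.zeros(n_genes)
    for g, e in de_genes:
        lfc[g] = e
    base = rng.normal(mean_log_expr, sd_log_expr, size=n_genes)
    pair_eff = rng.normal(0.0, pair_sd, size=n_pairs)

    samples, cols = [], []
    log_mu = np.empty((n_genes, 2 * n_pairs))
    j = 0
    for p in range(1, n_pairs + 1):
        batch = "A" if p <= n_pairs // 2 else "B"
        b = batch_shift if batch == "B" else 0.0
        for t, cohort in ((0, "young"), (1, "aged")):
            name = f"R{p:02d}_{cohort}"
            samples.append({"sample": name, "pair": p, "cohort": cohort, "batch": batch})
            log_mu[:, j] = base + pair_eff[p - 1] + b + lfc * np.log(2) * t
            cols.append(name)
            j += 1
    mu = np.exp(log_mu)
    n = 1.0 / dispersion
    counts = rng.negative_binomial(n, n / (n + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=cols)
    samples_df = pd.DataFrame(samples)
    truth = SimTruth(
        seed=-1 if seed is None else int(seed),
        de_genes=[(gene_ids[g], e) for g, e in de_genes],
        dispersion=dispersion,
    )
    return counts_df, samples_df, truth


def assign_annotations(
    variants: pd.DataFrame,
    genes: pd.DataFrame,
    seed: int | None = None,
    p_nonsyn: float = 1.0 / 3.0,
    flank: int = SNPEFF_FLANK,
) -> pd.Series:
    """Assign one SnpEff-style category label per variant.

    A variant inside a coding gene body becomes nonsynonymous with
    probability ``p_nonsyn`` and synonymous otherwise (the simulator
    carries no codon sequence, so the split is probabilistic).  Variants
    within ``flank`` bp 5' of a gene (strand-aware) are upstream gene
    variants, within ``flank`` bp 3' downstream gene variants, and
    everything else intergenic.  Genic assignment takes precedence over
    flanking, and the nearest qualifying gene wins ties.
    """
    validate_gene_models(genes)
    rng = np.random.default_rng(seed)
    known_chroms = set(genes["chrom"])
    labels = np.full(len(variants), ANN_INTERGENIC, dtype=object)
    by_chrom = {c: g.sort_values("start") for c, g in genes.groupby("chrom")}

    unknown = 0
    for i, (chrom, pos) in enumerate(zip(variants["chrom"], variants["pos"])):
        if chrom not in known_chroms:
            unknown += 1
            continue
        g = by_chrom[chrom]
        inside = g[(g["start"] <= pos) & (pos <= g["end"])]
        if len(inside):
            row = inside.iloc[0]
            if row.get("coding", True):
                labels[i] = ANN_NONSYN if rng.random() < p_nonsyn else ANN_SYN
            else:
                labels[i] = ANN_NONCODING
            continue
        # nearest flanking gene within `flank`, strand-aware direction
        best_d, best_lab = None, None
        near = g[(g["start"] - flank <= pos) & (pos <= g["end"] + flank)]
        for row in near.itertuples(index=False):
            if pos < row.start:
                d = row.start - pos
                lab = ANN_UPSTREAM if row.strand == "+" else ANN_DOWNSTREAM
            else:
                d = pos - row.end
                lab = ANN_DOWNSTREAM if row.strand == "+" else ANN_UPSTREAM
            if d <= flank and (best_d is None or d < best_d):
                best_d, best_lab = d, lab
        if best_lab is not None:
            labels[i] = best_lab
    if unknown:
        warnings.warn(
            f"{unknown} variants on chromosomes absent from the gene models; "
            "labeled intergenic"
        )
    return pd.Series(labels, index=variants.index, name="annotation")
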