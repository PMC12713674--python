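# Methods

This note documents the models, estimators, defaults and known
limitations of `poolage`. Notation: 12 replicate pairs, each with a
young and an aged pooled cohort; 4 founder strains; variants indexed by
genomic position; genes by gene id.

## Synthetic study generator (`poolage.sim`)

The generator emulates the sorted-cohort design end to end.

**Founder panel.** `simulate_founders` lays sites at a fixed spacing
across `n_chroms` chromosomes; each site is polymorphic among the
founders with probability `divergence` (default 0.06, a realistic
between-strain divergence for diverged yeast isolates), with the
genotype pattern drawn uniformly from the non-constant 0/1 patterns.
Positions are 1-based; the panel is validated to be biallelic and
sorted.

**Recombinant individuals.** Each genome is a founder-block mosaic: per
chromosome, a Poisson number of crossovers (default 12 per chromosome,
reflecting the repeatedly outcrossed base population) at uniform
positions, with each block's founder drawn independently. This is a
haploid caricature of the diploid pool: it reproduces the two features
the downstream estimators rely on — local founder identity and linkage
of nearby sites — but carries no heterozygosity, no crossover
interference and no realistic recombination map.

**Age-associated selection.** A causal site with coefficient *s* gives
carriers of the alternate allele relative fitness 1 + *s*. The aged
cohort of each replicate is the same set of individuals reweighted by
fitness, so at the causal site the allele frequency moves from $f$ to
$f(1+s)/(1+sf)$ — one round of haploid selection — and linked sites and
founder haplotypes shift through the mosaic structure rather than
through an explicit LD model. Young cohorts keep uniform weights. The
default study has one selected locus per chromosome (3 total, s = 0.5),
each a site where exactly one founder carries the alternate allele, so
each peak corresponds to a single ancestral haplotype rising — the
qualitative pattern of the real experiment. Selection strength in the
real sorting experiment is unknown; s = 0.5 makes the allele shift
(~0.08 from a founder frequency of 0.25) comparable to the read-noise
floor at the default coverage, which is the interesting regime.

**Pooled reads.** Depth per site and sample is negative binomial around
the mean coverage (default 117×, dispersion 0.15, giving the ~40–280×
spread seen in pooled libraries); alternate depth is binomial given
depth and the true pool frequency. Read draws are independent across
sites; no mapping bias, base error or effective-pool-size correction is
modeled.

**Expression.** Counts are negative binomial with log-mean
`base + pair + batch + lfc·ln2·T`; pair effects are N(0, 0.3²), batch B
(pairs 7–12) is shifted by +0.2 on the log scale, gene-level dispersion
defaults to 0.05 (typical for yeast bulk RNA-seq), and baseline
log-means are N(6, 1.5²). The default study makes 5 % of genes truly DE
(30 % up at +0.5 log2, 70 % down at −0.8), an elevated DE fraction
chosen so the desk-scale integration tallies are non-trivial; the real
study's fraction was ~1 % of a 5,620-gene transcriptome.

**Annotations.** The simulator carries no codon sequence, so variants
inside coding genes are labeled nonsynonymous with probability 1/3 and
synonymous otherwise; variants within 5 kb of a gene are labeled
upstream/downstream strand-awarely (SnpEff semantics), the rest
intergenic. Annotation labels are consumed downstream as opaque category
strings.

What passing tests on this generator do **not** show: robustness to
alignment artifacts, multi-allelic sites, uneven mappability, diploid
dosage, or dispersion trends across expression strata — none of which
the generator produces.

## Variant differentiation (`poolage.variants`)

Filters follow the study design: total depth within [20, 1000] in every
replicate-cohort (inclusive), then dataset-wide pooled MAF ≥ 5 %
(inclusive; read counts summed over all 24 samples, matching a
"across the dataset" definition). Coverage is applied before MAF; the
order is a free choice and both filters commute on fixed thresholds.

The CMH statistic is implemented from the Mantel–Haenszel formula with
no continuity correction, treating reads as independent draws. Strata
with a zero alt or ref margin (or total < 2) contribute nothing; a
variant degenerate in every stratum reports p = 1 with a flag.
Bonferroni cutoffs are per variant class (SNP/indel) by default because
the two classes are tested and reported separately; `joint_threshold`
pools them. A single-stratum CMH equals the 2×2 score chi-square
(Pearson × (T−1)/T), which the tests verify by brute force, and the
full statistic is cross-checked against an independent stratified-table
implementation.

Known limitation: read counts overstate the information content of a
pool when the effective number of sorted cells is small; no
effective-pool-size correction is applied.

## Haplotype windows (`poolage.haplotypes`)

Windows are 5 kb stepping 2 kb, anchored at each chromosome's first SNP
(the anchor is a free choice, recorded in output headers); membership is
half-open `[start, start + size)`; windows with fewer than `min_snps`
(default 3) SNPs are reported unestimated.

The simplex-constrained least-squares problem is solved with SLSQP from
a uniform start; the objective is convex so the solver reaches the
global optimum, and tests compare against a dense grid-search oracle
over the simplex. Founders with identical genotypes across a window are
unidentifiable: they are fitted as one group, the group frequency is
split equally among members, and the estimate carries a degeneracy flag.
If all founders coincide the window is unestimated.

D is computed on haplotype frequencies (per founder, then averaged over
founders), since the analysis is about ancestral haplotypes rising; the
quantity "window mean D × 100" is the percent-divergence scale. Peak
calling replaces visual QQ inspection with a reproducible rule: windows
at or above the empirical `quantile` (default 0.999) of genome-wide mean
D are flagged and adjacent flagged windows merge into peaks; a
theoretical-normal vs empirical quantile table is emitted for
inspection. D is descriptive; no significance test is attached.

Numerical notes: observed frequencies are clipped to [0, 1] within a
1e-9 tolerance; estimated simplexes are renormalized after clipping
negatives ≥ −1e-12; a constant-D genome flags nothing. At the default
desk scale (~30 SNPs per window, coverage ~100) the per-founder
estimation noise in a young-vs-aged difference is ~0.03 in absolute
frequency, so D peaks from s = 0.5 selection stand above the floor but
short trailing windows (few SNPs) do not — hence the `min_snps`
condition matters for peak ranking.

## Paired differential expression (`poolage.expression`)

Gene filter: total counts ≥ 5 and zeros in ≤ 12 of the 24 samples.
Normalization is median-of-ratios over genes nonzero in all samples,
rescaled to geometric mean 1, with a total-count fallback (warned) when
no reference gene exists.

The per-gene NB2 GLM (log link; intercept, 11 pair contrasts, treatment)
is fitted by iteratively reweighted least squares batched across genes.
Dispersion is a Pearson moment estimate on a first-pass Poisson fit with
a degrees-of-freedom correction, floored at 1e-8 and then floored again
at the genome-wide median ("trend floor"): at 24 samples the raw
per-gene estimate is noisy, and underestimates directly inflate the Wald
statistic. The treatment effect is Wald-tested against a t reference
with residual degrees of freedom (n − p = 11) rather than a normal: with
13 coefficients estimated from 24 observations the normal reference was
measurably anti-conservative (null p < 0.05 fraction ≈ 0.095, realized
FDP ≈ 0.11 at q = 0.1), while the t reference gives approximately
uniform null p (KS ≈ 0.03) and controls FDR with ample power. No
separate batch correction is fitted: batch is constant within pair, so
the pair intercepts absorb any additive log-scale batch effect exactly
in the mean model. Full empirical-Bayes dispersion shrinkage and
shrunken fold-change estimators are out of scope; the moment-plus-floor
estimator is deliberately simple.

Percent changes are reported in both conventions — `(2^lfc − 1)·100`
(signed ratio change) and `(2^|lfc| − 1)·100` (fold magnitude, which can
exceed 100 % for strong reductions) — clearly labeled, with log2 fold
change primary.

A property worth knowing: multiplying both samples of one pair by a
constant is absorbed by the size factors and pair intercept *almost*
exactly — exactly in a Poisson model, and to ~0.01 log2 units in the NB
model for well-expressed genes, because the NB working weights
μ/(1 + αμ) are not scale-invariant at small μ. DE calls are unchanged.

Non-convergent genes (non-finite or unbounded estimates) are flagged,
get missing p, and are excluded from the BH adjustment, which uses the
standard step-up with monotonicity enforcement (via statsmodels).

## Integration (`poolage.integrate`)

Distance from a variant to a gene is the gap to the nearest span edge,
strand-ignorant, 0 inside the gene; a variant near two DE genes counts
for both, and tally rows appear only for DE genes with ≥ 1 significant
variant within the largest threshold (10 kb). The 10-kb breakdown
buckets SNPs as nonsynonymous / synonymous / other ("intergenic", which
includes flanking-region labels) and all non-SNPs as indels, so the
breakdown always sums to the 10-kb count.

Annotation regrouping pools any category with candidate count ≤ 1 into
"other" in both the candidate and genome columns before testing. The
simulated Fisher test samples the fixed-margin null (multivariate
hypergeometric), computes each table's null probability, and reports the
add-one estimator p = (1 + #{P(sim) ≤ P(obs)}) / (n_sim + 1) with its
Monte-Carlo standard error; ties are resolved with a 1e-9 log-scale
tolerance. The estimator cannot go below 1/(n_sim + 1), and for tables
whose exact p is of that order its hit counts are Poisson — the test
suite therefore checks agreement with exact enumeration by an exact
binomial consistency test plus the plain 3-SE band where the normal
approximation applies.

The DE-proximity permutation test formalizes the informal question "are
DE genes more likely to be near significant variants": the statistic is
the fraction of DE genes with ≥ 1 significant variant within 10 kb, the
null redraws equal-sized gene sets uniformly from all tested genes
(sampled exactly as a hypergeometric count of hit genes, which is the
same null), and the one-sided p uses the add-one convention, making it
valid (stochastically ≥ uniform) under label randomization.

## Pipeline, formats, determinism (`poolage.io`, `poolage.pipeline`)

Coordinates are 1-based inclusive internally (VCF/GFF convention); BED
output converts to 0-based half-open. Pooled counts are written as
minimal VCF with per-sample `AD:DP` (AD in the spec's ref,alt form; the
alternate component is the pooled alternate depth) and an `ANN` INFO
field carrying the annotation category; gene models as GFF3; matrices
and results as TSV whose comment headers carry the tool version, a
SHA-256 configuration hash and the root seed. Multi-allelic records and
records violating AD ≤ DP are rejected at read time with logged counts.

All randomness flows from one root seed through per-stage
`SeedSequence` children, so `run_pipeline` with a fixed configuration is
byte-identical across reruns. The default synthetic scale — 90,000
sites (~5,300 segregating) over three 300-kb chromosomes, 500
individuals per replicate pool, 450 genes — was chosen so a full run
completes in well under a minute while keeping ≥ ~30 SNPs per window,
the density at which founder-frequency recovery error stays below 0.05.

## Known limitations

- Haploid mosaics; no diploid dosage or heterozygosity.
- Independent-read model; no effective-pool-size correction in the CMH
  test.
- Moment dispersion with a trend floor, not empirical-Bayes shrinkage;
  slightly conservative FDR as a consequence.
- Annotation categories are probabilistic labels, not sequence-derived;
  category-enrichment results on synthetic data validate the machinery,
  not any biological claim.
- The ">6 % divergence" reading of window mean D × 100 is exposed
  without asserting equivalence to other percent-divergence definitions.
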