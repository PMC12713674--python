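"""End-to-end orchestration: simulate -> filter -> CMH -> haplotypes -> DE -> integrate.

``simulate_study`` draws a complete synthetic study (founder panel,
recombinant cohorts under age-associated selection, pooled reads, gene
models, paired expression counts) from one root seed; ``run_pipeline``
executes every analysis stage on it, writes all stage outputs under an
output directory, and returns a machine-readable summary.  All
randomness flows from the root seed through per-stage child seeds, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import expression, haplotypes, integrate, sim
from .io import (
    RunConfig,
    write_bed,
    write_counts_tsv,
    write_founder_panel,
    write_gff3,
    write_sample_sheet,
    write_table,
    write_vcf,
)
from .variants import PoolCounts, extract_candidates, filter_variants, differentiation_test

logger = logging.getLogger("poolage")

__all__ = ["StudyData", "simulate_study", "run_pipeline"]

STAGE_NAMES = ("simulate", "variants", "haplotypes", "expression", "integrate")


@dataclass
class StudyData:
    """One synthetic study: inputs for every analysis stage plus ground truth."""

    panel: sim.FounderPanel
    genes: pd.DataFrame
    pool: PoolCounts
    expr_counts: pd.DataFrame
    expr_samples: pd.DataFrame
    truth: sim.SimTruth


def _stage_seeds(seed: int) -> dict[str, int]:
    """Derive one independent child seed per stage from the root seed."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGE_NAMES))
    return {
        name: int(child.generate_state(1)[0] % (2**31 - 1))
        for name, child in zip(STAGE_NAMES, children)
    }


def _pick_causal_sites(
    panel: sim.FounderPanel, n_causal: int, s: float, rng: np.random.Generator
) -> tuple[list[tuple[int, float]], list[str]]:
    """One selected site per chromosome, each favoring a different founder.

    Sites are chosen near the chromosome midpoint among polymorphic
    sites where exactly one founder carries the alternate allele, so the
    allele's rise is a single ancestral haplotype rising to prominence.
    """
    causal: list[tuple[int, float]] = []
    favored: list[str] = []
    chroms = list(pd.unique(panel.chrom))[:n_causal]
    founders = rng.permutation(panel.n_founders)[: len(chroms)]
    for c, fav in zip(chroms, founders):
        cols = np.flatnonzero(panel.chrom == c)
        g = panel.G[:, cols]
        singleton = (g.sum(axis=0) == 1) & (g[fav] == 1)
        cand = cols[singleton]
        if cand.size == 0:
            cand = cols[(g != g[0]).any(axis=0)]
        mid = np.median(panel.pos[cols])
        idx = int(cand[np.argmin(np.abs(panel.pos[cand] - mid))])
        causal.append((idx, s))
        favored.append(panel.founder_ids[fav])
    return causal, favored


def simulate_study(config: RunConfig) -> StudyData:
    """Draw a complete synthetic study from the configuration's seed."""
    seeds = _stage_seeds(config.seed)
    rng = np.random.default_rng(seeds["simulate"])

    panel_full = sim.simulate_founders(
        config.n_founders,
        config.n_sites,
        config.divergence,
        seed=int(rng.integers(2**31 - 1)),
        n_chroms=config.n_chroms,
        spacing=config.site_spacing,
    )
    panel = panel_full.subset(panel_full.polymorphic())
    causal, favored = _pick_causal_sites(panel, config.n_causal, config.selection_s, rng)

    n_var = panel.n_sites
    n_pairs = config.n_pairs
    is_indel = rng.random(n_var) < config.indel_fraction
    ad = np.zeros((n_var, 2 * n_pairs), dtype=np.int64)
    dp = np.zeros_like(ad)
    samples = []
    col = 0
    for p in range(1, n_pairs + 1):
        H = sim.simulate_individuals(
            panel,
            config.n_individuals,
            config.crossovers_per_chrom,
            seed=int(rng.integers(2**31 - 1)),
        )
        aged_w = sim.selection_weights(panel, H, causal)
        for cohort, w in (("young", None), ("aged", aged_w)):
            freqs = sim.pool_freqs_from_individuals(panel, H, w)
            a, d = sim.simulate_pool_reads(
                freqs,
                config.coverage,
                seed=int(rng.integers(2**31 - 1)),
                depth_dispersion=config.depth_dispersion,
            )
            ad[:, col] = a
            dp[:, col] = d
            samples.append(
                {"sample": f"R{p:02d}_{cohort}", "pair": p, "cohort": cohort}
            )
            col += 1

    variants = pd.DataFrame(
        {
            "chrom": panel.chrom,
            "pos": panel.pos,
            "ref": "A",
            "alt": np.where(is_indel, "AT", "G"),
            "variant_class": np.where(is_indel, "indel", "SNP"),
        }
    )
    chrom_lengths = {
        c: int(panel_full.pos[panel_full.chrom == c].max())
        for c in pd.unique(panel_full.chrom)
    }
    genes = sim.simulate_gene_models(
        chrom_lengths,
        config.gene_spacing,
        config.gene_length,
        seed=int(rng.integers(2**31 - 1)),
    )
    variants["annotation"] = sim.assign_annotations(
        variants, genes, seed=int(rng.integers(2**31 - 1))
    )
    pool = PoolCounts(variants, ad, dp, pd.DataFrame(samples))
    pool.validate()

    n_genes = len(genes)
    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False)
    n_up = int(round(config.de_up_fraction * n_de))
    de_effects = [
        (int(g), config.de_lfc_up if k < n_up else config.de_lfc_down)
        for k, g in enumerate(de_idx)
    ]
    expr_counts, expr_samples, expr_truth = sim.simulate_expression(
        n_genes,
        n_pairs=n_pairs,
        de_genes=de_effects,
        pair_sd=config.pair_sd,
        batch_shift=config.batch_shift,
        dispersion=config.expr_dispersion,
        seed=int(rng.integers(2**31 - 1)),
        gene_ids=list(genes["gene_id"]),
    )

    truth = sim.SimTruth(
        seed=config.seed,
        causal_sites=[
            (str(panel.chrom[i]), int(panel.pos[i]), s) for i, s in causal
        ],
        favored_founders=favored,
        de_genes=expr_truth.de_genes,
        dispersion=config.expr_dispersion,
    )
    return StudyData(panel, genes, pool, expr_counts, expr_samples, truth)


def run_pipeline(config: RunConfig, out_dir: str | Path, study: StudyData | None = None) -> dict:
    """Run every stage end-to-end and write all outputs under ``out_dir``.

    Returns the summary dictionary, which is also written as
    ``summary.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)

    logger.info("stage simulate: drawing synthetic study (seed=%d)", config.seed)
    try:
        if study is None:
            study = simulate_study(config)
        config.to_yaml(out / "config.yaml")
        write_vcf(study.pool, out / "pool_counts.vcf")
        write_founder_panel(study.panel, out / "founder_panel.tsv")
        write_sample_sheet(study.pool.samples, out / "dna_samples.tsv")
        write_gff3(study.genes, out / "genes.gff3")
        write_counts_tsv(study.expr_counts, out / "expr_counts.tsv", config)
        write_sample_sheet(study.expr_samples, out / "rna_samples.tsv")
        truth_df = pd.DataFrame(
            study.truth.causal_sites, columns=["chrom", "pos", "s"]
        )
        truth_df["favored_founder"] = study.truth.favored_founders
        write_table(truth_df, out / "truth_causal.tsv", config)
        write_table(
            pd.DataFrame(study.truth.de_genes, columns=["gene_id", "true_log2fc"]),
            out / "truth_de.tsv",
            config,
        )
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"stage 'simulate' failed: {e}") from e

    logger.info("stage variants: filtering and CMH testing")
    try:
        filtered = filter_variants(
            study.pool, config.min_cov, config.max_cov, config.min_maf
        )
        results = differentiation_test(
            filtered, alpha=config.alpha, joint_threshold=config.joint_threshold
        )
        candidates, significant, genes_hit = extract_candidates(results, study.genes)
        write_table(results, out / "cmh_results.tsv", config)
        write_table(candidates, out / "candidate_variants.tsv", config)
    except Exception as e:
        raise RuntimeError(f"stage 'variants' failed: {e}") from e

    logger.info("stage haplotypes: window estimation and D statistic")
    try:
        snp_mask = (filtered.variants["variant_class"] == "SNP").to_numpy()
        snps = filtered.subset(snp_mask)
        # map the retained SNPs back onto founder-panel columns by coordinate
        panel_key = pd.MultiIndex.from_arrays([study.panel.chrom, study.panel.pos])
        snp_key = pd.MultiIndex.from_frame(snps.variants[["chrom", "pos"]])
        panel_cols = panel_key.get_indexer(snp_key)
        if (panel_cols < 0).any():
            raise ValueError("filtered SNPs missing from the founder panel")
        windows = haplotypes.window_snps(
            snps.variants["chrom"].to_numpy(),
            snps.variants["pos"].to_numpy(),
            config.window_size,
            config.window_step,
            config.min_snps,
        )
        with np.errstate(invalid="ignore"):
            freqs = np.where(snps.dp > 0, snps.ad / np.maximum(snps.dp, 1), 0.0)
        G_snp = study.panel.G[:, panel_cols]
        estimates = haplotypes.estimate_windows(G_snp, windows, freqs, config.min_snps)
        d_table = haplotypes.window_d_table(
            windows, estimates, snps.samples, study.panel.founder_ids
        )
        flagged, peaks, qq = haplotypes.flag_divergent_windows(
            d_table, config.peak_quantile
        )
        write_table(flagged.drop(columns=[], errors="ignore"), out / "window_d.tsv", config)
        write_table(peaks, out / "peaks.tsv", config)
        if len(peaks):
            write_bed(peaks, out / "peaks.bed", name_col=None)
        write_table(qq, out / "d_quantiles.tsv", config)
    except Exception as e:
        raise RuntimeError(f"stage 'haplotypes' failed: {e}") from e

    logger.info("stage expression: paired NB differential expression")
    try:
        kept = expression.filter_genes(
            study.expr_counts, config.min_gene_total, config.max_zero_samples
        )
        de_res = expression.fit_paired_nb(kept, study.expr_samples, q=config.de_q)
        write_table(de_res.reset_index(), out / "de_results.tsv", config)
        de_gene_ids = list(de_res.index[de_res["de"]])
        n_up = int((de_res["de"] & (de_res["direction"] > 0)).sum())
        n_down = int((de_res["de"] & (de_res["direction"] < 0)).sum())
    except Exception as e:
        raise RuntimeError(f"stage 'expression' failed: {e}") from e

    logger.info("stage integrate: proximity, annotation categories, enrichment")
    try:
        de_models = study.genes[study.genes["gene_id"].isin(de_gene_ids)]
        sig_variants = results[results["significant"]]
        if len(de_models):
            tally = integrate.proximity_scan(
                sig_variants, de_models, config.proximity_thresholds
            )
            if len(tally):
                totals = integrate.tally_totals(tally)
                tally_out = pd.concat(
                    [tally, totals.to_frame().T], ignore_index=True
                )
            else:
                tally_out = tally
            write_table(tally_out, out / "proximity_tally.tsv", config)
        else:
            tally = pd.DataFrame(columns=integrate.TALLY_COLUMNS)

        sig_snps = sig_variants[sig_variants["variant_class"] == "SNP"]
        all_snps = results[results["variant_class"] == "SNP"]
        fisher_p, fisher_se = np.nan, np.nan
        if len(sig_snps) >= 2:
            cat = integrate.regroup_annotations(
                sig_snps["annotation"], all_snps["annotation"]
            )
            if len(cat) > 1:
                fisher_p, fisher_se = integrate.fisher_simulated(
                    cat, config.n_sim, seed=seeds["integrate"]
                )
            write_table(cat.reset_index(), out / "annotation_categories.tsv", config)

        tested_genes = study.genes[study.genes["gene_id"].isin(kept.index)]
        enrich = None
        if de_gene_ids and len(tested_genes):
            enrich = integrate.de_proximity_enrichment(
                [g for g in de_gene_ids if g in set(tested_genes["gene_id"])],
                tested_genes,
                sig_variants,
                threshold=config.proximity_thresholds[0],
                n_perm=config.n_perm,
                seed=seeds["integrate"] + 1,
            )
            write_table(pd.DataFrame([enrich]), out / "de_proximity_enrichment.tsv", config)
        shared = integrate.overlap_genes(genes_hit, de_gene_ids)
        write_table(shared, out / "overlap_genes.tsv", config)
    except Exception as e:
        raise RuntimeError(f"stage 'integrate' failed: {e}") from e

    summary = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_variants_simulated": int(study.pool.n_variants),
        "n_variants_filtered": int(filtered.n_variants),
        "n_snps_tested": int((results["variant_class"] == "SNP").sum()),
        "n_indels_tested": int((results["variant_class"] == "indel").sum()),
        "n_significant_snps": int(
            (results["significant"] & (results["variant_class"] == "SNP")).sum()
        ),
        "n_significant_indels": int(
            (results["significant"] & (results["variant_class"] == "indel")).sum()
        ),
        "n_candidate_variants": int(len(candidates)),
        "n_candidate_genes": int(len(genes_hit)),
        "n_windows": int(len(windows)),
        "n_peaks": int(len(peaks)),
        "top_peak": (
            {
                "chrom": str(peaks.iloc[0]["chrom"]),
                "start": int(peaks.iloc[0]["start"]),
                "end": int(peaks.iloc[0]["end"]),
                "max_D": float(peaks.iloc[0]["max_D"]),
            }
            if len(peaks)
            else None
        ),
        "n_genes_tested": int(len(kept)),
        "n_de_genes": int(len(de_gene_ids)),
        "n_de_up": n_up,
        "n_de_down": n_down,
        "n_de_genes_with_local_variant": int(len(tally)),
        "fisher_p": None if np.isnan(fisher_p) else float(fisher_p),
        "de_proximity_observed_fraction": (
            None if enrich is None else enrich["observed_fraction"]
        ),
        "de_proximity_p": None if enrich is None else enrich["p_value"],
        "n_overlap_genes": int(len(shared)),
        "overlap_genes": list(shared["gene_id"]),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
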