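"""Shared fixtures: small synthetic inputs with known structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from poolage import sim
from poolage.variants import PoolCounts

# The published tally of significant variants near differentially
# expressed genes: per-gene counts of variants within the transcript and
# within 10 kb, with the 10-kb set broken down by variant type.
TABLE1_ROWS = [
    # gene, within_gene, within_10kb, nonsyn, syn, intergenic, indels
    ("AHP1", 0, 10, 6, 0, 0, 4),
    ("CCW12", 0, 10, 6, 0, 0, 4),
    ("DIA4", 0, 3, 0, 0, 3, 0),
    ("DNM1", 0, 1, 0, 0, 1, 0),
    ("EKI1", 0, 2, 0, 1, 0, 1),
    ("FIT2", 0, 14, 4, 3, 6, 1),
    ("MRP1", 0, 1, 0, 1, 0, 0),
    ("RFA3", 4, 39, 10, 17, 12, 0),
    ("SPG5", 0, 1, 0, 0, 1, 0),
    ("TOS2", 0, 1, 0, 0, 1, 0),
    ("WSC4", 2, 14, 4, 10, 0, 0),
    ("YDR543C", 0, 1, 0, 0, 1, 0),
    ("YJL218W", 0, 26, 7, 18, 1, 0),
    ("YNR066C", 0, 1, 0, 1, 0, 0),
]
# within-transcript variants: RFA3 carries 2 nonsynonymous + 2 synonymous,
# WSC4 carries 2 synonymous
TABLE1_INSIDE = {"RFA3": [("SNP", sim.ANN_NONSYN)] * 2 + [("SNP", sim.ANN_SYN)] * 2,
                 "WSC4": [("SNP", sim.ANN_SYN)] * 2}


def build_table1_fixture() -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Construct gene models and variant positions reproducing the tally.

    Genes are spaced 40 kb apart on one chromosome so no variant can
    count toward two genes; variants not inside the transcript are
    placed 1.2-9 kb beyond the gene end.
    """
    genes, variants = [], []
    for i, (gene, inside, in10, nonsyn, syn, inter, indel) in enumerate(TABLE1_ROWS):
        start = 50_000 + i * 40_000
        end = start + 999
        genes.append(
            {"gene_id": gene, "chrom": "chrI", "start": start, "end": end,
             "strand": "+", "coding": True}
        )
        placed = {"SNP_nonsyn": 0, "SNP_syn": 0, "SNP_inter": 0, "indel": 0}
        for k, (vc, ann) in enumerate(TABLE1_INSIDE.get(gene, [])):
            variants.append(
                {"chrom": "chrI", "pos": start + 10 + k, "variant_class": vc,
                 "annotation": ann}
            )
            key = "SNP_nonsyn" if ann == sim.ANN_NONSYN else "SNP_syn"
            placed[key] += 1
        outside = [
            ("SNP", sim.ANN_NONSYN, nonsyn - placed["SNP_nonsyn"]),
            ("SNP", sim.ANN_SYN, syn - placed["SNP_syn"]),
            ("SNP", sim.ANN_INTERGENIC, inter),
            ("indel", sim.ANN_INTERGENIC, indel),
        ]
        offset = 1200
        for vc, ann, n in outside:
            for _ in range(n):
                variants.append(
                    {"chrom": "chrI", "pos": end + offset, "variant_class": vc,
                     "annotation": ann}
                )
                offset += 37
    expected = pd.DataFrame(
        TABLE1_ROWS,
        columns=["gene_id", "within_gene", "within_10kb", "nonsynonymous_snps",
                 "synonymous_snps", "intergenic_snps", "indels"],
    )
    return pd.DataFrame(variants), pd.DataFrame(genes), expected


@pytest.fixture(scope="session")
def table1_fixture():
    return build_table1_fixture()


def make_null_pool(
    n_var: int = 200,
    n_pairs: int = 12,
    coverage: float = 100.0,
    seed: int = 0,
    freq_range: tuple[float, float] = (0.1, 0.9),
) -> PoolCounts:
    """Pooled counts with no young/aged differentiation (read noise only)."""
    rng = np.random.default_rng(seed)
    f = rng.uniform(*freq_range, size=(n_var, 1))
    ad = np.zeros((n_var, 2 * n_pairs), dtype=np.int64)
    dp = np.zeros_like(ad)
    samples = []
    for p in range(n_pairs):
        a, d = sim.simulate_pool_reads(
            np.repeat(f, 2, axis=1), coverage, seed=int(rng.integers(2**31 - 1))
        )
        ad[:, 2 * p : 2 * p + 2] = a
        dp[:, 2 * p : 2 * p + 2] = d
        samples.append({"sample": f"R{p + 1:02d}_young", "pair": p + 1, "cohort": "young"})
        samples.append({"sample": f"R{p + 1:02d}_aged", "pair": p + 1, "cohort": "aged"})
    variants = pd.DataFrame(
        {
            "chrom": "chr1",
            "pos": np.arange(1, n_var + 1) * 100,
            "ref": "A",
            "alt": "G",
            "variant_class": "SNP",
        }
    )
    return PoolCounts(variants, ad, dp, pd.DataFrame(samples))


@pytest.fixture
def small_panel() -> sim.FounderPanel:
    return sim.simulate_founders(4, 2000, 0.2, seed=11, n_chroms=2, spacing=20)
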