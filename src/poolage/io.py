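"""Readers, writers and run configuration.

Formats are deliberately minimal but standard: VCF with per-sample AD:DP
for pooled counts (AD follows the VCF convention of one depth per
allele, ref first), GFF3 for gene models, and TSV for matrices and
result tables.  Coordinates are 1-based inclusive everywhere except BED
output, which is 0-based half-open.  Result files carry a comment header
with the tool version, the configuration hash and the root seed, so a
run is identifiable from any of its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from . import __version__
from .variants import PoolCounts

logger = logging.getLogger("poolage")

__all__ = [
    "RunConfig",
    "write_vcf",
    "read_pool_counts",
    "write_gff3",
    "read_gff3",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_table",
    "read_table",
    "write_bed",
    "write_founder_panel",
    "read_founder_panel",
]


@dataclass
class RunConfig:
    """Every knob of an end-to-end run, serializable to YAML."""

    seed: int = 1
    # synthetic study
    n_founders: int = 4
    n_chroms: int = 3
    n_sites: int = 90_000
    site_spacing: int = 10
    divergence: float = 0.06
    n_individuals: int = 500
    crossovers_per_chrom: float = 12.0
    n_pairs: int = 12
    coverage: float = 117.0
    depth_dispersion: float = 0.15
    indel_fraction: float = 0.07
    selection_s: float = 0.5
    n_causal: int = 3
    gene_spacing: int = 2000
    gene_length: int = 1200
    de_fraction: float = 0.05
    de_up_fraction: float = 0.3
    de_lfc_up: float = 0.5
    de_lfc_down: float = -0.8
    pair_sd: float = 0.3
    batch_shift: float = 0.2
    expr_dispersion: float = 0.05
    # variant filters and testing
    min_cov: int = 20
    max_cov: int = 1000
    min_maf: float = 0.05
    alpha: float = 0.05
    joint_threshold: bool = False
    # haplotype windows
    window_size: int = 5000
    window_step: int = 2000
    min_snps: int = 3
    peak_quantile: float = 0.999
    # differential expression
    de_q: float = 0.1
    min_gene_total: int = 5
    max_zero_samples: int = 12
    # integration
    proximity_thresholds: tuple[int, int, int] = (10_000, 5_000, 1_000)
    n_sim: int = 100_000
    n_perm: int = 10_000

    def __post_init__(self) -> None:
        if not 0 < self.de_q < 1:
            raise ValueError("de_q must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("min_cov", "max_cov", "window_size", "window_step", "min_snps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proximity_thresholds"] = list(self.proximity_thresholds)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "proximity_thresholds" in d:
            d["proximity_thresholds"] = tuple(d["proximity_thresholds"])
        return cls(**d)

    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]


def _result_header(config: RunConfig | None) -> list[str]:
    lines = [f"#poolage {__version__}"]
    if config is not None:
        lines.append(f"#config_hash={config.config_hash()}")
        lines.append(f"#seed={config.seed}")
    return lines


def write_table(
    df: pd.DataFrame, path: str | Path, config: RunConfig | None = None, index: bool = False
) -> None:
    """Write a result table as TSV with the provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in _result_header(config):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path: str | Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_counts_tsv(
    counts: pd.DataFrame, path: str | Path, config: RunConfig | None = None
) -> None:
    write_table(counts, path, config, index=True)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    return read_table(path, index_col=0)


def write_sample_sheet(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_founder_panel(panel, path: str | Path) -> None:
    """Write a founder genotype panel as TSV: chrom, pos, one 0/1 column per founder."""
    df = pd.DataFrame({"chrom": panel.chrom, "pos": panel.pos})
    for i, fid in enumerate(panel.founder_ids):
        df[fid] = panel.G[i]
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_founder_panel(path: str | Path):
    from .sim import FounderPanel

    df = pd.read_csv(path, sep="\t", comment="#")
    founder_ids = [c for c in df.columns if c not in ("chrom", "pos")]
    panel = FounderPanel(
        founder_ids,
        df["chrom"].to_numpy(dtype=object),
        df["pos"].to_numpy(dtype=np.int64),
        df[founder_ids].to_numpy(dtype=np.int8).T,
    )
    panel.validate()
    return panel


# ---------------------------------------------------------------- VCF


def write_vcf(pool: PoolCounts, path: str | Path) -> None:
    """Write pooled counts as a minimal uncompressed VCF with AD:DP genotypes.

    AD is written per the VCF spec as ref,alt depths; DP is the total
    depth.  Contig lengths are padded beyond the last variant.
    """
    pool.validate()
    path = Path(path)
    sample_names = list(pool.samples["sample"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=poolage {__version__}\n")
        chroms = pd.unique(pool.variants["chrom"])
        for c in chroms:
            length = int(pool.variants.loc[pool.variants["chrom"] == c, "pos"].max()) + 10_000
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write(
            '##INFO=<ID=ANN,Number=1,Type=String,'
            'Description="Functional annotation category">\n'
        )
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,'
            'Description="Allelic depths for the ref and alt alleles">\n'
        )
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_names)
            + "\n"
        )
        has_ann = "annotation" in pool.variants.columns
        for i, v in enumerate(pool.variants.itertuples(index=False)):
            info = f"ANN={v.annotation}" if has_ann else "."
            cells = [
                str(v.chrom),
                str(int(v.pos)),
                ".",
                str(v.ref),
                str(v.alt),
                ".",
                "PASS",
                info,
                "AD:DP",
            ]
            for s in range(len(sample_names)):
                dp = int(pool.dp[i, s])
                ad = int(pool.ad[i, s])
                cells.append(f"{dp - ad},{ad}:{dp}")
            fh.write("\t".join(cells) + "\n")


def read_pool_counts(
    path: str | Path, sample_sheet: pd.DataFrame | str | Path
) -> PoolCounts:
    """Read a VCF with per-sample AD/DP into a :class:`PoolCounts` table.

    Multi-allelic records, records missing AD or DP, and records with
    AD > DP are rejected; rejection counts are logged.  Every sample in
    the VCF must appear in the sample sheet.
    """
    if not isinstance(sample_sheet, pd.DataFrame):
        sample_sheet = read_sample_sheet(sample_sheet)
    vf = pysam.VariantFile(str(path))
    vcf_samples = list(vf.header.samples)
    sheet_samples = set(sample_sheet["sample"])
    for s in vcf_samples:
        if s not in sheet_samples:
            raise ValueError(f"sample {s!r} in VCF is absent from the sample sheet")
    sheet = (
        sample_sheet.set_index("sample").loc[vcf_samples].reset_index()
    )  # order follows the VCF

    rows, ads, dps = [], [], []
    rejected = {"multiallelic": 0, "missing_fields": 0, "ad_gt_dp": 0}
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            rejected["multiallelic"] += 1
            continue
        ad_row, dp_row, bad = [], [], None
        for s in vcf_samples:
            fmt = rec.samples[s]
            ad = fmt.get("AD")
            dp = fmt.get("DP")
            if ad is None or dp is None or len(ad) != 2 or ad[1] is None:
                bad = "missing_fields"
                break
            if ad[1] > dp:
                bad = "ad_gt_dp"
                break
            ad_row.append(int(ad[1]))
            dp_row.append(int(dp))
        if bad:
            rejected[bad] += 1
            continue
        ref, alt = rec.ref, rec.alts[0]
        row = {
            "chrom": rec.chrom,
            "pos": rec.pos,
            "ref": ref,
            "alt": alt,
            "variant_class": "SNP" if len(ref) == 1 and len(alt) == 1 else "indel",
        }
        ann = rec.info.get("ANN")
        if ann is not None:
            row["annotation"] = ann
        rows.append(row)
        ads.append(ad_row)
        dps.append(dp_row)
    n_rej = sum(rejected.values())
    if n_rej:
        logger.warning("rejected %d VCF records: %s", n_rej, rejected)
    cols = ["chrom", "pos", "ref", "alt", "variant_class"]
    if rows and "annotation" in rows[0]:
        cols.append("annotation")
    pool = PoolCounts(
        pd.DataFrame(rows, columns=cols),
        np.asarray(ads, dtype=np.int64).reshape(len(rows), len(vcf_samples)),
        np.asarray(dps, dtype=np.int64).reshape(len(rows), len(vcf_samples)),
        sheet,
    )
    pool.validate()
    return pool


# --------------------------------------------------------------- GFF3


def write_gff3(genes: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes.itertuples(index=False):
            coding = getattr(g, "coding", True)
            attrs = f"ID={g.gene_id};coding={'true' if coding else 'false'}"
            fh.write(
                f"{g.chrom}\tpoolage\tgene\t{int(g.start)}\t{int(g.end)}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path) -> pd.DataFrame:
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9 or f[2] != "gene":
            continue
        attrs = dict(
            kv.split("=", 1) for kv in f[8].split(";") if "=" in kv
        )
        rows.append(
            {
                "gene_id": attrs.get("ID", f"{f[0]}:{f[3]}"),
                "chrom": f[0],
                "start": int(f[3]),
                "end": int(f[4]),
                "strand": f[6],
                "coding": attrs.get("coding", "true") == "true",
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand", "coding"])


def write_bed(intervals: pd.DataFrame, path: str | Path, name_col: str | None = None) -> None:
    """Write 1-based inclusive intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for row in intervals.itertuples(index=False):
            name = getattr(row, name_col) if name_col else "."
            fh.write(f"{row.chrom}\t{int(row.start) - 1}\t{int(row.end)}\t{name}\n")
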