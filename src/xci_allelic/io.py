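"""Readers and writers for the pipeline's on-disk TSV dialects.

All tables are plain tab-separated text with a header line.  Pileups use
1-based genomic coordinates (samtools convention); gene models are BED-like,
0-based half-open.  Coordinate conversion happens in one place only
(:func:`xci_allelic.snp_discovery.annotate_and_filter`).
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError

BASES = ("A", "C", "G", "T")
QUAL_COLS = ("qA", "qC", "qG", "qT")

PILEUP_COLUMNS = ["chrom", "pos", "ref"] + list(BASES) + list(QUAL_COLS)
GENE_COLUMNS = ["chrom", "start", "end", "gene_id", "score", "strand"]
SNP_COLUMNS = [
    "chrom", "pos", "allele_cloneA", "allele_cloneB",
    "depth_A", "depth_B", "qual_A", "qual_B", "gene_id", "strategy",
]
PHASED_COLUMNS = ["chrom", "pos", "gene_id", "xa_allele_refclone", "xi_allele_refclone"]
SUMMARY_COLUMNS = [
    "gene_id", "sample_id", "clone", "timepoint", "replicate",
    "xa_reads", "xi_reads", "total_reads", "xi_qualsum", "xi_pct",
]
MANIFEST_COLUMNS = ["sample_id", "clone", "timepoint", "replicate", "pileup"]


def validate_pileup(df: pd.DataFrame) -> pd.DataFrame:
    """Check pileup invariants; raise :class:`InputError` on violation."""
    missing = [c for c in PILEUP_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"pileup missing columns: {missing}")
    if (df["pos"] < 1).any():
        raise InputError("pileup positions must be 1-based (pos >= 1)")
    counts = df[list(BASES)].to_numpy()
    quals = df[list(QUAL_COLS)].to_numpy()
    if (counts < 0).any() or (quals < 0).any():
        raise InputError("pileup counts and quality sums must be non-negative")
    if ((counts == 0) & (quals != 0)).any():
        raise InputError("qualsum must be 0 wherever the base count is 0")
    if df.duplicated(subset=["chrom", "pos"]).any():
        raise InputError("duplicate (chrom, pos) in pileup")
    return df


def read_pileup(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return validate_pileup(df)


def write_pileup(df: pd.DataFrame, path) -> None:
    validate_pileup(df)
    df.to_csv(path, sep="\t", index=False, columns=PILEUP_COLUMNS)


def read_gene_models(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", names=GENE_COLUMNS, dtype={"chrom": str}, comment="#")
    if (df["start"] >= df["end"]).any():
        raise InputError("gene model intervals must satisfy start < end")
    return df


def write_gene_models(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, header=False, columns=GENE_COLUMNS)


def read_snps(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})


def write_snps(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=SNP_COLUMNS)


def read_phased(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})


def write_phased(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=PHASED_COLUMNS)


def read_summaries(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str, "clone": str, "timepoint": str})


def write_summaries(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "clone": str, "timepoint": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"manifest missing columns: {missing}")
    if df.duplicated(subset=["clone", "timepoint", "replicate"]).any():
        raise InputError("manifest (clone, timepoint, replicate) must be unique")
    return df


def read_species_flags(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("maps_to_human", "maps_to_mouse"):
        if col not in df.columns:
            raise InputError(f"species flag table missing column {col}")
        df[col] = df[col].astype(bool)
    return df
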