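"""Phasing and allele-specific read counting.

The reciprocal-clone design gives phasing for free: at each heterozygous SNP
the allele with the higher read depth in the reference clone sits on that
clone's active X (Xa) and, by reciprocity, on the inactive X (Xi) of the
other clone.  Phasing is established once, on the pre-fusion pileup of the
reference clone, and reused for every sample of the time course.

Counts are then aggregated per gene: reads supporting the Xa or Xi allele at
any SNP of a gene are summed, together with the phred qualities of the
Xi-supporting reads (the mixture model consumes that quality sum to anchor
its error rate).  Reads carrying a third or fourth base are sequencing error
and are ignored, so total = Xa + Xi.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import InputError
from .io import BASES, QUAL_COLS

logger = logging.getLogger(__name__)


def filter_species_reads(flags: pd.DataFrame) -> pd.DataFrame:
    """Keep reads that align to the human genome only.

    Heterokaryon RNA-seq contains human and mouse transcripts; reads mapping
    to both genomes are ambiguous and excluded.
    """
    human = flags["maps_to_human"].to_numpy(dtype=bool)
    mouse = flags["maps_to_mouse"].to_numpy(dtype=bool)
    if (~human & ~mouse).any():
        raise InputError("species flag table contains reads mapping to neither genome")
    return flags[human & ~mouse].reset_index(drop=True)


def phase_alleles(snps: pd.DataFrame, pileup_ref_clone: pd.DataFrame) -> pd.DataFrame:
    """Assign Xa/Xi alleles from the reference clone's read depths.

    For each candidate SNP, the allele with the higher count in the reference
    clone becomes its Xa allele (and the Xi allele of the reciprocal clone).
    Ties and SNPs missing from the pileup are excluded.
    """
    pile = pileup_ref_clone.set_index(["chrom", "pos"])
    rows = []
    n_missing = n_tie = 0
    for snp in snps.itertuples(index=False):
        key = (snp.chrom, snp.pos)
        try:
            rec = pile.loc[key]
        except KeyError:
            n_missing += 1
            continue
        a, b = snp.allele_cloneA, snp.allele_cloneB
        ca, cb = rec[a], rec[b]
        if ca == cb:
            n_tie += 1
            continue
        xa, xi = (a, b) if ca > cb else (b, a)
        rows.append((snp.chrom, snp.pos, snp.gene_id, xa, xi))
    if n_missing:
        logger.warning("phase_alleles: %d SNPs absent from reference pileup, excluded", n_missing)
    if n_tie:
        logger.warning("phase_alleles: %d SNPs with tied allele depths, excluded", n_tie)
    return pd.DataFrame(rows, columns=["chrom", "pos", "gene_id",
                                       "xa_allele_refclone", "xi_allele_refclone"])


def count_alleles_at_snp(record, xa_allele: str, xi_allele: str):
    """Counts of the two phased alleles at one pileup record.

    Returns (xa_count, xi_count, xi_qualsum); other bases are ignored.
    """
    xa = int(record[xa_allele])
    xi = int(record[xi_allele])
    xi_q = float(record["q" + xi_allele])
    return xa, xi, xi_q


def count_sample(pileup: pd.DataFrame, phased: pd.DataFrame, is_ref_clone: bool) -> pd.DataFrame:
    """Per-SNP allele counts for one sample.

    For the reciprocal clone the Xa/Xi labels are swapped relative to the
    phased table (anti-symmetry of the reciprocal design).  SNPs not covered
    in this sample get zero counts.
    """
    merged = phased.merge(pileup, on=["chrom", "pos"], how="left")
    counts = merged[list(BASES)].fillna(0.0).to_numpy(dtype=float)
    quals = merged[list(QUAL_COLS)].fillna(0.0).to_numpy(dtype=float)
    base_idx = {b: i for i, b in enumerate(BASES)}
    xa_col = "xa_allele_refclone" if is_ref_clone else "xi_allele_refclone"
    xi_col = "xi_allele_refclone" if is_ref_clone else "xa_allele_refclone"
    ia = np.array([base_idx[b] for b in merged[xa_col]])
    ii = np.array([base_idx[b] for b in merged[xi_col]])
    rows = np.arange(len(merged))
    return pd.DataFrame({
        "chrom": merged["chrom"],
        "pos": merged["pos"],
        "gene_id": merged["gene_id"],
        "xa_count": counts[rows, ia].astype(int),
        "xi_count": counts[rows, ii].astype(int),
        "xi_qualsum": quals[rows, ii],
    })


def aggregate_gene(snp_counts: pd.DataFrame) -> pd.DataFrame:
    """Sum per-SNP Xa/Xi counts and Xi quality sums within each gene."""
    if snp_counts.empty:
        return pd.DataFrame(columns=["gene_id", "xa_reads", "xi_reads",
                                     "total_reads", "xi_qualsum"])
    agg = (snp_counts.groupby("gene_id", as_index=False)
           .agg(xa_reads=("xa_count", "sum"),
                xi_reads=("xi_count", "sum"),
                xi_qualsum=("xi_qualsum", "sum")))
    agg["total_reads"] = agg["xa_reads"] + agg["xi_reads"]
    return agg[["gene_id", "xa_reads", "xi_reads", "total_reads", "xi_qualsum"]]


def merge_replicates(summaries: pd.DataFrame, sample_id: str = "merged") -> pd.DataFrame:
    """Merge biological replicates of one clone x timepoint by summing reads
    and quality sums per gene."""
    if summaries.empty:
        raise InputError("merge_replicates requires at least one summary")
    keys = ["gene_id"]
    for k in ("clone", "timepoint"):
        if k in summaries.columns and summaries[k].nunique() > 1:
            raise InputError(f"merge_replicates: mixed values in column {k!r}")
        if k in summaries.columns:
            keys.append(k)
    agg = (summaries.groupby(keys, as_index=False)
           .agg(xa_reads=("xa_reads", "sum"),
                xi_reads=("xi_reads", "sum"),
                xi_qualsum=("xi_qualsum", "sum")))
    agg["total_reads"] = agg["xa_reads"] + agg["xi_reads"]
    agg["sample_id"] = sample_id
    return agg


def xi_fraction(xa_reads, xi_reads):
    """Percentage of Xi-supporting reads, to one decimal; NaN when total=0."""
    xa = np.asarray(xa_reads, dtype=float)
    xi = np.asarray(xi_reads, dtype=float)
    total = xa + xi
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(total > 0, 100.0 * xi / total, np.nan)
    return np.round(pct, 1)


def quantify_samples(pileups: dict[str, pd.DataFrame], phased: pd.DataFrame,
                     meta: pd.DataFrame, ref_clone: str) -> pd.DataFrame:
    """Gene-level allelic summaries for every sample in ``meta``.

    ``meta`` must carry sample_id, clone, timepoint, replicate; ``pileups``
    maps sample_id to its pileup table.
    """
    out = []
    for s in meta.itertuples(index=False):
        counts = count_sample(pileups[s.sample_id], phased, s.clone == ref_clone)
        summary = aggregate_gene(counts)
        summary["sample_id"] = s.sample_id
        summary["clone"] = s.clone
        summary["timepoint"] = s.timepoint
        summary["replicate"] = s.replicate
        out.append(summary)
    df = pd.concat(out, ignore_index=True)
    df["xi_pct"] = xi_fraction(df["xa_reads"], df["xi_reads"])
    return df
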