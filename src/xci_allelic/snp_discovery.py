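"""Heterozygous SNP discovery from reciprocal-clone RNA-seq pileups.

Two single-cell-derived fibroblast clones from the same female donor carry
opposite X-inactivation patterns, so at a heterozygous site each clone
predominantly expresses a different allele.  Two complementary strategies
exploit this:

* **reciprocal** — call the most abundant base per position in each clone
  independently; positions where the top base differs between clones are
  putative heterozygous SNPs.  Works even when one allele is fully silenced.
* **merged** — pool the two clones (mimicking genomic DNA, since the clones
  express mirrored haplotypes) and call heterozygosity with a diploid
  genotype-likelihood model.

Both apply a minimum depth and a minimum phred-scaled call quality, taken as
the mean base quality of the reads supporting the called allele(s).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError
from .io import BASES, QUAL_COLS

NO_GENE = "."

DEFAULT_MIN_DEPTH = 8
DEFAULT_MIN_QUAL = 20.0


def call_top_base(record, min_depth: int = DEFAULT_MIN_DEPTH,
                  min_qual: float = DEFAULT_MIN_QUAL):
    """Call the most abundant base at one pileup record.

    Parameters
    ----------
    record : mapping with keys A, C, G, T and qA, qC, qG, qT
        Base counts and summed phred qualities at one position.

    Returns
    -------
    (base, depth, qual) or None
        ``None`` when the position is rejected: total depth below
        ``min_depth``, mean phred of the top base below ``min_qual``, or a
        tie for the most abundant base (undefined call, treated as noise).
    """
    counts = np.array([record[b] for b in BASES], dtype=float)
    if (counts < 0).any():
        raise InputError("negative base count in pileup record")
    depth = int(counts.sum())
    if depth < min_depth:
        return None
    order = np.argsort(counts)
    if counts[order[-1]] == counts[order[-2]]:
        return None  # tie: "most abundant base" undefined
    top = order[-1]
    qual = float(record[QUAL_COLS[top]]) / counts[top]
    if qual < min_qual:
        return None
    return BASES[top], depth, qual


def _top_base_table(pileup: pd.DataFrame, min_depth: int, min_qual: float) -> pd.DataFrame:
    """Vectorised call_top_base over a whole pileup; rejected rows dropped."""
    counts = pileup[list(BASES)].to_numpy(dtype=float)
    if (counts < 0).any():
        raise InputError("negative base count in pileup")
    quals = pileup[list(QUAL_COLS)].to_numpy(dtype=float)
    depth = counts.sum(axis=1)
    part = np.sort(counts, axis=1)
    tie = part[:, -1] == part[:, -2]
    top = counts.argmax(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        topqual = quals[np.arange(len(pileup)), top] / counts[np.arange(len(pileup)), top]
    keep = (depth >= min_depth) & ~tie & (topqual >= min_qual)
    out = pd.DataFrame({
        "chrom": pileup["chrom"].to_numpy()[keep],
        "pos": pileup["pos"].to_numpy()[keep],
        "base": np.array(BASES)[top[keep]],
        "depth": depth[keep].astype(int),
        "qual": topqual[keep],
    })
    return out


def find_het_snps_reciprocal(pileup_A: pd.DataFrame, pileup_B: pd.DataFrame,
                             min_depth: int = DEFAULT_MIN_DEPTH,
                             min_qual: float = DEFAULT_MIN_QUAL) -> pd.DataFrame:
    """Strategy "reciprocal": positions whose most abundant base differs
    between the two clones, both passing depth/quality filters."""
    ta = _top_base_table(pileup_A, min_depth, min_qual)
    tb = _top_base_table(pileup_B, min_depth, min_qual)
    merged = ta.merge(tb, on=["chrom", "pos"], suffixes=("_A", "_B"))
    het = merged[merged["base_A"] != merged["base_B"]]
    return pd.DataFrame({
        "chrom": het["chrom"].to_numpy(),
        "pos": het["pos"].to_numpy(),
        "allele_cloneA": het["base_A"].to_numpy(),
        "allele_cloneB": het["base_B"].to_numpy(),
        "depth_A": het["depth_A"].to_numpy(),
        "depth_B": het["depth_B"].to_numpy(),
        "qual_A": het["qual_A"].to_numpy(),
        "qual_B": het["qual_B"].to_numpy(),
        "gene_id": NO_GENE,
        "strategy": "reciprocal",
    })


def merge_pileups(pileup_A: pd.DataFrame, pileup_B: pd.DataFrame) -> pd.DataFrame:
    """Sum base counts and quality sums position-wise across two pileups."""
    cols = list(BASES) + list(QUAL_COLS)
    both = pd.concat([pileup_A, pileup_B], ignore_index=True)
    agg = {c: "sum" for c in cols}
    agg["ref"] = "first"
    merged = both.groupby(["chrom", "pos"], as_index=False, sort=True).agg(agg)
    return merged[["chrom", "pos", "ref"] + cols]


def genotype_loglik(n1, n2, n_other, eps):
    """Log-likelihoods of (hom-major, het, hom-minor) for top-2 base counts.

    Symmetric per-read error model: a read from allele ``b`` reports ``b``
    with probability 1-eps and each other base with probability eps/3.
    Heterozygote emits either allele with probability 1/2.
    """
    n1, n2, n_other = (np.asarray(x, dtype=float) for x in (n1, n2, n_other))
    eps = np.asarray(eps, dtype=float)
    log_hit = np.log1p(-eps)
    log_miss = np.log(eps / 3.0)
    log_het = np.log((1.0 - eps) / 2.0 + eps / 6.0)
    ll_hom1 = n1 * log_hit + (n2 + n_other) * log_miss
    ll_hom2 = n2 * log_hit + (n1 + n_other) * log_miss
    ll_het = (n1 + n2) * log_het + n_other * log_miss
    return ll_hom1, ll_het, ll_hom2


def find_het_snps_merged(pileup_A: pd.DataFrame, pileup_B: pd.DataFrame,
                         min_depth: int = DEFAULT_MIN_DEPTH,
                         min_qual: float = DEFAULT_MIN_QUAL) -> pd.DataFrame:
    """Strategy "merged": pool the clones and call heterozygosity by diploid
    genotype likelihoods over the two most abundant bases.

    The per-read error rate is derived from the mean phred over reads of the
    two candidate alleles (eps = 10^(-Qbar/10)).  A position is emitted when
    the heterozygous genotype strictly maximises the likelihood and passes
    the depth/quality thresholds.
    """
    merged = merge_pileups(pileup_A, pileup_B)
    counts = merged[list(BASES)].to_numpy(dtype=float)
    if (counts < 0).any():
        raise InputError("negative base count in pileup")
    quals = merged[list(QUAL_COLS)].to_numpy(dtype=float)
    depth = counts.sum(axis=1)
    order = np.argsort(counts, axis=1)
    i1, i2 = order[:, -1], order[:, -2]
    rows = np.arange(len(merged))
    n1, n2 = counts[rows, i1], counts[rows, i2]
    n_other = depth - n1 - n2
    with np.errstate(invalid="ignore", divide="ignore"):
        qbar = (quals[rows, i1] + quals[rows, i2]) / np.where(n1 + n2 > 0, n1 + n2, np.nan)
    eps = np.clip(10.0 ** (-qbar / 10.0), 1e-10, 0.25)
    ll_hom1, ll_het, ll_hom2 = genotype_loglik(n1, n2, n_other, np.nan_to_num(eps, nan=0.25))
    het_best = (ll_het > ll_hom1) & (ll_het > ll_hom2)
    keep = het_best & (depth >= min_depth) & (qbar >= min_qual) & (n2 > 0)
    return pd.DataFrame({
        "chrom": merged["chrom"].to_numpy()[keep],
        "pos": merged["pos"].to_numpy()[keep],
        "allele_cloneA": np.array(BASES)[i1[keep]],
        "allele_cloneB": np.array(BASES)[i2[keep]],
        "depth_A": depth[keep].astype(int),
        "depth_B": depth[keep].astype(int),
        "qual_A": qbar[keep],
        "qual_B": qbar[keep],
        "gene_id": NO_GENE,
        "strategy": "merged",
    })


def _merged_intervals(genes: pd.DataFrame):
    """Per-chromosome sorted lists of (start, end, gene_id), intervals merged
    within each gene."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for (chrom, gene_id), grp in genes.groupby(["chrom", "gene_id"]):
        ivals = sorted(zip(grp["start"], grp["end"]))
        merged: list[list[int]] = []
        for s, e in ivals:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        by_chrom.setdefault(chrom, []).extend((s, e, gene_id) for s, e in merged)
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    return by_chrom


def annotate_and_filter(snps: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Annotate SNPs with the gene whose mature-transcript intervals contain
    them; drop intergenic positions and positions inside more than one gene.

    SNP positions are 1-based, gene intervals 0-based half-open; a SNP at
    ``pos`` overlaps interval [start, end) iff start <= pos-1 < end.
    """
    if len(snps) and len(genes):
        if not set(snps["chrom"]) & set(genes["chrom"]):
            raise InputError("SNP and gene-model chromosome names do not overlap")
    index = _merged_intervals(genes)
    gene_ids = []
    for chrom, pos in zip(snps["chrom"], snps["pos"]):
        p = pos - 1  # to 0-based
        hits = {g for s, e, g in index.get(chrom, ()) if s <= p < e}
        gene_ids.append(hits.pop() if len(hits) == 1 else NO_GENE)
    out = snps.copy()
    out["gene_id"] = gene_ids
    return out[out["gene_id"] != NO_GENE].reset_index(drop=True)


def strategy_overlap(snps1: pd.DataFrame, snps2: pd.DataFrame) -> tuple[int, int, int]:
    """Compare two SNP sets keyed on (chrom, pos): (only-in-1, only-in-2, both)."""
    s1 = set(zip(snps1["chrom"], snps1["pos"]))
    s2 = set(zip(snps2["chrom"], snps2["pos"]))
    return len(s1 - s2), len(s2 - s1), len(s1 & s2)
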