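"""Synthetic reciprocal-clone datasets with known ground truth.

The generator emulates the structure of the real study: two single-cell
clones with mirrored Xa/Xi haplotypes, sequenced before fusion (hF) and at
0, 4 and 6 days after fusion with mouse ES cells, two biological replicates
each.  Roughly 15% of genes constitutively express their Xi allele
(escapers); of the remaining inactive genes, 10% switch on Xi expression
after day 0 (reactivated, modelled as a step change at day 4).  Residual
Xi-allele reads at inactive genes arise only from base-call errors at rate
epsilon.  Everything is deterministic given the seed.

Outputs are the exact TSV dialects consumed by the discovery and
quantification stages, plus truth tables for every planted quantity.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .io import (BASES, write_gene_models, write_pileup)

CHROM = "chrXsim"
CLONES = ("clone1", "clone2")  # clone1 is the reference clone

ESCAPE = "escape"
REACTIVATED = "reactivated"
INACTIVE = "inactive"


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters; defaults mirror the study's magnitudes."""
    seed: int
    n_genes: int = 500
    snps_per_gene_mean: float = 2.0      # Poisson, floored at 1 SNP/gene
    depth_mean: float = 200.0            # negative binomial per SNP per sample
    depth_dispersion: float = 5.0        # NB size; var = m + m^2/size
    frac_escape: float = 0.15
    escape_xi_beta: tuple = (1.5, 4.5)   # escaper Xi fraction ~ Beta(a, b)
    frac_reactivated: float = 0.10       # of the inactive genes
    error_rate: float = 0.001
    phred_mean: float = 30.0
    phred_sd: float = 3.0
    timepoints: tuple = ("hF", "day0", "day4", "day6")
    n_replicates: int = 2
    frac_cross_mappable: float = 0.3
    xi_overdispersion: float = 0.02      # rho of allelic beta-binomial draw
    n_nonvariant_positions: int = 500
    n_multigene_snps: int = 5
    ramp_reactivation: bool = False      # default: step change at day 4

    def validate(self):
        for name in ("frac_escape", "frac_reactivated", "error_rate",
                     "frac_cross_mappable", "xi_overdispersion"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InputError(f"{name} must lie in [0,1], got {v}")
        if self.depth_mean <= 0 or self.n_genes <= 0:
            raise InputError("depth_mean and n_genes must be positive")
        if self.seed is None:
            raise InputError("seed is mandatory")
        return self


PRE = ("hF", "day0")


def _betabin_draw(rng, n, mu, rho):
    """Beta-binomial sample; rho=0 degenerates to binomial."""
    if mu <= 0:
        return np.zeros_like(n)
    if rho <= 0:
        return rng.binomial(n, mu)
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    p = rng.beta(a, b, size=np.shape(n))
    return rng.binomial(n, p)


def _qualsum(rng, counts, phred_mean, phred_sd):
    """Summed phred over `counts` reads, Normal per-read quality, >= 1."""
    counts = np.asarray(counts)
    total = np.zeros(counts.shape, dtype=float)
    nz = counts > 0
    if nz.any():
        c = counts[nz].astype(float)
        total[nz] = np.maximum(
            rng.normal(c * phred_mean, np.sqrt(c) * phred_sd), c * 1.0)
    return np.round(total, 1)


def simulate_dataset(config: SimulationConfig):
    """Generate one full reciprocal-clone time-course dataset.

    Returns a dict with keys: ``pileups`` (sample_id -> pileup DataFrame),
    ``species_flags`` (sample_id -> flag DataFrame, post-fusion samples),
    ``genes`` (BED-like DataFrame), ``manifest`` (sample sheet),
    ``truth_genes`` and ``truth_snps`` (ground truth), ``config``.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- gene classes (exact by construction) ---------------------------
    n_escape = round(cfg.frac_escape * cfg.n_genes)
    n_inactive_pool = cfg.n_genes - n_escape
    n_react = round(cfg.frac_reactivated * n_inactive_pool)
    classes = ([ESCAPE] * n_escape + [REACTIVATED] * n_react
               + [INACTIVE] * (n_inactive_pool - n_react))
    rng.shuffle(classes)

    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    gene_rows, snp_rows, truth_gene_rows = [], [], []
    gene_span = 10_000
    base_arr = np.array(BASES)

    for i, (gid, cls) in enumerate(zip(gene_ids, classes)):
        g0 = i * gene_span + 1000
        # two exons per gene, fixed geometry
        exons = [(g0, g0 + 1500), (g0 + 3000, g0 + 5000)]
        for s, e in exons:
            gene_rows.append((CHROM, s, e, gid, 0, "+"))
        n_snps = max(1, rng.poisson(cfg.snps_per_gene_mean))
        # SNP positions: 0-based inside exons -> store 1-based
        exon_pos = np.concatenate([np.arange(s, e) for s, e in exons])
        pos0 = np.sort(rng.choice(exon_pos, size=min(n_snps, len(exon_pos)),
                                  replace=False))
        for p0 in pos0:
            h1, h2 = rng.choice(4, size=2, replace=False)
            snp_rows.append((CHROM, int(p0) + 1, gid,
                             base_arr[h1], base_arr[h2]))

        # Xi fraction per timepoint (shared across clones)
        a, b = cfg.escape_xi_beta
        if cls == ESCAPE:
            f = float(rng.beta(a, b))
            frac = {tp: f for tp in cfg.timepoints}
        elif cls == REACTIVATED:
            f = float(rng.beta(a, b))
            frac = {}
            for tp in cfg.timepoints:
                if tp in PRE:
                    frac[tp] = 0.0
                elif cfg.ramp_reactivation and tp == "day4":
                    frac[tp] = f / 2.0
                else:
                    frac[tp] = f
        else:
            frac = {tp: 0.0 for tp in cfg.timepoints}
        row = {"gene_id": gid, "class": cls}
        row.update({f"xi_fraction_{tp}": frac[tp] for tp in cfg.timepoints})
        truth_gene_rows.append(row)

    # overlapping decoy genes: one extra gene sharing part of a host exon,
    # with one planted SNP inside the shared window (must be filtered out)
    overlap_snp_rows = []
    for j in range(cfg.n_multigene_snps):
        host = int(rng.integers(0, cfg.n_genes))
        hg0 = host * gene_span + 1000
        s, e = hg0, hg0 + 300
        gene_rows.append((CHROM, s, e, f"OVL{j:02d}", 0, "+"))
        p0 = int(rng.integers(s, e))
        h1, h2 = rng.choice(4, size=2, replace=False)
        overlap_snp_rows.append((CHROM, p0 + 1, gene_ids[host],
                                 base_arr[h1], base_arr[h2]))

    genes = pd.DataFrame(gene_rows,
                         columns=["chrom", "start", "end", "gene_id", "score", "strand"])
    truth_snps = pd.DataFrame(snp_rows + overlap_snp_rows,
                              columns=["chrom", "pos", "gene_id",
                                       "allele_h1", "allele_h2"])
    truth_snps = truth_snps.drop_duplicates(subset=["chrom", "pos"]).reset_index(drop=True)
    truth_genes = pd.DataFrame(truth_gene_rows)

    # non-variant homozygous positions, shared across samples
    nv_start = cfg.n_genes * gene_span + 100_000
    nv_pos = np.arange(nv_start, nv_start + cfg.n_nonvariant_positions) + 1
    nv_base = rng.integers(0, 4, size=cfg.n_nonvariant_positions)

    frac_lookup = truth_genes.set_index("gene_id")
    xi_frac_cols = {tp: f"xi_fraction_{tp}" for tp in cfg.timepoints}

    samples, pileups, flags = [], {}, {}
    base_idx = {b: i for i, b in enumerate(BASES)}
    snp_gene = truth_snps["gene_id"].to_numpy()
    snp_h1 = np.array([base_idx[b] for b in truth_snps["allele_h1"]])
    snp_h2 = np.array([base_idx[b] for b in truth_snps["allele_h2"]])
    n_snp = len(truth_snps)

    for clone in CLONES:
        xa_idx, xi_idx = (snp_h1, snp_h2) if clone == "clone1" else (snp_h2, snp_h1)
        for tp in cfg.timepoints:
            xi_f = frac_lookup.loc[snp_gene, xi_frac_cols[tp]].to_numpy(dtype=float)
            for rep in range(1, cfg.n_replicates + 1):
                sample_id = f"{clone}_{tp}_r{rep}"
                samples.append((sample_id, clone, tp, rep))
                depth = rng.negative_binomial(
                    cfg.depth_dispersion,
                    cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean),
                    size=n_snp)
                depth = np.maximum(depth, 1)
                # allelic origin, then symmetric base-call errors at rate eps
                xi_true = np.array([_betabin_draw(rng, d, f, cfg.xi_overdispersion)
                                    for d, f in zip(depth, xi_f)])
                xa_true = depth - xi_true
                counts = np.zeros((n_snp, 4), dtype=int)
                for origin, idx in ((xa_true, xa_idx), (xi_true, xi_idx)):
                    err = rng.binomial(origin, cfg.error_rate)
                    correct = origin - err
                    counts[np.arange(n_snp), idx] += correct
                    if err.sum():
                        # errors land uniformly on the three other bases
                        others = np.array([[b for b in range(4) if b != i]
                                           for i in idx])
                        spread = rng.multinomial(err, [1 / 3] * 3)
                        for col in range(3):
                            np.add.at(counts, (np.arange(n_snp), others[:, col]),
                                      spread[:, col])
                quals = _qualsum(rng, counts, cfg.phred_mean, cfg.phred_sd)
                # non-variant block
                nv_depth = np.maximum(rng.negative_binomial(
                    cfg.depth_dispersion,
                    cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean),
                    size=cfg.n_nonvariant_positions), 1)
                nv_counts = np.zeros((cfg.n_nonvariant_positions, 4), dtype=int)
                nv_err = rng.binomial(nv_depth, cfg.error_rate)
                nv_counts[np.arange(len(nv_pos)), nv_base] = nv_depth - nv_err
                if nv_err.sum():
                    others = np.array([[b for b in range(4) if b != i]
                                       for i in nv_base])
                    spread = rng.multinomial(nv_err, [1 / 3] * 3)
                    for col in range(3):
                        np.add.at(nv_counts, (np.arange(len(nv_pos)), others[:, col]),
                                  spread[:, col])
                nv_quals = _qualsum(rng, nv_counts, cfg.phred_mean, cfg.phred_sd)

                pile = pd.DataFrame({
                    "chrom": CHROM,
                    "pos": np.concatenate([truth_snps["pos"].to_numpy(), nv_pos]),
                    "ref": np.concatenate([truth_snps["allele_h1"].to_numpy(),
                                           np.array(BASES)[nv_base]]),
                })
                allc = np.vstack([counts, nv_counts])
                allq = np.vstack([quals, nv_quals])
                for bi, b in enumerate(BASES):
                    pile[b] = allc[:, bi]
                    pile["q" + b] = np.where(allc[:, bi] > 0, allq[:, bi], 0.0)
                pile = pile.sort_values("pos").reset_index(drop=True)
                pileups[sample_id] = pile

                if tp != "hF":  # heterokaryon samples carry mouse reads too
                    # flag table capped: it exercises the filter, the pileup
                    # already holds only the retained (human-only) reads
                    n_retained = min(int(allc.sum()), 10_000)
                    n_cross = int(round(n_retained * cfg.frac_cross_mappable
                                        / max(1 - cfg.frac_cross_mappable, 1e-9)))
                    fl = pd.DataFrame({
                        "read_id": [f"{sample_id}_rd{i}" for i in
                                    range(n_retained + n_cross)],
                        "maps_to_human": True,
                        "maps_to_mouse": np.concatenate(
                            [np.zeros(n_retained, bool), np.ones(n_cross, bool)]),
                    })
                    flags[sample_id] = fl.sample(frac=1.0, random_state=cfg.seed
                                                 ).reset_index(drop=True)

    manifest = pd.DataFrame(samples,
                            columns=["sample_id", "clone", "timepoint", "replicate"])
    return {
        "pileups": pileups,
        "species_flags": flags,
        "genes": genes,
        "manifest": manifest,
        "truth_genes": truth_genes,
        "truth_snps": truth_snps,
        "config": cfg,
    }


TINY = SimulationConfig(seed=0, n_genes=20, timepoints=("hF", "day4"),
                        depth_mean=100.0, n_nonvariant_positions=100,
                        n_multigene_snps=2)
STANDARD = SimulationConfig(seed=0)

PRESETS = {"tiny": TINY, "standard": STANDARD}


def simulate_counts(rng, n_genes, pi0, mu0, rho0, mu1, rho1,
                    depth_mean=200.0, depth_dispersion=5.0, phred_mean=30.0):
    """Gene-level draw straight from the mixture's generative law.

    Used for parameter-recovery and calibration studies where the full
    pileup machinery is unnecessary.  Returns (k, n, xi_qualsum, component)
    with component 0 = inactivated.
    """
    n = np.maximum(rng.negative_binomial(
        depth_dispersion, depth_dispersion / (depth_dispersion + depth_mean),
        size=n_genes), 1)
    z = (rng.random(n_genes) >= pi0).astype(int)  # 1 = escape component
    k = np.empty(n_genes, dtype=int)
    for comp, (mu, rho) in enumerate(((mu0, rho0), (mu1, rho1))):
        m = z == comp
        if m.any():
            k[m] = _betabin_draw(rng, n[m], mu, rho)
    qual = _qualsum(rng, k, phred_mean, 3.0)
    return k, n, qual, z


def emit_fixture(out_dir, size: str = "tiny", seed: int | None = None):
    """Write a fixture bundle (pileups, genes, manifest, truth, config).

    ``size`` selects a preset: "tiny" (20 genes, hF+day4; unit-test scale)
    or "standard" (500 genes, full design).  ``seed`` overrides the preset's.
    """
    if size not in PRESETS:
        raise InputError(f"unknown preset {size!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[size]
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    bundle = simulate_dataset(cfg)
    out = Path(out_dir)
    (out / "pileups").mkdir(parents=True, exist_ok=True)
    paths = {}
    for sample_id, pile in bundle["pileups"].items():
        p = out / "pileups" / f"{sample_id}.tsv"
        write_pileup(pile, p)
        paths[sample_id] = str(p)
    if bundle["species_flags"]:
        (out / "species_flags").mkdir(exist_ok=True)
        for sample_id, fl in bundle["species_flags"].items():
            fl.to_csv(out / "species_flags" / f"{sample_id}.tsv",
                      sep="\t", index=False)
    write_gene_models(bundle["genes"], out / "genes.bed")
    manifest = bundle["manifest"].copy()
    manifest["pileup"] = manifest["sample_id"].map(paths)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    bundle["truth_genes"].to_csv(out / "truth_genes.tsv", sep="\t", index=False)
    bundle["truth_snps"].to_csv(out / "truth_snps.tsv", sep="\t", index=False)
    cfg_dict = {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(cfg).items()}
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=False)
    return bundle
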