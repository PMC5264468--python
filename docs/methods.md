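# Methods

## Design

The pipeline analyses allele-specific expression of X-linked genes in two
reciprocal clones — single-cell-derived lines from one female donor that
silenced opposite X chromosomes — sequenced before (hF) and after fusion
with mouse ES cells (days 0, 4, 6; two biological replicates). Input is
per-position base-count pileups (counts and summed phred qualities for
A/C/G/T), 1-based coordinates; gene models are BED-like, 0-based half-open.
The coordinate conversion is confined to the annotation step.

## Heterozygous SNP discovery

**Reciprocal strategy.** Per clone, the most abundant base is called at every
position with total depth ≥ 8 and mean phred of the top base ≥ 20
(replicates merged by summing counts and quality sums before filtering).
Positions whose top base differs between clones are heterozygous candidates.
This works even when one allele is completely silenced — the design's
central asymmetry. Ties for the most abundant base reject the position:
"most abundant" is undefined there and ties are overwhelmingly noise.

**Merged strategy.** Counts of the two clones are pooled (the mirrored
haplotypes mimic genomic DNA) and the two most abundant bases b₁, b₂ are
scored under three diploid genotypes {b₁b₁, b₁b₂, b₂b₂} with a symmetric
per-read error model: a read from allele *b* reports *b* with probability
1−ε and each other base with probability ε/3, where ε = 10^(−Q̄/10) from
the mean phred over reads of the two candidate alleles. The heterozygote is
emitted when it strictly maximises the likelihood and the depth/quality
thresholds pass. A uniform genotype prior is used; for a single biallelic
site with unknown allele frequency this is the neutral choice.

The call quality used in both filters is the mean phred of the supporting
reads — a monotone, pileup-computable proxy for a consensus-caller site
quality; it is a proxy, not a reimplementation of any specific caller.

SNPs are kept only when their position lies in the merged mature-transcript
(exon+UTR) intervals of exactly one gene; positions inside two or more gene
models are discarded because reads there cannot be attributed to a single
gene.

## Phasing and quantification

At each SNP the allele with the higher read depth in the reference clone's
replicate-merged pre-fusion pileup is taken as that clone's Xa allele and,
by reciprocity, the Xi allele of the other clone; ties exclude the SNP.
Phasing is fixed once and reused for every sample in the time series.

Per sample, reads supporting the two phased alleles are counted at each SNP
and summed within genes, together with the summed phred of Xi-supporting
bases. Reads carrying a third or fourth base are sequencing errors and are
ignored, so total = Xa + Xi (the reported Xi fraction is
100·Xi/(Xa+Xi), one decimal). Replicates are merged by summing reads and
quality sums. Aggregation is permutation-invariant and commutes with
replicate merging, both asserted by tests.

For heterokaryon samples (post-fusion) a per-read species-flag table marks
whether each read aligns to the human and/or mouse genome; reads aligning to
both are excluded, reads aligning to neither are an input error.

## Mixture model

Gene-level counts (k Xi reads of n total) in one sample follow a
two-component beta-binomial mixture; beta-binomials are parameterised by
mean μ and overdispersion ρ via α = μ(1−ρ)/ρ, β = (1−μ)(1−ρ)/ρ, with ρ = 0
the exact binomial. The pmf is computed in log space (scipy's beta-binomial
kernel) and is stable to n = 10⁵.

EM details:

* E-step: τ_i0 = π₀f₀(k_i) / (π₀f₀(k_i) + (1−π₀)f₁(k_i)).
* M-step: π₀ closed-form (mean responsibility, clipped to (10⁻⁶, 1−10⁻⁶));
  each component's (μ, ρ) by bounded L-BFGS-B on the responsibility-weighted
  negative log-likelihood, never accepting a step that worsens the weighted
  objective, so the observed log-likelihood is non-decreasing (asserted to
  1e-8 in tests).
* μ₀ anchoring: μ₀ is constrained to [ε̄/3, 3ε̄+10⁻⁶] where ε̄ is the
  responsibility-weighted mean of the per-gene quality-derived error rates
  ε_i = 10^(−Q̄_i/10) (genes with no Xi reads fall back to ε₀ = 0.001).
  This ties the inactivated component to the sequencing-error regime, which
  is what makes the "significant Xi expression" call calibrated.
* μ₁ ∈ [0.05, 0.995]: an escaping gene means appreciable Xi transcription;
  the floor keeps the escape component identifiable and away from the error
  regime (and, with the μ₀ ceiling capped below it, enforces μ₀ < μ₁).
* Initialisation π₀ = 0.8, μ₀ = ε̄, ρ₀ = 0.01, μ₁ = 0.3, ρ₁ = 0.1;
  tol = 10⁻⁶ on the log-likelihood; max 1000 iterations (typical runs
  converge in 5–30). Non-convergence returns the last iterate, flagged.
  An all-zero k vector is a degenerate fit, flagged, with τ ≡ 1.
* One fit per clone × timepoint on replicate-merged data; each sample's τ
  uses its own fit, because the error structure and the escape fraction both
  change across reprogramming.

τ_i0 ≤ α (α = 0.05) calls significant Xi expression. τ is a posterior
probability, not a p-value; no multiple-testing correction is applied. The
wording "< 0.05" versus "≤ 0.05" differs between uses in the source
material; ≤ is used uniformly (a measure-zero difference).

## Time-course classification

On replicate-merged data per clone, with pre-fusion points {hF, day0} and
post-fusion points {day4, day6}: a gene is **evaluable** when it has ≥ 20
allele-specific reads at ≥ 1 pre-fusion point and ≥ 1 post-fusion point (any
clone). A strict mode instead requires day 4 and day 6 each to reach 20
reads — the two readings of the published filter; the permissive one is the
default. Then:

* **active** — significant (τ ≤ 0.05) at ≥ 1 observed pre point and ≥ 1
  observed post point;
* **reactivated** — not significant at any observed pre point in either
  clone, significant at ≥ 1 post point in ≥ 1 clone;
* **inactive** — not significant anywhere.

Precedence active > reactivated > inactive makes the rule total: every
combination of significant / not-significant / missing across the four
timepoints maps to exactly one class (exhaustively tested over all 3⁴
combinations).

Per-SNP concordance applies τ to each SNP's own (k, n) within multi-SNP
genes and reports the fraction of SNPs whose significance call matches
their gene's call.

## Synthetic data generator

The generator emulates the study design on one synthetic chromosome
("chrXsim"): `n_genes` two-exon genes, SNPs per gene ~ Poisson(2.0) floored
at 1 (matching roughly two expressed het SNPs per gene), per-SNP per-sample
depth ~ NegBin(mean 200, size 5), phred ~ Normal(30, 3) (ε = 10⁻³). Gene
classes are exact by construction: 15% escapers; of the remainder 10%
reactivate. Escaper Xi fractions are drawn from Beta(1.5, 4.5) — mean 0.25
with appreciable mass near and above 50%, matching the spread of published
escape-gene Xi fractions, which include near-balanced and Xi-biased cases.
Reactivation is a step change at day 4 (a ramp option exists, default off).
Allelic sampling uses a beta-binomial with ρ = 0.02, representing the
clone-to-clone stochasticity of Xi expression. Sequencing errors move each
read to one of the three other bases uniformly (rate ε), which is what
creates residual Xi reads at inactive genes (per-base leak ε/3) and
third-base noise. Homozygous non-variant positions (default 500) exercise
false-positive control, and decoy genes overlapping host exons plant
multi-gene SNPs that the annotation filter must drop. Cross-mappable reads
for post-fusion samples are flagged uniformly at random (30%), independent
of allele.

Everything is deterministic given the seed. Presets: `tiny` (20 genes,
hF+day4, for sub-second unit tests) and `standard` (500 genes, full
design) — the scale used by the acceptance script; dataset-level counts of
the original study (hundreds of SNPs over ~10⁵ expressed positions of a real
transcriptome) are deliberately not reproduced at desk scale.

What the generator does **not** model: read-level alignment and mapping
bias (reference-allele bias), transcript isoforms, UMI structure,
SNP-level heterogeneity within a gene, linked errors (error rate is i.i.d.
per read), and the mouse transcriptome beyond the cross-mappable flag.
Passing tests therefore demonstrate the statistical machinery is correct
under the stated generative assumptions, not that real-data artefacts such
as mapping bias are handled.

## Numerical and edge-case choices

* Top-base ties → position rejected (per clone); phasing ties → SNP dropped.
* Positions covered in only one clone are skipped by the reciprocal
  strategy (it requires both).
* ε clipped to [10⁻¹⁰, 0.25] in genotype likelihoods; qualsum must be 0
  wherever a base count is 0 (validated on input).
* Genes with n = 0 get τ = NaN and are reported not-evaluated.
* `fit_mixture` requires ≥ 10 genes with reads.
* All stochastic tests use fixed seeds; pipeline outputs are byte-identical
  given identical inputs and seed.

## Known limitations

* The mean-phred call quality is a proxy; results with a different site
  quality definition may differ near the ≥ 20 threshold.
* The reciprocal strategy inherently misses heterozygous sites whose two
  alleles are near-balanced in both clones (escapers at ~50% Xi): the
  "most abundant base" can coincide between clones there. The merged
  strategy recovers these; running with `--strategy both` combines them.
* μ₀ anchoring assumes base qualities are honest; inflated phred scores
  would overstate significance of small Xi counts.
* Per-sample fits need enough genes (and some Xi signal) per clone ×
  timepoint; very small panels should pool timepoints or use the
  degenerate-fit flag to detect failure.
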