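# Methods

## Study design emulated by the generator

The synthetic cohort mirrors a two-breed, multi-tissue ribosome-profiling
atlas: `n_tissues` tissues (default 3) × 2 breeds × `n_reps` biological
replicates (default 3), each condition measured at the transcriptome
(RNA-seq) and translatome (Ribo-seq) level, with a matched protein layer.
Counts are negative binomial with the mean/dispersion parameterization
var = μ + αμ² (α = `nb_dispersion`, default 0.05 — typical for bulk
RNA-seq biological replicates); per-library size factors are log-normal
with sd `library_size_spread` (0.2). Gene means come from a latent log2
expression with gene baseline N(5, 1.5), per-tissue effects N(0, 0.8),
and replicate-level biological noise N(0, 0.25). The RPF mean is the RNA
mean times the gene's true TE, log-normal with sd `te_log_sd` (0.5 log2
units); α below 1e-8 switches to a Poisson draw so the noise-free limit
is well defined. `depth_scale` (3.0) sets typical counts near 100 so
that count noise does not dominate replicate TE estimates.

Planted structure, all recorded in a `GroundTruth` object:

- **Interaction classes.** `frac_reinforcing` and `frac_compensatory`
  (default 0.05 each, matching the few-percent interaction-gene rates a
  tissue atlas reports) of genes receive breed-A shifts of magnitude
  `interaction_effect` (2 log2 units, random sign). Reinforcing genes
  shift mRNA with TE unchanged, so the RPF fold change equals the mRNA
  fold change. Compensatory genes shift mRNA while TE moves oppositely
  at 1.5× the effect, leaving an attenuated, opposite-sign RPF response
  (−effect/2). The attenuation is deliberate: buffering that merely
  mirrored the mRNA shift at full magnitude would move protein as much
  as amplification does, contradicting the defining observation that
  buffered genes show smaller protein divergence.
- **TF network.** The first `n_tfs` genes are regulators with extra
  per-sample activity N(0, 1); each true edge (density
  `network_density` of the TF × target grid) adds
  `coupling_strength` × mean regulator activity to the target's latent
  expression, in both omics layers. This multiplicative-on-the-mean
  coupling is simple and recoverable by importance-based inference.
- **Protein.** log2 protein = latent RPF log2 expression + N(0,
  `protein_noise_sd`). Deriving protein from the translational output
  (not mRNA) makes the RPF–protein correlation exceed the mRNA–protein
  correlation, as observed in matched proteome data.
- **Tissue-specific genes.** A small fraction per tissue get +5 log2 in
  their tissue and −8 elsewhere, putting them above the τ > 0.9 call.
- **Population layer.** Genotypes are Binomial(2, AF) per population.
  Causal 5'UTR variants carry planted AFs (0.9, 0.2), hence ΔAF = 0.7 >
  0.3 by construction, and multiply the gene's TE by
  `causal_te_multiplier`^(2·AF) per population (expected allele dosage),
  so the higher-AF population has higher TE when the multiplier exceeds
  one. A GWAS locus lands 2–15 kb from a `gwas_fraction` subset of causal
  variants; the rest are covered by the known-regulator gate. The assay
  table's luciferase direction matches the planted multiplier for exactly
  `round(concordance · n_assayed)` variants (the knob that reproduces a
  17/33 = 51.5% concordance when set to 17/33).

## Statistical procedures

**Size factors and TPM.** Median-of-ratios on the pooled RNA+RPF count
matrix (reference = per-gene geometric mean over all pooled samples,
genes with any zero excluded); normalized counts are divided by
length/1000 and scaled to one million per sample. Gene length is CDS
length for the TE layer (the generator emits CDS-region counts for both
modalities).

**Interaction classification.** u = (m + r)/√2, v = (m − r)/√2 with SDs
taken over all finite genes (sample SD, ddof = 1) — including, not
excluding, the classified genes; a switch for the filtered subset is
not exposed because the reference population was chosen once. Thresholds
|u| > 2·s_u (same sign) and |v| > 2·s_v (opposite signs), ratio filter
strict |log10(|m/r|)| < 0.5 with both m, r ≠ 0.

**Permutation null.** Derangements are sampled by rejection (≤100
tries, then a random single-cycle rotation). The surrogate
r* = μ_r + σ_r(ρ·z_m + √(1−ρ²)·z_e), with z_m the standardized m and
z_e the standardized residual of the permuted vector after removing its
projection on z_m, matches mean, SD, and correlation to machine
precision (asserted at 1e-9 in the tests). Thresholds s_u, s_v are
recomputed inside every permuted dataset. Empirical p-values use the
(1 + count)/(1 + B) correction and can never be zero. Degenerate inputs
(|ρ| = 1, n < 4) are rejected.

*Power asymmetry.* When the observed m–r correlation is high — as it is
whenever both layers share latent expression — the correlation-matched
null itself produces many same-sign pairs, especially by pairing
large-|m| genes with correlated surrogates. Enrichment of the
reinforcing category is therefore much harder to detect than the
compensatory one at equal planting; at the benchmark scale (5,300
genes, 300 planted) both categories reach p ≈ 0.001–0.006 only because
the planted effects ride on top of background variation. This is a
property of the published test design, reproduced faithfully.

**Differential calls.** Welch t-tests on log2(TE) and log2(TPM+1) with
Benjamini–Hochberg correction and the |log2FC| > 1, FDR < 0.05 call
rule. These are declared stand-ins for count-model tools: with three
replicates the Welch p-value floor is ≈1e-3, so BH across hundreds of
genes passes only datasets with many strong signals. Type-I error is
controlled (verified by null calibration); sensitivity is deliberately
not patched, and downstream candidate counts in small full-pipeline
runs are correspondingly conservative.

**Quantiles.** All quantiles (TE range, quintile groups) use linear
interpolation (type 7, the numpy default). Quintile ties break on
(TE, gene id) so grouping is deterministic.

**GRN inference.** One `RandomForestRegressor` per target (100 trees at
desk scale; √p candidate features per split), edge weight = summed
impurity importance of each regulator, the target excluded from its own
regulators. Top-K cuts resolve boundary ties lexicographically by
(regulator, target). Fusion is the strict three-way edge intersection —
the published fused-network size (~8% of the per-configuration cut)
implies intersection, not union — with the fused weight the arithmetic
mean of the three configuration weights (a choice; the sources are
silent on the fused weight).

**Variant cascade.** MAF and missingness boundaries are inclusive; ΔAF
is a strict inequality; the GWAS window (±20 kb) is inclusive and
measured to the nearest base of the locus interval; BED input is
half-open and converted internally to 1-based. The ΔAF reading of
population differentiation (absolute difference of alternate-allele
frequencies) is used throughout; only SNPs enter the candidate cascade,
though INDELs survive filtering. Concordance: a variant counts as
concordant when the allele with the higher reporter TE is the more
frequent allele in the population with the higher tissue TE; variants
with equal population AFs are undetermined and excluded from the rate's
denominator (rate = 100 · concordant / assayed).

## Pipeline and reproducibility

The orchestrator derives one seed per stage from the global seed via
`SeedSequence([seed, stage_index])`, so re-running a stage does not
depend on execution order; every writer is byte-deterministic given the
seed. Default desk-scale sizes (800 genes, top-K 2,000, 100 trees, B
1,000 permutations) keep a full run near one minute; the benchmark
script uses 5,300 genes and B = 1,000 and runs in seconds.

## What the generator does not model

Read-level artifacts (no FASTQ, P-site periodicity, or positional
bias), splice-isoform abundance, batch effects, genuine linkage
disequilibrium (genotypes are independent Binomial draws), trait
structure behind GWAS loci, and assay effect magnitudes (the assay table
records direction only). Passing tests therefore demonstrate that the
statistics recover the structures they are designed for under idealized
noise — not that they are robust to alignment artifacts or confounded
real-world designs. The τ tissue-specificity formula follows the common
max-normalized-complement convention; other TSI variants would shift the
0.9 threshold's meaning.
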