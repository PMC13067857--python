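# ribofuse

Paired RNA-seq / Ribo-seq analysis of translational regulation across
tissues and populations: translation-efficiency (TE) quantification,
translational buffering/amplification statistics, multi-omics gene
regulatory network (GRN) fusion, and prioritization of 5'UTR variants
that shift translation between two breeds or populations.

The package is aimed at computational biologists working with matched
transcriptome/translatome designs (e.g. livestock or model-organism
tissue atlases with two populations and a few biological replicates per
condition). Every analysis stage is driven by a synthetic-data generator
with planted ground truth, so each statistic has a parameter-recovery
test surface.

## What it computes

**Quantification.** Counts from both modalities are pooled for
median-of-ratios size factors; normalized counts become TPM; a gene is
detectable in a tissue when its replicate total exceeds 10 and at least
two replicates are nonzero. TE is the per-replicate ratio of RPF TPM to
RNA TPM over the CDS, defined only where both modalities are detectable:

```
TE_g = TPM_RPF(g) / TPM_RNA(g)
```

**Buffering vs amplification.** For each gene, cross-breed log2 fold
changes m (mRNA) and r (RPF) are projected onto the diagonals
u = (m + r)/√2 and v = (m − r)/√2. A gene is *reinforcing*
(amplification) when m and r share a sign and |u| > 2·sd(u), and
*compensatory* (buffering) when the signs differ and |v| > 2·sd(v); a
ratio filter |log10(|m/r|)| < 0.5 keeps only genes where both layers
contribute. Category enrichment is tested against a permutation null in
which r is deranged across genes and rescaled to match the observed
mean, SD, and correlation with m *exactly*:

```
r* = μ_r + σ_r (ρ·z_m + sqrt(1 − ρ²)·z_e),   p_cat = (1 + #{null ≥ obs}) / (1 + B)
```

**TE dynamics.** The TE range statistic (97.5%/2.5% quantile ratio),
per-gene mRNA–TE Pearson correlations across tissues with a
gene-shuffling null (two-sample KS comparison), and threshold-based
differential TE / expression calls (|log2FC| > 1, FDR < 0.05; Welch
t-test on log values with BH correction, a deliberately simple stand-in
for count-model tools, labeled as such in outputs).

**Sequence features.** 5'UTR/CDS/3'UTR length–TE Spearman correlations,
upstream-AUG counts, TE quintile groups (Top1 = highest 20%), ORF
category rules (uORF/dORF/iORF/aORF/lORF), and grouped TE comparisons
against alternative-splicing events and active small-ORF counts.

**GRN fusion.** Random-forest importance networks (one regression forest
per target; GENIE3-style) in three configurations — transcriptome→
transcriptome (Mm), translatome→translatome (Tt), transcriptome→
translatome (Tm) — each cut to its top-K edges; the multi-omics fusion
(MF) network is their strict three-way intersection, which measurably
raises edge precision over any single configuration on planted networks.

**Variant prioritization.** VCF filtering (MAF ≥ 0.05, missingness
≤ 0.2), per-population alternate-allele frequencies, differentiation
ΔAF > 0.3, candidate gates (5'UTR of a differential-TE gene in the fused
sub-network, plus a GWAS locus within ±20 kb or a known regulator gene),
reporter flanks (±50 bp clipped to the 5'UTR), and direction concordance
between reporter assays and the breed allele/TE configuration.

## Worked example

Run the full synthetic pipeline at the default study design (800 genes,
20 TFs, 3 tissues, 2 breeds, 3 replicates):

```python
from ribofuse import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, permutations=500, n_trees=50))
print(report["stages"]["coupling"])
print(report["stages"]["grn"])
print(report["stages"]["variants"])
```

prints (exact numbers for this seed):

```
{'n_reinforcing': 43, 'n_compensatory': 34, 'p_reinforcing': 0.5808383233532934, 'p_compensatory': 0.001996007984031936}
{'top_k': 2000, 'n_mf_edges': 666, 'mf_precision': 0.2237}
{'n_after_filter': 191, 'n_differentiated': 15, 'n_candidates': 0, 'n_assayed': 8, 'concordance_rate': 100.0}
```

Reading the report: the classifier finds 34 compensatory genes in the
first tissue against a permutation null that expects far fewer
(p ≈ 0.002), while the reinforcing category is not separable from the
correlation-matched null at this scale (see the methods note on power
asymmetry). The fused network keeps 666 of 2,000 edges per
configuration and reaches 22% precision against the planted network —
above every single configuration. All 8 assayed reporter variants are
direction-concordant because the generator's concordance knob defaults
to 1.0; `n_candidates` is 0 here because the Welch-based differential-TE
stand-in rarely clears BH correction with three replicates, a documented
limitation of the stand-in rather than of the gates (the gate logic is
exercised with planted truth sets in the test suite).

The same run is available from the shell:

```
ribofuse simulate --out data --seed 7          # counts, GTF, FASTA, VCF, BED, truth JSON
ribofuse quantify --rna data/rna_counts.tsv --rpf data/rpf_counts.tsv \
    --samples data/samples.tsv --lengths lengths.tsv --out quant
ribofuse coupling --rna-tpm quant/rna_tpm.tsv --rpf-tpm quant/rpf_tpm.tsv \
    --samples data/samples.tsv --tissue tissue1 --breeds A,B --perms 1000 --seed 3 --out coupling.json
ribofuse pipeline --seed 5 --perms 200 --out report.json
```

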