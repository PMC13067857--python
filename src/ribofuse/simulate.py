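"""Synthetic multi-omics data with planted ground truth.

Generates every input of the pipeline under known truth: transcript models
on a synthetic chromosome, negative-binomial RNA/RPF counts coupled
through gene-level translation efficiencies, a protein layer derived from
translational output, planted reinforcing/compensatory breed effects, a
TF -> target network expressed in both omics layers, two-population
genotypes, 5'UTR causal variants with allele-dependent TE multipliers,
GWAS loci near a subset of causal variants, and a reporter-assay table
with a controllable direction-concordance rate. Every stage is
deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import RNA, RPF, CountMatrix
from .seq_features import TranscriptModel

BASES = np.array(list("ACGT"))
STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults emulate a two-breed, multi-tissue design with three
    biological replicates per condition and moderate RNA-seq-like
    overdispersion.
    """

    n_genes: int = 800
    n_tfs: int = 20
    n_tissues: int = 3
    n_breeds: int = 2
    n_reps: int = 3
    nb_dispersion: float = 0.05
    library_size_spread: float = 0.2
    te_log_sd: float = 0.5
    frac_reinforcing: float = 0.05
    frac_compensatory: float = 0.05
    interaction_effect: float = 2.0
    network_density: float = 0.05
    protein_noise_sd: float = 0.5
    n_variants: int = 200
    causal_te_multiplier: float = 3.0
    seed: int = 0
    # secondary knobs
    frac_lncrna: float = 0.1
    coupling_strength: float = 0.8
    bio_noise_sd: float = 0.25
    tissue_effect_sd: float = 0.8
    base_log2_mean: float = 5.0
    base_log2_sd: float = 1.5
    frac_tissue_specific: float = 0.02
    n_causal_variants: int = 8
    causal_af: tuple[float, float] = (0.9, 0.2)
    background_af_jitter: float = 0.05
    n_pop_samples: int = 12
    gwas_fraction: float = 0.75
    concordance: float = 1.0
    depth_scale: float = 3.0
    populations: tuple[str, str] = ("popA", "popB")
    breeds: tuple[str, str] = ("A", "B")
    tissues: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.frac_reinforcing + self.frac_compensatory >= 1:
            raise ValueError("planted fractions must sum to < 1")
        for name in ("n_genes", "n_tfs", "n_tissues", "n_breeds", "n_reps", "n_variants"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in (
            "frac_reinforcing",
            "frac_compensatory",
            "network_density",
            "frac_lncrna",
            "gwas_fraction",
            "concordance",
        ):
            val = getattr(self, name)
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not self.tissues:
            self.tissues = tuple(f"tissue{i + 1}" for i in range(self.n_tissues))


@dataclass
class GroundTruth:
    """Planted truth shared by all simulated layers."""

    true_edges: set[tuple[str, str]]
    gene_class: dict[str, str]  # reinforcing / compensatory / background
    class_sign: dict[str, int]  # planted direction of the breed-A shift
    true_te: pd.DataFrame  # genes x (tissue, breed)
    causal_variants: list[dict]
    tissue_specific_genes: dict[str, set[str]]
    tf_ids: list[str] = field(default_factory=list)

    def genes_of_class(self, cls: str) -> list[str]:
        return [g for g, c in self.gene_class.items() if c == cls]

    def causal_gene_set(self) -> set[str]:
        return {c["gene"] for c in self.causal_variants}

    def breed_te_direction(self, pops: tuple[str, str]) -> pd.Series:
        """Per causal gene, the population with the higher translational
        output (implied by the allele-dosage TE multiplier)."""
        out = {}
        for c in self.causal_variants:
            up_pop = pops[0] if c["af"][0] > c["af"][1] else pops[1]
            out[c["gene"]] = up_pop if c["multiplier"] > 1 else (
                pops[1] if up_pop == pops[0] else pops[0]
            )
        return pd.Series(out, name="high_te_pop")


def _gene_ids(config: SimConfig) -> list[str]:
    width = len(str(config.n_genes))
    return [f"gene{str(i + 1).zfill(width)}" for i in range(config.n_genes)]


def simulate_transcript_models(config: SimConfig) -> dict[str, TranscriptModel]:
    """Lay out one representative transcript per gene along a synthetic
    chromosome: contiguous 5'UTR, CDS (ATG ... stop, length divisible by
    3) and 3'UTR for coding genes; a single exon for lncRNAs."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    ids = _gene_ids(config)
    n_lnc = int(round(config.frac_lncrna * config.n_genes))
    lnc = set(rng.choice(config.n_genes, size=n_lnc, replace=False)) if n_lnc else set()
    models: dict[str, TranscriptModel] = {}
    pos = 1000
    for i, gid in enumerate(ids):
        if i in lnc:
            length = int(rng.integers(300, 1200))
            seq = "".join(rng.choice(BASES, size=length))
            models[gid] = TranscriptModel(
                gid, f"{gid}.t1", "chrS", "+", None, None, None,
                utr3_seq=seq, biotype="lncRNA",
            )
            # lncRNA exon occupies [pos, pos+length-1]
            models[gid].utr3 = (pos, pos + length - 1)
            pos += length + int(rng.integers(1000, 5000))
            continue
        u5 = int(rng.integers(100, 301))
        n_codons = int(rng.integers(100, 401))
        u3 = int(rng.integers(150, 501))
        utr5_seq = "".join(rng.choice(BASES, size=u5))
        body = "".join(rng.choice(BASES, size=3 * (n_codons - 2)))
        cds_seq = "ATG" + body + STOP_CODONS[int(rng.integers(0, 3))]
        utr3_seq = "".join(rng.choice(BASES, size=u3))
        cds_len = len(cds_seq)
        utr5 = (pos, pos + u5 - 1)
        cds = (utr5[1] + 1, utr5[1] + cds_len)
        utr3 = (cds[1] + 1, cds[1] + u3)
        models[gid] = TranscriptModel(
            gid, f"{gid}.t1", "chrS", "+", utr5, cds, utr3,
            utr5_seq, cds_seq, utr3_seq, "coding",
        )
        pos = utr3[1] + 1 + int(rng.integers(1000, 5000))
    return models


def make_ground_truth(config: SimConfig, models: dict[str, TranscriptModel]) -> GroundTruth:
    """Plant interaction classes, the TF network, per-condition TEs,
    tissue-specific genes, and 5'UTR causal variants."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    ids = list(models)
    tf_ids = ids[: config.n_tfs]
    coding_targets = [g for g in ids[config.n_tfs :] if models[g].biotype == "coding"]

    n_re = int(round(config.frac_reinforcing * config.n_genes))
    n_co = int(round(config.frac_compensatory * config.n_genes))
    planted = list(rng.choice(coding_targets, size=n_re + n_co, replace=False))
    gene_class = {g: "background" for g in ids}
    class_sign = {}
    for g in planted[:n_re]:
        gene_class[g] = "reinforcing"
    for g in planted[n_re:]:
        gene_class[g] = "compensatory"
    for g in planted:
        class_sign[g] = int(rng.choice([-1, 1]))

    n_targets = len(ids) - config.n_tfs
    n_edges = int(round(config.network_density * config.n_tfs * n_targets))
    all_pairs = [(tf, t) for tf in tf_ids for t in ids[config.n_tfs :]]
    edge_idx = rng.choice(len(all_pairs), size=n_edges, replace=False)
    true_edges = {all_pairs[i] for i in edge_idx}

    # baseline log2 TE per gene, mild tissue modulation, breed shifts from
    # compensatory planting and causal-variant allele dosages
    log_te = rng.normal(0.0, config.te_log_sd, size=len(ids))
    tissue_mod = rng.normal(0.0, 0.1, size=(len(ids), config.n_tissues))
    cols = pd.MultiIndex.from_product(
        [config.tissues, config.breeds], names=["tissue", "breed"]
    )
    te = pd.DataFrame(index=pd.Index(ids, name="gene"), columns=cols, dtype=float)
    for ti, tissue in enumerate(config.tissues):
        for breed in config.breeds:
            te[(tissue, breed)] = 2.0 ** (log_te + tissue_mod[:, ti])

    # compensatory: translational buffering damps and reverses the mRNA
    # shift, so the RPF response is attenuated (RPF FC = -effect/2)
    for g in planted[n_re:]:
        shift = -1.5 * class_sign[g] * config.interaction_effect
        for tissue in config.tissues:
            te.loc[g, (tissue, config.breeds[0])] *= 2.0**shift

    # tissue-specific genes
    n_ts = int(round(config.frac_tissue_specific * config.n_genes))
    ts_pool = [g for g in coding_targets if gene_class[g] == "background"]
    tissue_specific = {}
    taken: set[str] = set()
    for tissue in config.tissues:
        avail = [g for g in ts_pool if g not in taken]
        chosen = set(rng.choice(avail, size=min(n_ts, len(avail)), replace=False))
        taken |= chosen
        tissue_specific[tissue] = chosen

    # causal 5'UTR variants with allele-dosage TE multipliers
    causal_pool = [
        g for g in coding_targets
        if gene_class[g] == "background" and g not in taken and models[g].utr5 is not None
    ]
    n_causal = min(config.n_causal_variants, len(causal_pool))
    causal_genes = list(rng.choice(causal_pool, size=n_causal, replace=False))
    causal = []
    for g in causal_genes:
        lo, hi = models[g].utr5
        pos = int((lo + hi) // 2)
        ref = models[g].utr5_seq[pos - lo]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        mult = config.causal_te_multiplier
        af = config.causal_af
        causal.append(
            {
                "variant_id": f"chrS_{pos}",
                "chrom": "chrS",
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": g,
                "multiplier": mult,
                "af": af,
                "direction": "up" if mult > 1 else "down",
            }
        )
        # expected dosage 2*AF per population; population p maps to breed p
        for breed, a in zip(config.breeds, af):
            for tissue in config.tissues:
                te.loc[g, (tissue, breed)] *= mult ** (2.0 * a)
    return GroundTruth(true_edges, gene_class, class_sign, te, causal, tissue_specific, tf_ids)


@dataclass
class SimulatedExpression:
    rna: CountMatrix
    rpf: CountMatrix
    protein: pd.DataFrame
    protein_samples: pd.DataFrame
    latent_log2: pd.DataFrame  # genes x (tissue, breed, rep) RNA latent


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB(mean mu, var mu + a*mu^2); Poisson limit for tiny dispersion."""
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    if dispersion < 1e-8:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_counts(config: SimConfig, truth: GroundTruth,
                    models: dict[str, TranscriptModel] | None = None) -> SimulatedExpression:
    """Draw paired RNA/RPF count matrices and the protein layer.

    RNA counts ~ NB(size_factor * 2^latent * CDS-kb * depth, dispersion);
    RPF mean = RNA mean * TE(gene, tissue, breed). The latent log2
    expression carries tissue effects, planted breed shifts (reinforcing
    genes shift mRNA with TE unchanged, so RPF follows; compensatory genes
    shift mRNA while TE moves oppositely at twice the magnitude), and a
    multiplicative TF -> target coupling driven by per-sample regulator
    activity. Protein = log2 translational output + Gaussian noise.
    """
    if models is None:
        models = simulate_transcript_models(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    ids = list(models)
    n = len(ids)
    gi = {g: i for i, g in enumerate(ids)}
    base = rng.normal(config.base_log2_mean, config.base_log2_sd, size=n)
    tissue_eff = rng.normal(0.0, config.tissue_effect_sd, size=(n, config.n_tissues))
    for ti, tissue in enumerate(config.tissues):
        for g in truth.tissue_specific_genes.get(tissue, ()):
            tissue_eff[gi[g], :] = -8.0
            tissue_eff[gi[g], ti] = 5.0

    conditions = [
        (tissue, breed, rep)
        for tissue in config.tissues
        for breed in config.breeds
        for rep in range(1, config.n_reps + 1)
    ]
    n_cond = len(conditions)
    latent = np.tile(base[:, None], (1, n_cond))
    for ci, (tissue, breed, rep) in enumerate(conditions):
        latent[:, ci] += tissue_eff[:, config.tissues.index(tissue)]
    if config.bio_noise_sd > 0:
        latent += rng.normal(0.0, config.bio_noise_sd, size=latent.shape)

    # planted breed shifts on mRNA (breed A relative to breed B)
    for g, cls in truth.gene_class.items():
        if cls in ("reinforcing", "compensatory"):
            s = truth.class_sign[g] * config.interaction_effect
            for ci, (tissue, breed, rep) in enumerate(conditions):
                if breed == config.breeds[0]:
                    latent[gi[g], ci] += s

    # TF activity drives targets multiplicatively on the log scale
    tf_rows = np.array([gi[t] for t in truth.tf_ids])
    activity = rng.normal(0.0, 1.0, size=(len(tf_rows), n_cond))
    latent[tf_rows] += activity
    targets_of: dict[str, list[int]] = {}
    for tf, target in truth.true_edges:
        targets_of.setdefault(target, []).append(list(truth.tf_ids).index(tf))
    for target, tf_idx in targets_of.items():
        latent[gi[target]] += config.coupling_strength * activity[tf_idx].mean(axis=0)

    cds_kb = np.array(
        [models[g].cds_len / 1000.0 if models[g].biotype == "coding"
         else models[g].utr3_len / 1000.0 for g in ids]
    )
    log2_te = np.zeros((n, n_cond))
    for ci, (tissue, breed, rep) in enumerate(conditions):
        log2_te[:, ci] = np.log2(truth.true_te[(tissue, breed)].to_numpy(dtype=float))

    sample_rows, rna_cols, rpf_cols = [], [], []
    sf = np.exp(rng.normal(0.0, config.library_size_spread, size=2 * n_cond))
    for k, (ci, modality) in enumerate(
        [(ci, mod) for ci in range(n_cond) for mod in (RNA, RPF)]
    ):
        tissue, breed, rep = conditions[ci]
        sid = f"{tissue}_{breed}_{rep}_{modality}"
        sample_rows.append((sid, tissue, breed, rep, modality))
        mu = sf[k] * (2.0 ** latent[:, ci]) * cds_kb * config.depth_scale
        if modality == RPF:
            mu = mu * (2.0 ** log2_te[:, ci])
        counts = _nb_draw(rng, mu, config.nb_dispersion)
        (rna_cols if modality == RNA else rpf_cols).append((sid, counts))

    samples = pd.DataFrame(
        sample_rows, columns=["sample_id", "tissue", "breed", "replicate", "modality"]
    )
    idx = pd.Index(ids, name="gene")

    def build(cols, modality):
        vals = pd.DataFrame({sid: c for sid, c in cols}, index=idx)
        sheet = samples[samples["modality"] == modality].reset_index(drop=True)
        return CountMatrix(vals[list(sheet["sample_id"])], sheet)

    rna = build(rna_cols, RNA)
    rpf = build(rpf_cols, RPF)

    prot_cols, prot_rows = {}, []
    for ci, (tissue, breed, rep) in enumerate(conditions):
        sid = f"{tissue}_{breed}_{rep}_protein"
        prot_rows.append((sid, tissue, breed, rep, "protein"))
        signal = latent[:, ci] + log2_te[:, ci]
        prot_cols[sid] = signal + (
            rng.normal(0.0, config.protein_noise_sd, size=n)
            if config.protein_noise_sd > 0
            else 0.0
        )
    protein = pd.DataFrame(prot_cols, index=idx)
    protein_samples = pd.DataFrame(
        prot_rows, columns=["sample_id", "tissue", "breed", "replicate", "modality"]
    )
    latent_df = pd.DataFrame(
        latent, index=idx,
        columns=pd.MultiIndex.from_tuples(conditions, names=["tissue", "breed", "replicate"]),
    )
    return SimulatedExpression(rna, rpf, protein, protein_samples, latent_df)


@dataclass
class SimulatedPopulation:
    variants: pd.DataFrame  # chrom, pos, ref, alt, variant_id, af per pop, causal
    genotypes: pd.DataFrame  # variants x samples, dosage 0/1/2
    pop_of: pd.Series
    gwas_loci: pd.DataFrame  # chrom, start, end, name (BED half-open)
    assay_table: pd.DataFrame  # gene, direction per assayed variant


def simulate_population(
    config: SimConfig,
    truth: GroundTruth,
    models: dict[str, TranscriptModel] | None = None,
) -> SimulatedPopulation:
    """Two-population genotypes, GWAS loci, and the reporter-assay table.

    Genotypes are Binomial(2, AF_pop) draws; causal variants carry the
    planted allele frequencies (|delta AF| > 0.3 by construction), a GWAS
    locus lands within 20 kb of a ``gwas_fraction`` subset of causal
    variants (the remainder are covered by the known-regulator gate), and
    the assay table's luciferase direction agrees with the planted TE
    multiplier for exactly a ``concordance`` fraction of assayed variants.
    """
    if models is None:
        models = simulate_transcript_models(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    if config.n_variants < len(truth.causal_variants):
        raise ValueError("n_variants smaller than the number of causal variants")

    pops = config.populations
    chrom_end = max(
        iv[1] for m in models.values() for iv in (m.utr5, m.cds, m.utr3) if iv is not None
    )
    recs = []
    for c in truth.causal_variants:
        for a in c["af"]:
            if not 0 <= a <= 1:
                raise ValueError("allele frequency outside [0, 1]")
        recs.append(
            dict(
                chrom=c["chrom"], pos=c["pos"], ref=c["ref"], alt=c["alt"],
                variant_id=c["variant_id"],
                **{f"af_{pops[0]}": c["af"][0], f"af_{pops[1]}": c["af"][1]},
                causal=True,
            )
        )
    taken = {c["pos"] for c in truth.causal_variants}
    n_bg = config.n_variants - len(recs)
    while n_bg > 0:
        pos = int(rng.integers(1, chrom_end + 10000))
        if pos in taken:
            continue
        taken.add(pos)
        base_af = float(rng.uniform(0.05, 0.95))
        jit = config.background_af_jitter
        af_a = float(np.clip(base_af + rng.uniform(-jit, jit), 0.0, 1.0))
        af_b = float(np.clip(base_af + rng.uniform(-jit, jit), 0.0, 1.0))
        ref, alt = rng.choice(BASES, size=2, replace=False)
        recs.append(
            dict(
                chrom="chrS", pos=pos, ref=str(ref), alt=str(alt),
                variant_id=f"chrS_{pos}",
                **{f"af_{pops[0]}": af_a, f"af_{pops[1]}": af_b},
                causal=False,
            )
        )
        n_bg -= 1
    variants = pd.DataFrame(recs).sort_values("pos").reset_index(drop=True)
    variants.index = pd.Index(variants["variant_id"], name="variant_id")

    sample_ids = [f"{p}_{i + 1}" for p in pops for i in range(config.n_pop_samples)]
    pop_of = pd.Series(
        [p for p in pops for _ in range(config.n_pop_samples)], index=sample_ids, name="pop"
    )
    geno = np.zeros((len(variants), len(sample_ids)), dtype=int)
    for p_i, p in enumerate(pops):
        af = variants[f"af_{p}"].to_numpy(dtype=float)
        block = rng.binomial(2, af[:, None], size=(len(variants), config.n_pop_samples))
        geno[:, p_i * config.n_pop_samples : (p_i + 1) * config.n_pop_samples] = block
    genotypes = pd.DataFrame(geno, index=variants.index, columns=sample_ids)

    causal = [c for c in truth.causal_variants]
    n_gwas = int(round(config.gwas_fraction * len(causal)))
    gwas_rows = []
    for i, c in enumerate(causal[:n_gwas]):
        offset = int(rng.integers(2000, 15000))
        start1 = max(1, c["pos"] + offset)
        gwas_rows.append(
            {"chrom": "chrS", "start": start1 - 1, "end": start1 + 999, "name": f"locus{i + 1}"}
        )
    for j in range(2):  # decoy loci far from any gene
        start1 = chrom_end + 200000 + j * 50000
        gwas_rows.append(
            {"chrom": "chrS", "start": start1 - 1, "end": start1 + 999, "name": f"decoy{j + 1}"}
        )
    gwas_loci = pd.DataFrame(gwas_rows)

    n_assay = len(causal)
    n_conc = int(round(config.concordance * n_assay))
    flip = set(rng.permutation(n_assay)[n_conc:])
    assay_rows = []
    for i, c in enumerate(causal):
        direction = c["direction"]
        if i in flip:
            direction = "down" if direction == "up" else "up"
        assay_rows.append({"variant_id": c["variant_id"], "gene": c["gene"], "direction": direction})
    assay_table = pd.DataFrame(assay_rows).set_index("variant_id")
    return SimulatedPopulation(variants, genotypes, pop_of, gwas_loci, assay_table)


def simulate_fold_changes(
    n_background: int,
    n_reinforcing: int,
    n_compensatory: int,
    effect: float = 2.0,
    sd: float = 0.5,
    correlation: float = 0.6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Direct (mRNA, RPF) log2 fold-change draw for classifier studies.

    All genes carry the bivariate-normal background variation (common
    ``sd``, the given correlation); planted reinforcing genes additionally
    receive same-sign effects of magnitude ``effect`` (random sign per
    gene) in both layers, compensatory genes opposite-sign effects.
    Returns (m, r, labels).
    """
    rng = np.random.default_rng(seed)
    cov = sd * sd * np.array([[1.0, correlation], [correlation, 1.0]])
    bg = rng.multivariate_normal([0.0, 0.0], cov, size=n_background)
    signs_re = rng.choice([-1.0, 1.0], size=n_reinforcing)
    signs_co = rng.choice([-1.0, 1.0], size=n_compensatory)
    re = np.column_stack([signs_re * effect, signs_re * effect]) + rng.multivariate_normal(
        [0.0, 0.0], cov, size=n_reinforcing
    )
    co = np.column_stack([signs_co * effect, -signs_co * effect]) + rng.multivariate_normal(
        [0.0, 0.0], cov, size=n_compensatory
    )
    m = np.concatenate([bg[:, 0], re[:, 0], co[:, 0]])
    r = np.concatenate([bg[:, 1], re[:, 1], co[:, 1]])
    labels = np.array(
        ["background"] * n_background
        + ["reinforcing"] * n_reinforcing
        + ["compensatory"] * n_compensatory
    )
    return m, r, labels
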