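"""Population-genetic prioritization of 5'UTR translational variants.

Biallelic variants are filtered on pooled minor-allele frequency and
missingness, per-population alternate-allele frequencies give a
differentiation score (delta-AF between the two breeds), and candidates
are required to fall in the 5'UTR of a differential-TE gene from the
fused-network target set and to be anchored either by a GWAS locus within
a +/-20 kb window or by a known regulator gene. Reporter flanks for
luciferase constructs and direction-concordance bookkeeping against assay
results complete the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # genotype code for missing calls (else 0/1/2 alt-allele dosage)


@dataclass
class VariantTable:
    """Biallelic variant records plus a genotype dosage matrix.

    ``records``: DataFrame with columns chrom, pos (1-based), ref, alt,
    variant_id. ``genotypes``: variants x samples alt-allele dosages in
    {0, 1, 2} with -1 for missing. ``pop_of`` maps sample -> population.
    """

    records: pd.DataFrame
    genotypes: pd.DataFrame
    pop_of: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.records = self.records.set_index(
            pd.Index(self.records["variant_id"], name="variant_id"), drop=False
        ) if "variant_id" in self.records.columns else self.records
        self.genotypes = self.genotypes.reindex(self.records.index)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_snp(self) -> pd.Series:
        return (self.records["ref"].str.len() == 1) & (self.records["alt"].str.len() == 1)


def read_vcf(path: str, pop_of: pd.Series | None = None) -> VariantTable:
    """Read biallelic records from a VCF (v4.2) into a :class:`VariantTable`."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    recs, gts = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        vid = v.ID if v.ID not in (None, ".") else f"{v.CHROM}_{v.POS}"
        recs.append((v.CHROM, v.POS, v.REF, v.ALT[0], vid))
        g = v.gt_types.astype(int)  # 0/1/2 dosage, 3 = unknown
        gts.append(np.where(g == 3, MISSING, g))
    records = pd.DataFrame(recs, columns=["chrom", "pos", "ref", "alt", "variant_id"])
    genotypes = pd.DataFrame(np.array(gts, dtype=int), columns=samples)
    genotypes.index = pd.Index(records["variant_id"], name="variant_id")
    return VariantTable(records, genotypes, pop_of)


def _af_missing(genotypes: pd.DataFrame) -> tuple[pd.Series, pd.Series, pd.Series]:
    g = genotypes.to_numpy(dtype=float)
    miss = g == MISSING
    called = (~miss).sum(axis=1)
    alt = np.where(miss, 0, g).sum(axis=1)
    af = np.divide(alt, 2 * called, out=np.full(len(g), np.nan), where=called > 0)
    idx = genotypes.index
    return (
        pd.Series(af, index=idx, name="af"),
        pd.Series(np.minimum(af, 1 - af), index=idx, name="maf"),
        pd.Series(miss.mean(axis=1), index=idx, name="missing_rate"),
    )


def filter_variants(
    table: VariantTable, maf_min: float = 0.05, miss_max: float = 0.2
) -> VariantTable:
    """Keep records with pooled MAF >= ``maf_min`` and missing-genotype
    fraction <= ``miss_max`` (both boundaries inclusive). MAF is computed
    over non-missing alleles with the two populations pooled; fully
    missing records are dropped."""
    _, maf, miss = _af_missing(table.genotypes)
    keep = maf.notna() & (maf >= maf_min) & (miss <= miss_max)
    return VariantTable(
        table.records.loc[keep].copy(), table.genotypes.loc[keep].copy(), table.pop_of
    )


def population_af(table: VariantTable, pop_of: pd.Series | None = None) -> pd.DataFrame:
    """Alternate-allele frequency per population.

    AF = alt allele count / non-missing allele count; missing where a
    population has no genotyped sample at the record.
    """
    pop_of = pop_of if pop_of is not None else table.pop_of
    if pop_of is None:
        raise ValueError("population assignment required")
    cols = {}
    for pop in sorted(pop_of.dropna().unique()):
        samples = [s for s in table.genotypes.columns if pop_of.get(s) == pop]
        af, _, _ = _af_missing(table.genotypes[samples])
        cols[pop] = af
    return pd.DataFrame(cols)


def differentiated_variants(
    afs: pd.DataFrame, threshold: float = 0.3, pops: tuple[str, str] | None = None
) -> list[str]:
    """Variants with |AF_A - AF_B| strictly above ``threshold``; records
    missing either AF are skipped."""
    a, b = pops if pops is not None else tuple(afs.columns[:2])
    delta = (afs[a] - afs[b]).abs()
    return list(afs.index[delta.notna() & (delta > threshold)])


def _utr5_hit(models, chrom: str, pos: int) -> str | None:
    for model in models.values():
        if model.utr5 is None or model.chrom != chrom:
            continue
        lo, hi = model.utr5
        if lo <= pos <= hi:
            return model.gene_id
    return None


def _gwas_distance(gwas: pd.DataFrame, chrom: str, pos: int) -> float:
    """Distance to the nearest base of any locus (BED half-open input)."""
    sub = gwas[gwas["chrom"] == chrom]
    if sub.empty:
        return np.inf
    start1 = sub["start"].to_numpy() + 1  # 1-based first base
    end1 = sub["end"].to_numpy()
    d = np.where(pos < start1, start1 - pos, np.where(pos > end1, pos - end1, 0))
    return float(d.min())


def annotate_candidates(
    table: VariantTable,
    models: dict,
    detg_submf_genes,
    gwas_loci: pd.DataFrame,
    regulator_genes,
    afs: pd.DataFrame | None = None,
    pops: tuple[str, str] | None = None,
    delta_af_min: float = 0.3,
    window: int = 20000,
    snps_only: bool = True,
) -> pd.DataFrame:
    """Annotate variants with all prioritization gates and the candidate flag.

    A candidate lies in the 5'UTR of a differential-TE gene from the
    fused sub-network, has delta-AF > ``delta_af_min`` between the two
    populations, and is within ``window`` bp (inclusive) of a GWAS locus
    or inside a known regulator gene.
    """
    known_chroms = {m.chrom for m in models.values()} | set(gwas_loci["chrom"])
    bad = sorted(set(table.records["chrom"]) - known_chroms)
    if bad:
        raise ValueError(f"chromosome names absent from annotation: {bad}")
    if afs is None:
        afs = population_af(table)
    a, b = pops if pops is not None else tuple(afs.columns[:2])
    detg_submf_genes = set(detg_submf_genes)
    regulator_genes = set(regulator_genes)
    rows = []
    for vid, rec in table.records.iterrows():
        if snps_only and not (len(rec["ref"]) == 1 and len(rec["alt"]) == 1):
            continue
        gene = _utr5_hit(models, rec["chrom"], rec["pos"])
        delta = abs(afs.loc[vid, a] - afs.loc[vid, b]) if vid in afs.index else np.nan
        gwas_near = _gwas_distance(gwas_loci, rec["chrom"], rec["pos"]) <= window
        known_reg = gene in regulator_genes if gene else False
        in_submf = gene in detg_submf_genes if gene else False
        candidate = (
            gene is not None
            and in_submf
            and np.isfinite(delta)
            and delta > delta_af_min
            and (gwas_near or known_reg)
        )
        rows.append(
            {
                "variant_id": vid,
                "chrom": rec["chrom"],
                "pos": rec["pos"],
                "gene": gene,
                "in_utr5": gene is not None,
                "delta_af": delta,
                "gwas_within_window": gwas_near,
                "known_regulator_gene": known_reg,
                "detg_in_submf": in_submf,
                "candidate": candidate,
            }
        )
    return pd.DataFrame(rows).set_index("variant_id")


def reporter_flank(
    variant: pd.Series, model, flank: int = 50
) -> tuple[str, str]:
    """Reference and alternate reporter sequences around a 5'UTR SNP.

    Extends ``flank`` bp up- and downstream of the variant and clips to
    the 5'UTR boundaries, so the output is at most 2*flank + 1 nt. The two
    sequences differ only at the variant base.
    """
    if model.utr5 is None:
        raise ValueError("model has no 5'UTR")
    lo, hi = model.utr5
    pos = int(variant["pos"])
    if not (lo <= pos <= hi) or model.chrom != variant["chrom"]:
        raise ValueError("variant outside the model's 5'UTR")
    off = pos - lo  # 0-based offset into the 5'UTR sequence
    seq = model.utr5_seq
    if seq[off].upper() != str(variant["ref"]).upper():
        raise ValueError("reference allele mismatch with 5'UTR sequence")
    start = max(0, off - flank)
    end = min(len(seq), off + flank + 1)
    ref_seq = seq[start:end]
    alt_seq = seq[start:off] + str(variant["alt"]) + seq[off + 1 : end]
    return ref_seq, alt_seq


def assess_concordance(
    assay_table: pd.DataFrame,
    breed_te_direction: pd.Series,
    afs: pd.DataFrame,
    pops: tuple[str, str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """Direction concordance between reporter assays and breed allele/TE data.

    ``assay_table`` needs columns gene and direction ("up" = alternate
    allele raises luciferase TE, "down" = lowers, "ns" = no significant
    effect), indexed by variant id. ``breed_te_direction`` maps gene ->
    the population with the higher tissue TE. A variant is concordant when
    the allele with the higher assay TE is the more frequent allele in the
    higher-TE population. Variants with equal population AFs are
    undetermined and excluded; the rate is 100 * concordant / assayed,
    over variants with a significant assay direction.
    """
    a, b = pops if pops is not None else tuple(afs.columns[:2])
    rows = []
    for vid, rec in assay_table.iterrows():
        direction = rec["direction"]
        status = "not_assayed"
        if direction in ("up", "down"):
            gene = rec["gene"]
            high_pop = breed_te_direction.get(gene)
            if high_pop is None or vid not in afs.index:
                status = "undetermined"
            else:
                af_high = afs.loc[vid, high_pop]
                af_low = afs.loc[vid, b if high_pop == a else a]
                if not (np.isfinite(af_high) and np.isfinite(af_low)) or af_high == af_low:
                    status = "undetermined"
                else:
                    alt_favored = af_high > af_low
                    up = direction == "up"
                    status = "concordant" if (alt_favored == up) else "discordant"
        rows.append({"variant_id": vid, "direction": direction, "status": status})
    out = pd.DataFrame(rows).set_index("variant_id")
    assayed = out["status"].isin(["concordant", "discordant"])
    n_assayed = int(assayed.sum())
    rate = 100.0 * (out["status"] == "concordant").sum() / n_assayed if n_assayed else np.nan
    return out, float(rate)


def concordance_rate(n_concordant: int, n_assayed: int) -> float:
    """Concordance rate in percent: 100 * concordant / assayed."""
    if n_assayed <= 0:
        raise ValueError("no assayed variants")
    return 100.0 * n_concordant / n_assayed
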