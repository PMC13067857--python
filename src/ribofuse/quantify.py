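"""Normalization and translation-efficiency quantification for paired
RNA-seq / Ribo-seq count matrices.

Counts from both modalities are pooled for size-factor estimation
(median-of-ratios on the combined matrix), normalized counts are converted
to TPM, and TE is the per-replicate ratio of RPF TPM to RNA TPM over the
CDS, restricted to genes passing the detectability rule in both modalities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RNA = "RNA"
RPF = "RPF"

SAMPLE_COLUMNS = ["sample_id", "tissue", "breed", "replicate", "modality"]


@dataclass
class CountMatrix:
    """Gene-by-sample integer counts with a sample sheet.

    ``values`` is genes x samples (columns = sample ids); ``samples`` has one
    row per column of ``values`` with columns sample_id / tissue / breed /
    replicate / modality.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative counts")
        ids = list(self.samples["sample_id"])
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids")
        if list(self.values.columns) != ids:
            raise ValueError("sample sheet does not match count columns")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def subset_samples(self, mask: pd.Series | np.ndarray) -> "CountMatrix":
        samples = self.samples.loc[np.asarray(mask)].reset_index(drop=True)
        return CountMatrix(self.values[list(samples["sample_id"])], samples)

    def for_modality(self, modality: str) -> "CountMatrix":
        return self.subset_samples((self.samples["modality"] == modality).to_numpy())

    def for_tissue(self, tissue: str) -> "CountMatrix":
        if tissue not in set(self.samples["tissue"]):
            raise ValueError(f"unknown tissue: {tissue}")
        return self.subset_samples((self.samples["tissue"] == tissue).to_numpy())


@dataclass
class ExpressionMatrix:
    """TPM matrix plus the size factors and gene lengths used to build it."""

    tpm: pd.DataFrame
    size_factors: pd.Series
    lengths: pd.Series
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]


@dataclass
class TEMatrix:
    """Per-replicate translation efficiency (RPF TPM / RNA TPM).

    ``te`` columns are (tissue, breed, replicate) tuples; NaN marks genes
    failing detectability in either modality or with zero RNA signal.
    ``detect_mask`` is indexed by gene with one boolean column per
    (tissue, modality).
    """

    te: pd.DataFrame
    detect_mask: pd.DataFrame


def pooled_size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors on the pooled matrix.

    The reference is the per-gene geometric mean over all samples; genes
    with a zero anywhere are excluded from the reference. Each sample's
    factor is the median over reference genes of count / reference.
    """
    values = counts.values if isinstance(counts, CountMatrix) else counts
    arr = values.to_numpy(dtype=float)
    ref_rows = (arr > 0).all(axis=1)
    if not ref_rows.any():
        raise ValueError("no reference genes: every gene has a zero in some sample")
    log_ref = np.log(arr[ref_rows]).mean(axis=1)
    ratios = np.log(arr[ref_rows]) - log_ref[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=values.columns, name="size_factor")


def tpm(
    counts: CountMatrix | pd.DataFrame,
    lengths: pd.Series,
    size_factors: pd.Series | None = None,
) -> ExpressionMatrix:
    """Size-factor-normalized counts converted to transcripts per million.

    normalized = count / factor; rate = normalized / (length / 1000);
    TPM = rate / sum(rate) * 1e6 per sample.
    """
    is_cm = isinstance(counts, CountMatrix)
    values = counts.values if is_cm else counts
    lengths = lengths.reindex(values.index)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValueError("all genes need a positive length")
    if size_factors is None:
        size_factors = pooled_size_factors(values)
    size_factors = size_factors.reindex(values.columns)
    norm = values.to_numpy(dtype=float) / size_factors.to_numpy()[None, :]
    rate = norm / (lengths.to_numpy()[:, None] / 1000.0)
    totals = rate.sum(axis=0)
    if (totals == 0).any():
        bad = values.columns[totals == 0].tolist()
        raise ValueError(f"zero total rate in samples: {bad}")
    out = pd.DataFrame(rate / totals[None, :] * 1e6, index=values.index, columns=values.columns)
    return ExpressionMatrix(out, size_factors, lengths, counts.samples if is_cm else None)


def detectable_genes(
    counts: CountMatrix,
    tissue: str,
    min_total: int = 10,
    min_samples: int = 2,
) -> pd.Series:
    """Detectability rule: replicate total > ``min_total`` and nonzero counts
    in at least ``min_samples`` replicates within the tissue."""
    sub = counts.for_tissue(tissue)
    if sub.values.shape[1] < min_samples:
        raise ValueError(f"tissue {tissue} has fewer than {min_samples} samples")
    arr = sub.values.to_numpy()
    return pd.Series(
        (arr.sum(axis=1) > min_total) & ((arr > 0).sum(axis=1) >= min_samples),
        index=counts.genes,
        name=tissue,
    )


def detectability_masks(
    counts: CountMatrix, min_total: int = 10, min_samples: int = 2
) -> pd.DataFrame:
    """Per-(tissue, breed, modality) detectability, ANDed over breeds so a
    gene is tissue-detectable only if each breed's replicates pass."""
    cols = {}
    for (tissue, modality), grp in counts.samples.groupby(["tissue", "modality"], sort=True):
        sub = counts.subset_samples(counts.samples.index.isin(grp.index).astype(bool))
        per_breed = []
        for _, breed_grp in sub.samples.groupby("breed", sort=True):
            b = sub.subset_samples(sub.samples.index.isin(breed_grp.index))
            per_breed.append(detectable_genes(b, tissue, min_total, min_samples))
        cols[(tissue, modality)] = np.logical_and.reduce(per_breed)
    out = pd.DataFrame(cols, index=counts.genes)
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["tissue", "modality"])
    return out


def compute_te(
    rna: ExpressionMatrix,
    rpf: ExpressionMatrix,
    masks: pd.DataFrame | None = None,
) -> TEMatrix:
    """TE = RPF TPM / RNA TPM per gene per (tissue, breed, replicate).

    RNA and RPF samples are matched on (tissue, breed, replicate); a
    mismatch is an error. TE is missing wherever the detectability mask
    fails for either modality in that tissue, or RNA TPM is zero.
    """
    if rna.samples is None or rpf.samples is None:
        raise ValueError("expression matrices need sample sheets to match modalities")
    key = ["tissue", "breed", "replicate"]
    rna_keys = rna.samples.set_index(key)["sample_id"]
    rpf_keys = rpf.samples.set_index(key)["sample_id"]
    if sorted(rna_keys.index) != sorted(rpf_keys.index):
        raise ValueError("RNA and RPF samples do not match on (tissue, breed, replicate)")
    cols = {}
    for cond in rna_keys.index:
        num = rpf.tpm[rpf_keys.loc[cond]].to_numpy(dtype=float)
        den = rna.tpm[rna_keys.loc[cond]].to_numpy(dtype=float)
        te = np.divide(num, den, out=np.full(len(den), np.nan), where=den > 0)
        if masks is not None:
            tissue = cond[0]
            ok = masks[(tissue, RNA)].to_numpy() & masks[(tissue, RPF)].to_numpy()
            te = np.where(ok, te, np.nan)
        cols[cond] = te
    te_df = pd.DataFrame(cols, index=rna.tpm.index)
    te_df.columns = pd.MultiIndex.from_tuples(te_df.columns, names=key)
    mask_df = masks if masks is not None else pd.DataFrame(index=rna.tpm.index)
    return TEMatrix(te_df, mask_df)


def active_orf_mask(
    orf_rna: CountMatrix,
    orf_rpf: CountMatrix,
    tissue: str,
    min_total: int = 10,
    min_samples: int = 2,
) -> pd.Series:
    """Actively translated ORFs: the detectability rule must pass at both the
    transcriptional and translational level in the tissue."""
    rna_ok = detectable_genes(orf_rna, tissue, min_total, min_samples)
    rpf_ok = detectable_genes(orf_rpf, tissue, min_total, min_samples)
    return (rna_ok & rpf_ok).rename(tissue)
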