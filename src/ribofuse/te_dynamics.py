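"""TE dynamics across tissues and breeds.

Range of the TE distribution (97.5% / 2.5% quantile ratio), the per-gene
mRNA-TE correlation with a gene-shuffling null, and threshold-based
differential TE / differential expression calls (Welch t-test on log
values with BH correction; deliberately simple stand-ins for shrinkage
estimators, labeled as such in their outputs).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quantify import tpm as _tpm


@dataclass
class TERangeResult:
    q_low: float
    q_high: float
    range_ratio: float


@dataclass
class DifferentialResult:
    """Per-gene differential table with threshold-based calls.

    ``table`` columns: log2fc, p, fdr, called. ``method`` records the test
    used (welch-log stand-in).
    """

    table: pd.DataFrame
    method: str
    lfc_min: float
    fdr_max: float

    @property
    def called(self) -> list[str]:
        return list(self.table.index[self.table["called"]])


def te_range(te_values, q: float = 0.025) -> TERangeResult:
    """Ratio of the (1-q) to the q quantile of TE (type-7 interpolation)."""
    vals = np.asarray(pd.Series(te_values).dropna(), dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 TE values")
    q_low, q_high = np.quantile(vals, [q, 1.0 - q])  # numpy default = type 7
    if q_low <= 0:
        raise ValueError("lower quantile is not positive; ratio undefined")
    return TERangeResult(float(q_low), float(q_high), float(q_high / q_low))


def gene_te_mrna_correlation(
    te_by_tissue: pd.DataFrame,
    rna_by_tissue: pd.DataFrame,
    min_tissues: int = 3,
) -> pd.Series:
    """Per-gene Pearson r between TE and RNA abundance across tissue means.

    Computed on linear values. Missing for genes observed in fewer than
    ``min_tissues`` tissues or with zero variance in either vector.
    """
    tissues = [t for t in te_by_tissue.columns if t in set(rna_by_tissue.columns)]
    genes = te_by_tissue.index.intersection(rna_by_tissue.index)
    te = te_by_tissue.loc[genes, tissues].to_numpy(dtype=float)
    rna = rna_by_tissue.loc[genes, tissues].to_numpy(dtype=float)
    out = np.full(len(genes), np.nan)
    for i in range(len(genes)):
        ok = np.isfinite(te[i]) & np.isfinite(rna[i])
        if ok.sum() < min_tissues:
            continue
        x, y = te[i, ok], rna[i, ok]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        out[i] = np.corrcoef(x, y)[0, 1]
    return pd.Series(out, index=genes, name="r")


def shuffle_null(
    rna_counts: pd.DataFrame,
    rpf_counts: pd.DataFrame,
    lengths: pd.Series,
    tissue_of: pd.Series,
    seed: int = 0,
    n_shuffles: int = 1,
    min_tissues: int = 3,
    permutation: np.ndarray | None = None,
) -> dict:
    """Gene-shuffling null for the mRNA-TE correlation distribution.

    Ribo-seq counts are permuted across genes (same permutation for every
    sample), TE is recomputed from TPM tissue means against the intact
    RNA-seq counts, and the resulting per-gene correlation distribution is
    compared to the observed one with a two-sample KS test. Columns of the
    two count matrices must match; ``tissue_of`` maps sample id -> tissue.
    """
    if list(rna_counts.columns) != list(rpf_counts.columns):
        raise ValueError("RNA and RPF matrices must share columns")
    rng = np.random.default_rng(seed)

    def corr_distribution(rpf_mat: pd.DataFrame) -> pd.Series:
        rna_tpm = _tpm(rna_counts, lengths).tpm
        rpf_tpm = _tpm(rpf_mat, lengths).tpm
        rna_mean = rna_tpm.T.groupby(tissue_of).mean().T
        rpf_mean = rpf_tpm.T.groupby(tissue_of).mean().T
        te = rpf_mean / rna_mean.replace(0, np.nan)
        return gene_te_mrna_correlation(te, rna_mean, min_tissues).dropna()

    observed = corr_distribution(rpf_counts)
    null_parts = []
    for _ in range(n_shuffles):
        perm = permutation if permutation is not None else rng.permutation(len(rpf_counts))
        shuffled = pd.DataFrame(
            rpf_counts.to_numpy()[perm], index=rpf_counts.index, columns=rpf_counts.columns
        )
        null_parts.append(corr_distribution(shuffled))
    null = pd.concat(null_parts)
    ks = stats.ks_2samp(observed.to_numpy(), null.to_numpy())
    return {
        "observed_r": observed,
        "null_r": null,
        "ks_stat": float(ks.statistic),
        "ks_p": float(ks.pvalue),
    }


def _welch_bh_calls(
    log_a: np.ndarray,
    log_b: np.ndarray,
    index: pd.Index,
    method: str,
    lfc_min: float,
    fdr_max: float,
) -> DifferentialResult:
    log2fc = log_a.mean(axis=1) - log_b.mean(axis=1)
    t, p = stats.ttest_ind(log_a, log_b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    fdr = multipletests(p, method="fdr_bh")[1]
    called = (np.abs(log2fc) > lfc_min) & (fdr < fdr_max)
    table = pd.DataFrame(
        {"log2fc": log2fc, "p": p, "fdr": fdr, "called": called}, index=index
    )
    return DifferentialResult(table, method, lfc_min, fdr_max)


def differential_te(
    te: pd.DataFrame,
    breed_of: pd.Series,
    breeds: tuple[str, str],
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> DifferentialResult:
    """Differential TE between breeds: Welch t-test on log2(TE), BH FDR,
    called at |log2FC| > lfc_min and FDR < fdr_max.

    ``te`` columns are replicate samples; ``breed_of`` maps column -> breed.
    Genes with a zero or missing TE in any replicate are excluded.
    """
    cols_a = [c for c in te.columns if breed_of[c] == breeds[0]]
    cols_b = [c for c in te.columns if breed_of[c] == breeds[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per breed")
    sub = te[cols_a + cols_b]
    keep = (sub > 0).all(axis=1) & sub.notna().all(axis=1)
    sub = sub[keep]
    return _welch_bh_calls(
        np.log2(sub[cols_a].to_numpy(dtype=float)),
        np.log2(sub[cols_b].to_numpy(dtype=float)),
        sub.index,
        "welch-log2TE (stand-in)",
        lfc_min,
        fdr_max,
    )


def differential_expression(
    tpm_mat: pd.DataFrame,
    breed_of: pd.Series,
    breeds: tuple[str, str],
    lfc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> DifferentialResult:
    """Differential expression between breeds on log2(TPM + 1); same test
    and thresholds as :func:`differential_te`."""
    cols_a = [c for c in tpm_mat.columns if breed_of[c] == breeds[0]]
    cols_b = [c for c in tpm_mat.columns if breed_of[c] == breeds[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need at least 2 replicates per breed")
    return _welch_bh_calls(
        np.log2(tpm_mat[cols_a].to_numpy(dtype=float) + 1.0),
        np.log2(tpm_mat[cols_b].to_numpy(dtype=float) + 1.0),
        tpm_mat.index,
        "welch-log2TPM (stand-in)",
        lfc_min,
        fdr_max,
    )


def detg_deg_enrichment(detg_set, deg_set, background) -> "EnrichmentResult":
    """Hypergeometric enrichment of differential-TE genes within
    differential-expression genes (delegates to the GRN module's test)."""
    from .grn import hypergeom_enrichment

    return hypergeom_enrichment(detg_set, deg_set, background)


from .grn import EnrichmentResult  # noqa: E402  (re-export for type hint)
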