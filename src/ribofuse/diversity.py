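"""Expression diversity metrics: between-sample divergence, replicate
variability, tissue specificity, and cross-layer correlation."""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def euclidean_divergence(x, y, gene_set=None) -> float:
    """Root-mean-squared deviation of log2(TPM + 1) between two samples.

    D(x, y) = sqrt( (1/N) * sum_i (log2(x_i + 1) - log2(y_i + 1))^2 )
    over the N genes of ``gene_set`` (all shared genes when omitted).
    """
    x = pd.Series(x, dtype=float) if not isinstance(x, pd.Series) else x.astype(float)
    y = pd.Series(y, dtype=float) if not isinstance(y, pd.Series) else y.astype(float)
    if gene_set is not None:
        gene_set = list(gene_set)
        x, y = x.reindex(gene_set), y.reindex(gene_set)
    else:
        y = y.reindex(x.index)
    if len(x) == 0:
        raise ValueError("empty gene set")
    d = np.log2(x.to_numpy() + 1.0) - np.log2(y.to_numpy() + 1.0)
    return float(np.sqrt(np.mean(d * d)))


def pairwise_divergence(
    expr: pd.DataFrame,
    grouping: pd.Series,
    gene_set=None,
) -> pd.DataFrame:
    """All replicate-combination divergences between every pair of groups.

    ``grouping`` maps sample id -> group (e.g. tissue). For two groups with
    three replicates each this yields the 3x3 = 9 combinations per pair.
    """
    groups = sorted(grouping.dropna().unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    rows = []
    for ga, gb in combinations(groups, 2):
        for sa in grouping.index[grouping == ga]:
            for sb in grouping.index[grouping == gb]:
                rows.append(
                    {
                        "group_a": ga,
                        "group_b": gb,
                        "sample_a": sa,
                        "sample_b": sb,
                        "D": euclidean_divergence(expr[sa], expr[sb], gene_set),
                    }
                )
    return pd.DataFrame(rows)


def gene_cv(expr: pd.DataFrame, sample_ids=None) -> pd.Series:
    """Coefficient of variation across replicates on TPM: sd (ddof=1) / mean.

    Missing where the replicate mean is zero.
    """
    sub = expr[list(sample_ids)] if sample_ids is not None else expr
    if sub.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    arr = sub.to_numpy(dtype=float)
    mean = arr.mean(axis=1)
    sd = arr.std(axis=1, ddof=1)
    cv = np.divide(sd, mean, out=np.full(len(mean), np.nan), where=mean > 0)
    return pd.Series(cv, index=sub.index, name="cv")


@dataclass
class SpecificityIndex:
    """Tau tissue-specificity per gene plus the tissue-specific gene call."""

    tsi: pd.Series
    assigned_tissue: pd.Series
    threshold: float = 0.9

    def specific_genes(self, tissue: str | None = None) -> list[str]:
        mask = self.tsi > self.threshold
        if tissue is not None:
            mask &= self.assigned_tissue == tissue
        return list(self.tsi.index[mask.fillna(False)])


def tsi(expr_mean_by_tissue: pd.DataFrame, threshold: float = 0.9) -> SpecificityIndex:
    """Tissue specificity index (tau) on log2(TPM + 1) tissue means.

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1); 1 = expressed in a single
    tissue, 0 = uniform. Genes above ``threshold`` are assigned to their
    argmax tissue. All-zero genes get a missing index.
    """
    if expr_mean_by_tissue.shape[1] < 2:
        raise ValueError("need at least 2 tissues")
    x = np.log2(expr_mean_by_tissue.to_numpy(dtype=float) + 1.0)
    mx = x.max(axis=1)
    n = x.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        tau = (1.0 - x / mx[:, None]).sum(axis=1) / (n - 1)
    tau = np.where(mx > 0, tau, np.nan)
    assigned = expr_mean_by_tissue.columns.to_numpy()[x.argmax(axis=1)]
    idx = expr_mean_by_tissue.index
    return SpecificityIndex(
        pd.Series(tau, index=idx, name="tsi"),
        pd.Series(assigned, index=idx, name="tissue").where(pd.Series(tau, index=idx).notna()),
        threshold,
    )


def cross_layer_correlation(
    a: pd.DataFrame | pd.Series,
    b: pd.DataFrame | pd.Series,
    scope: str = "within_sample",
) -> tuple[pd.Series, float]:
    """Pearson correlation between two expression layers on log2(x + 1).

    ``within_sample``: one r per shared column, across genes (e.g. RPF vs
    protein in each sample). ``across_tissue``: one r per gene across the
    shared columns (tissue means). Returns (r values, median r).
    """
    if scope not in ("within_sample", "across_tissue"):
        raise ValueError(f"unknown scope: {scope}")
    a = a.to_frame() if isinstance(a, pd.Series) else a
    b = b.to_frame() if isinstance(b, pd.Series) else b
    genes = a.index.intersection(b.index)
    cols = [c for c in a.columns if c in set(b.columns)]
    if len(genes) < 3:
        raise ValueError("need at least 3 shared genes")
    la = np.log2(a.loc[genes, cols].to_numpy(dtype=float) + 1.0)
    lb = np.log2(b.loc[genes, cols].to_numpy(dtype=float) + 1.0)
    if scope == "within_sample":
        rs = pd.Series(_columnwise_r(la, lb), index=cols, name="r")
    else:
        rs = pd.Series(_columnwise_r(la.T, lb.T), index=genes, name="r")
    return rs, float(rs.median(skipna=True))


def _columnwise_r(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson r per column; NaN where either column has zero variance."""
    a = a - a.mean(axis=0)
    b = b - b.mean(axis=0)
    num = (a * b).sum(axis=0)
    den = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    return np.divide(num, den, out=np.full(a.shape[1], np.nan), where=den > 0)
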