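"""Cross-breed translational coupling: reinforcing vs compensatory genes.

A gene's mRNA and RPF log2 fold changes between breeds are projected onto
the diagonals u = (m + r)/sqrt(2) and v = (m - r)/sqrt(2). Reinforcing
(translational amplification) genes move in the same direction in both
layers and lie beyond two standard deviations along y = x; compensatory
(translational buffering) genes move in opposite directions beyond two
standard deviations along y = -x. A ratio filter keeps only genes where
both layers contribute comparably. Enrichment of either category is tested
against a permutation null in which the RPF fold changes are deranged
across genes and rescaled to match the observed mean, standard deviation,
and correlation with the mRNA fold changes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

SQRT2 = np.sqrt(2.0)

REINFORCING = "reinforcing"
COMPENSATORY = "compensatory"
NONE = "none"


@dataclass
class FoldChangeTable:
    """Per-gene mRNA (m) and RPF (r) log2 fold changes with diagonal
    projections and interaction class labels."""

    m: pd.Series
    r: pd.Series
    u: pd.Series = field(init=False)
    v: pd.Series = field(init=False)
    s_u: float = field(init=False)
    s_v: float = field(init=False)
    classes: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        self.r = self.r.reindex(self.m.index)
        self.u = ((self.m + self.r) / SQRT2).rename("u")
        self.v = ((self.m - self.r) / SQRT2).rename("v")
        self.s_u = float(np.nan)
        self.s_v = float(np.nan)
        self.classes = pd.Series(NONE, index=self.m.index, name="class")


@dataclass
class PermutationResult:
    B: int
    observed: dict[str, int]
    null_counts: pd.DataFrame
    p: dict[str, float]
    alpha: float
    seed: int

    def significant(self, category: str) -> bool:
        return self.p[category] < self.alpha


def breed_log2fc(
    tpm: pd.DataFrame,
    samples: pd.DataFrame,
    tissue: str,
    modality: str,
    breeds: tuple[str, str],
    detectable: pd.Series | None = None,
) -> pd.Series:
    """log2((mean TPM breed A + 1) / (mean TPM breed B + 1)) within a tissue."""
    means = []
    for breed in breeds:
        sel = samples[
            (samples["tissue"] == tissue)
            & (samples["breed"] == breed)
            & (samples["modality"] == modality)
        ]
        if sel.empty:
            raise ValueError(f"no samples for breed {breed} in tissue {tissue}")
        means.append(tpm[list(sel["sample_id"])].mean(axis=1))
    fc = np.log2((means[0] + 1.0) / (means[1] + 1.0)).rename("log2fc")
    if detectable is not None:
        fc = fc.where(detectable.reindex(fc.index).fillna(False))
    return fc


def _classify_arrays(
    m: np.ndarray,
    r: np.ndarray,
    sd_mult: float,
    ratio_bound: float,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Vectorized classifier; returns (reinforcing mask, compensatory mask,
    s_u, s_v). SDs are computed over all finite genes."""
    u = (m + r) / SQRT2
    v = (m - r) / SQRT2
    s_u = float(np.std(u, ddof=1))
    s_v = float(np.std(v, ddof=1))
    both_nonzero = (m != 0) & (r != 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_ok = np.abs(np.log10(np.abs(m / r))) < ratio_bound
    ratio_ok = np.where(both_nonzero, ratio_ok, False)
    same_sign = both_nonzero & (np.sign(m) == np.sign(r))
    reinf = same_sign & (np.abs(u) > sd_mult * s_u) & ratio_ok
    comp = both_nonzero & (np.sign(m) != np.sign(r)) & (np.abs(v) > sd_mult * s_v) & ratio_ok
    return reinf, comp, s_u, s_v


def classify_interactions(
    fc: FoldChangeTable,
    sd_mult: float = 2.0,
    ratio_bound: float = 0.5,
) -> FoldChangeTable:
    """Label genes reinforcing / compensatory / none (in place, returned).

    Reinforcing: sign(m) = sign(r), |u| > sd_mult * s_u, and the ratio
    filter |log10(|m / r|)| < ratio_bound holds. Compensatory: opposite
    signs, |v| > sd_mult * s_v, same filter. s_u and s_v are SDs of the
    projections over all finite genes.
    """
    finite = np.isfinite(fc.m) & np.isfinite(fc.r)
    if finite.sum() < 3:
        raise ValueError("need at least 3 genes with finite fold changes")
    m = fc.m[finite].to_numpy(dtype=float)
    r = fc.r[finite].to_numpy(dtype=float)
    reinf, comp, s_u, s_v = _classify_arrays(m, r, sd_mult, ratio_bound)
    labels = np.where(reinf, REINFORCING, np.where(comp, COMPENSATORY, NONE))
    fc.s_u, fc.s_v = s_u, s_v
    fc.classes = pd.Series(NONE, index=fc.m.index, name="class")
    fc.classes[fc.m.index[finite]] = labels
    return fc


def _derangement(n: int, rng: np.random.Generator, max_tries: int = 100) -> np.ndarray:
    """Uniform-ish derangement by rejection; cyclic-shift fallback."""
    idx = np.arange(n)
    for _ in range(max_tries):
        perm = rng.permutation(n)
        if not np.any(perm == idx):
            return perm
    perm = rng.permutation(n)
    # rotate along the random cycle order: position i takes the next element
    out = np.empty(n, dtype=int)
    out[perm] = perm[np.roll(np.arange(n), -1)]
    return out


def matched_permutation(
    m: pd.Series | np.ndarray,
    r: pd.Series | np.ndarray,
    B: int = 1000,
    seed: int = 0,
    sd_mult: float = 2.0,
    ratio_bound: float = 0.5,
    alpha: float = 0.01,
) -> PermutationResult:
    """Permutation test for enrichment of reinforcing / compensatory genes.

    Each iteration derangements the RPF fold changes (no gene keeps its
    own value) and rebuilds a surrogate r* with exactly the observed
    sample mean, SD, and Pearson correlation with m:

        r* = mu_r + sigma_r * (rho * z_m + sqrt(1 - rho^2) * z_e)

    where z_m standardizes m and z_e standardizes the residual of the
    permuted values after removing their linear projection on m. The
    classifier is re-run on (m, r*) with thresholds recomputed per
    iteration; the empirical p-value per category is
    (1 + #{null count >= observed}) / (1 + B).
    """
    m = np.asarray(m, dtype=float)
    r = np.asarray(r, dtype=float)
    keep = np.isfinite(m) & np.isfinite(r)
    m, r = m[keep], r[keep]
    n = len(m)
    if n < 4:
        raise ValueError("need at least 4 genes")
    mu_r, sigma_r = float(np.mean(r)), float(np.std(r, ddof=1))
    rho = float(np.corrcoef(m, r)[0, 1])
    if not np.isfinite(rho) or abs(rho) >= 1.0 - 1e-12:
        raise ValueError("degenerate correlation between m and r")
    z_m = (m - m.mean()) / np.std(m, ddof=1)

    obs_reinf, obs_comp, _, _ = _classify_arrays(m, r, sd_mult, ratio_bound)
    observed = {REINFORCING: int(obs_reinf.sum()), COMPENSATORY: int(obs_comp.sum())}

    rng = np.random.default_rng(seed)
    zm_norm = float(z_m @ z_m)
    null = np.empty((B, 2), dtype=int)
    for b in range(B):
        p = r[_derangement(n, rng)]
        r_star = _match_moments(p, z_m, zm_norm, mu_r, sigma_r, rho)
        reinf, comp, _, _ = _classify_arrays(m, r_star, sd_mult, ratio_bound)
        null[b, 0] = reinf.sum()
        null[b, 1] = comp.sum()
    null_df = pd.DataFrame(null, columns=[REINFORCING, COMPENSATORY])
    pvals = {
        cat: float((1 + int((null_df[cat] >= observed[cat]).sum())) / (1 + B))
        for cat in (REINFORCING, COMPENSATORY)
    }
    return PermutationResult(B, observed, null_df, pvals, alpha, seed)


def match_moments(p: np.ndarray, m: np.ndarray, mu_r: float, sigma_r: float, rho: float) -> np.ndarray:
    """Rescale a permuted vector to the target mean, SD, and correlation
    with m (public wrapper, used by tests)."""
    z_m = (m - m.mean()) / np.std(m, ddof=1)
    return _match_moments(np.asarray(p, float), z_m, float(z_m @ z_m), mu_r, sigma_r, rho)


def _match_moments(
    p: np.ndarray,
    z_m: np.ndarray,
    zm_norm: float,
    mu_r: float,
    sigma_r: float,
    rho: float,
) -> np.ndarray:
    pc = p - p.mean()
    e = pc - (pc @ z_m) / zm_norm * z_m
    sd_e = np.std(e, ddof=1)
    z_e = e / sd_e if sd_e > 0 else np.zeros_like(e)
    return mu_r + sigma_r * (rho * z_m + np.sqrt(1.0 - rho * rho) * z_e)


def protein_divergence_by_class(
    protein_fc: pd.Series,
    classes: pd.Series,
    m: pd.Series,
) -> pd.DataFrame:
    """Protein fold changes split by interaction class and mRNA direction.

    Direction (Up / Down) follows the sign of the mRNA log2FC. For each
    class the Up and Down groups are compared by a two-sided Welch t-test;
    groups with fewer than 2 genes are flagged insufficient.
    """
    genes = protein_fc.dropna().index.intersection(classes.index).intersection(m.index)
    direction = pd.Series(np.where(m[genes] >= 0, "Up", "Down"), index=genes)
    rows = []
    for cls in (REINFORCING, COMPENSATORY, NONE):
        in_cls = genes[classes[genes] == cls]
        up = protein_fc[in_cls[direction[in_cls] == "Up"]].to_numpy(dtype=float)
        down = protein_fc[in_cls[direction[in_cls] == "Down"]].to_numpy(dtype=float)
        t = p = np.nan
        ok = len(up) >= 2 and len(down) >= 2
        if ok:
            t, p = stats.ttest_ind(up, down, equal_var=False)
        rows.append(
            {
                "class": cls,
                "n_up": len(up),
                "n_down": len(down),
                "mean_fc_up": float(np.mean(up)) if len(up) else np.nan,
                "mean_fc_down": float(np.mean(down)) if len(down) else np.nan,
                "mean_abs_fc": float(np.mean(np.abs(np.concatenate([up, down]))))
                if len(up) + len(down)
                else np.nan,
                "t": float(t) if ok else np.nan,
                "p": float(p) if ok else np.nan,
                "sufficient": ok,
            }
        )
    return pd.DataFrame(rows).set_index("class")


def te_fc_by_ratio_group(
    protein_fc: pd.Series,
    mrna_fc: pd.Series,
    te_fc: pd.Series,
    bound: float = 1.5,
) -> tuple[pd.Series, pd.DataFrame]:
    """Group genes by the linear protein-to-mRNA fold-change ratio.

    Groups: ratio > bound, ratio < 1/bound, and "other". Genes with zero
    mRNA fold change are excluded. Returns (labels, per-group TE FC
    summary).
    """
    genes = protein_fc.index.intersection(mrna_fc.index).intersection(te_fc.index)
    genes = genes[mrna_fc[genes] != 0]
    ratio = protein_fc[genes] / mrna_fc[genes]
    labels = pd.Series(
        np.where(ratio > bound, f">{bound}", np.where(ratio < 1 / bound, f"<1/{bound}", "other")),
        index=genes,
        name="ratio_group",
    )
    rows = []
    for lab in (f">{bound}", f"<1/{bound}", "other"):
        vals = te_fc[genes[labels == lab]].dropna().to_numpy(dtype=float)
        rows.append(
            {
                "group": lab,
                "n_genes": len(vals),
                "median_te_fc": float(np.median(vals)) if len(vals) else np.nan,
                "mean_te_fc": float(np.mean(vals)) if len(vals) else np.nan,
            }
        )
    return labels, pd.DataFrame(rows).set_index("group")
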