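"""Gene regulatory network inference and multi-omics fusion.

Three single-layer networks are inferred with a random-forest importance
scheme (one regression forest per target gene, regulators as features):
Mm (transcriptome regulators -> transcriptome targets), Tt (translatome ->
translatome) and Tm (transcriptome regulators -> translatome targets).
Each keeps its top-K edges; the multi-omics fusion (MF) network is the
strict three-way intersection of those edge sets, which suppresses
layer-specific noise and concentrates true regulatory edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor


@dataclass
class EdgeList:
    """Weighted regulator -> target edges from one network configuration."""

    edges: pd.DataFrame  # columns: regulator, target, weight
    configuration: str = ""

    def __post_init__(self) -> None:
        e = self.edges
        if (e["regulator"] == e["target"]).any():
            raise ValueError("self-edges not allowed")
        if e.duplicated(["regulator", "target"]).any():
            raise ValueError("duplicate edges")
        if not np.isfinite(e["weight"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite edge weights")

    def __len__(self) -> int:
        return len(self.edges)

    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.edges["regulator"], self.edges["target"]))


@dataclass
class EnrichmentResult:
    N: int
    K: int
    n: int
    k: int
    fold: float
    p: float


def infer_grn(
    regulator_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    n_trees: int = 100,
    seed: int = 0,
    configuration: str = "",
) -> EdgeList:
    """Random-forest network inference (GENIE3-style importances).

    For each target gene a regression forest predicts its expression from
    all regulators (excluding the target itself when it is a regulator);
    the edge weight regulator -> target is the regulator's total impurity
    importance. Candidate splits consider sqrt(#regulators) features.
    Constant targets yield zero weights for all their edges.
    """
    if list(regulator_expr.columns) != list(target_expr.columns):
        raise ValueError("regulator and target matrices must share sample columns")
    regs = list(regulator_expr.index)
    if len(regs) < 2:
        raise ValueError("need at least 2 regulators")
    X_all = regulator_expr.to_numpy(dtype=float).T  # samples x regulators
    rows = []
    rng = np.random.default_rng(seed)
    for target in target_expr.index:
        y = target_expr.loc[target].to_numpy(dtype=float)
        use = [i for i, r in enumerate(regs) if r != target]
        X = X_all[:, use]
        names = [regs[i] for i in use]
        if np.std(y) == 0:
            importances = np.zeros(len(use))
        else:
            forest = RandomForestRegressor(
                n_estimators=n_trees,
                max_features="sqrt",
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            forest.fit(X, y)
            importances = forest.feature_importances_
        for name, w in zip(names, importances):
            rows.append((name, target, float(w)))
    edges = pd.DataFrame(rows, columns=["regulator", "target", "weight"])
    return EdgeList(edges, configuration)


def top_k_edges(edges: EdgeList, K: int) -> EdgeList:
    """Keep the K highest-weight edges; boundary ties resolve by
    (regulator, target) lexicographic order."""
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(edges):
        warnings.warn(f"K={K} exceeds edge count {len(edges)}; returning all edges")
        K = len(edges)
    ranked = edges.edges.sort_values(
        ["weight", "regulator", "target"], ascending=[False, True, True], kind="mergesort"
    )
    return EdgeList(ranked.head(K).reset_index(drop=True), edges.configuration)


def fuse_mf(mm: EdgeList, tt: EdgeList, tm: EdgeList) -> EdgeList:
    """Multi-omics fusion: strict three-way intersection of edge sets;
    fused weight = mean of the three configuration weights."""
    frames = []
    for el in (mm, tt, tm):
        frames.append(el.edges.set_index(["regulator", "target"])["weight"])
    common = frames[0].index.intersection(frames[1].index).intersection(frames[2].index)
    weight = sum(f.loc[common] for f in frames) / 3.0
    out = weight.rename("weight").reset_index().sort_values(["regulator", "target"])
    return EdgeList(out.reset_index(drop=True), "MF")


def extract_subnetwork(edges: EdgeList, tf_set) -> EdgeList:
    """Edges whose regulator belongs to ``tf_set``."""
    tf_set = set(tf_set)
    if not tf_set:
        raise ValueError("tf_set is empty")
    sub = edges.edges[edges.edges["regulator"].isin(tf_set)].reset_index(drop=True)
    return EdgeList(sub, edges.configuration)


def hypergeom_enrichment(query_set, gene_set, background) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of ``query_set`` in ``gene_set``.

    p = P(X >= k), X ~ Hypergeom(N=|background|, K=|gene_set|, n=|query|);
    fold = (k/n) / (K/N).
    """
    background = set(background)
    query = set(query_set) & background
    genes = set(gene_set) & background
    if not background:
        raise ValueError("empty background")
    if not query:
        raise ValueError("empty query set")
    N, K, n = len(background), len(genes), len(query)
    k = len(query & genes)
    p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
    fold = (k / n) / (K / N) if K else np.nan
    return EnrichmentResult(N, K, n, k, float(fold), min(p, 1.0))


def compare_weights(
    edges: EdgeList, mf_targets, other_targets
) -> tuple[float, float, pd.DataFrame]:
    """Two-sided Welch t-test on edge weights, grouped by whether the edge
    target belongs to the fused-network target set."""
    mf_targets, other_targets = set(mf_targets), set(other_targets)
    w_mf = edges.edges.loc[edges.edges["target"].isin(mf_targets), "weight"].to_numpy(float)
    w_other = edges.edges.loc[edges.edges["target"].isin(other_targets), "weight"].to_numpy(float)
    if len(w_mf) < 2 or len(w_other) < 2:
        raise ValueError("each group needs at least 2 edges")
    t, p = stats.ttest_ind(w_mf, w_other, equal_var=False)
    summary = pd.DataFrame(
        {
            "group": ["mf_targets", "other_targets"],
            "n_edges": [len(w_mf), len(w_other)],
            "mean_weight": [float(w_mf.mean()), float(w_other.mean())],
        }
    )
    return float(t), float(p), summary


def edge_precision(edges: EdgeList, true_edges: set[tuple[str, str]]) -> float:
    """Fraction of edges present in a ground-truth edge set."""
    if len(edges) == 0:
        return float("nan")
    return len(edges.pair_set() & true_edges) / len(edges)
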