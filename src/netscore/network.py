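"""Weighted gene coexpression network construction.

Pearson correlation over samples, soft-threshold power selection by
scale-free topology fit, unsigned adjacency a_ij = |r_ij|^beta,
topological overlap, average-linkage clustering on TOM dissimilarity,
module eigengenes (first principal component per module) and gene
module membership (kME).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "CorrelationMatrix",
    "AdjacencyMatrix",
    "TOMatrix",
    "PowerSelection",
    "ModuleEigengenes",
    "DEFAULT_POWER",
    "pearson_correlation_matrix",
    "pick_soft_threshold",
    "adjacency",
    "topological_overlap",
    "hierarchical_cluster",
    "module_eigengenes",
    "gene_module_membership",
    "top_variable_genes",
]

#: default soft-threshold power when the caller bypasses selection
DEFAULT_POWER = 6


@dataclass
class CorrelationMatrix:
    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")


@dataclass
class AdjacencyMatrix:
    gene_ids: list[str]
    values: np.ndarray  # zero diagonal
    power: int

    @property
    def connectivity(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass
class TOMatrix:
    gene_ids: list[str]
    values: np.ndarray  # unit diagonal

    @property
    def dissimilarity(self) -> np.ndarray:
        d = 1.0 - self.values
        np.fill_diagonal(d, 0.0)
        return d


@dataclass
class PowerSelection:
    table: pd.DataFrame  # power, r2_signed, mean_connectivity
    chosen: int
    threshold: float


@dataclass
class ModuleEigengenes:
    """First-PC summary profile per module (sample mean 0, unit variance),
    oriented so each ME correlates non-negatively with the module's mean
    standardized expression."""

    sample_ids: list[str]
    values: pd.DataFrame  # samples x modules
    variance_explained: pd.Series
    flipped: pd.Series  # True where the raw PC was negated to fix orientation

    @property
    def module_labels(self) -> list[str]:
        return list(self.values.columns)


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=1, ddof=1, keepdims=True)
    return (X - X.mean(axis=1, keepdims=True)) / sd


def pearson_correlation_matrix(expression: pd.DataFrame) -> CorrelationMatrix:
    """All-pairs Pearson r across samples (genes are rows)."""
    if expression.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    if expression.isna().any().any():
        raise ValueError("expression contains missing values")
    sd = expression.std(axis=1, ddof=1)
    zero = sd.index[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance gene(s): {list(zero[:5])}")
    r = np.corrcoef(expression.to_numpy(dtype=float))
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(gene_ids=list(expression.index), values=r)


def adjacency(corr: CorrelationMatrix, power: int = DEFAULT_POWER) -> AdjacencyMatrix:
    """Unsigned adjacency a_ij = |r_ij|^power, diagonal zeroed."""
    if power < 1:
        raise ValueError("power must be >= 1")
    a = np.abs(corr.values) ** power
    np.fill_diagonal(a, 0.0)
    return AdjacencyMatrix(gene_ids=corr.gene_ids, values=a, power=int(power))


def pick_soft_threshold(
    corr: CorrelationMatrix,
    candidates: list[int] = (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 12, 14, 16, 18, 20),
    *,
    r2_threshold: float = 0.80,
    n_bins: int = 10,
) -> PowerSelection:
    """Scale-free-topology fit across candidate powers.

    For each power the connectivities are binned on log10 scale and
    log10(frequency) is regressed on log10(k); the signed fit index is
    -sign(slope) * R^2.  The chosen power is the smallest candidate
    reaching ``r2_threshold``, else the candidate maximizing the index.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate powers")
    rows = []
    for power in candidates:
        adj = adjacency(corr, power)
        k = adj.connectivity
        rows.append(
            {
                "power": int(power),
                "r2_signed": _scale_free_fit(k, n_bins),
                "mean_connectivity": float(k.mean()),
            }
        )
    table = pd.DataFrame(rows)
    passing = table[table["r2_signed"] >= r2_threshold]
    if len(passing):
        chosen = int(passing["power"].iloc[0])
    else:
        chosen = int(table.loc[table["r2_signed"].idxmax(), "power"])
    return PowerSelection(table=table, chosen=chosen, threshold=r2_threshold)


def _scale_free_fit(connectivity: np.ndarray, n_bins: int) -> float:
    k = connectivity[connectivity > 0]
    if len(np.unique(k)) < 2:
        raise ValueError("degenerate connectivity distribution (all values identical)")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-9, n_bins + 1)
    counts, _ = np.histogram(logk, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mask = counts > 0
    if mask.sum() < 2:
        return 0.0
    x, y = centers[mask], np.log10(counts[mask])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        return 0.0
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot
    return float(-np.sign(slope) * r2)


def topological_overlap(adj: AdjacencyMatrix) -> TOMatrix:
    """Unsigned topological overlap.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    l_ij = sum_u a_iu a_uj and k_i the node connectivity; TOM_ii = 1.
    """
    a = adj.values
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    a = (a + a.T) / 2.0
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    L = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (L + a) / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return TOMatrix(gene_ids=adj.gene_ids, values=tom)


@dataclass
class Dendrogram:
    """Average-linkage tree over genes (scipy linkage encoding)."""

    gene_ids: list[str]
    linkage: np.ndarray  # (n-1) x 4 scipy linkage matrix

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage))


def hierarchical_cluster(dissimilarity: np.ndarray, gene_ids: list[str] | None = None) -> Dendrogram:
    """Average-linkage hierarchical clustering of a dissimilarity matrix."""
    d = np.asarray(dissimilarity, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("dissimilarity must be symmetric")
    dd = d.copy()
    np.fill_diagonal(dd, 0.0)
    Z = hierarchy.linkage(squareform(dd, checks=False), method="average")
    if gene_ids is None:
        gene_ids = [str(i) for i in range(d.shape[0])]
    return Dendrogram(gene_ids=list(gene_ids), linkage=Z)


def module_eigengenes(expression: pd.DataFrame, assignment) -> ModuleEigengenes:
    """First-principal-component summary per module.

    Genes are standardized, the first right-singular vector over samples
    is scaled to unit variance, and the sign is fixed so the ME
    correlates non-negatively with the module's mean standardized
    expression.  The gray (unassigned) label is excluded.
    """
    from .treecut import ModuleAssignment  # local to avoid cycle

    if isinstance(assignment, ModuleAssignment):
        labels = assignment.labels
    else:
        labels = pd.Series(assignment)
    labels = labels.loc[labels.index.intersection(expression.index)]

    sample_ids = list(expression.columns)
    me_cols, var_exp, flipped = {}, {}, {}
    for label in _ordered_module_labels(labels):
        genes = labels.index[labels == label]
        if len(genes) < 2:
            raise ValueError(f"module {label} has fewer than 2 genes")
        sub = expression.loc[genes].to_numpy(dtype=float)
        if np.any(sub.std(axis=1) == 0):
            raise ValueError(f"module {label} contains constant genes")
        Z = _standardize_rows(sub)
        # SVD of genes x samples: right singular vectors live in sample space
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        pc = Vt[0]
        pc = pc / pc.std(ddof=0)
        pc = pc - pc.mean()
        mean_profile = Z.mean(axis=0)
        if np.corrcoef(pc, mean_profile)[0, 1] < 0:
            pc = -pc
            flipped[label] = True
        else:
            flipped[label] = False
        me_cols[label] = pc
        var_exp[label] = float(s[0] ** 2 / np.sum(s**2))
    if not me_cols:
        raise ValueError("no modules to summarize (all genes gray?)")
    values = pd.DataFrame(me_cols, index=sample_ids)
    return ModuleEigengenes(
        sample_ids=sample_ids,
        values=values,
        variance_explained=pd.Series(var_exp),
        flipped=pd.Series(flipped),
    )


def _ordered_module_labels(labels: pd.Series) -> list[str]:
    sizes = labels[labels != "gray"].value_counts()
    return sorted(sizes.index, key=lambda lb: (-sizes[lb], lb))


def gene_module_membership(expression: pd.DataFrame, mes: ModuleEigengenes) -> pd.DataFrame:
    """kME: Pearson correlation of every gene with every module eigengene."""
    shared = [s for s in expression.columns if s in mes.values.index]
    if not shared:
        raise ValueError("no shared samples between expression and eigengenes")
    X = expression[shared].to_numpy(dtype=float)
    if np.any(X.std(axis=1) == 0):
        bad = expression.index[X.std(axis=1) == 0]
        raise ValueError(f"zero-variance gene(s): {list(bad[:5])}")
    M = mes.values.loc[shared].to_numpy(dtype=float)
    Xz = _standardize_rows(X)
    Mz = _standardize_rows(M.T)
    n = len(shared)
    kme = (Xz @ Mz.T) / (n - 1)
    return pd.DataFrame(
        np.clip(kme, -1.0, 1.0), index=expression.index, columns=mes.values.columns
    )


def top_variable_genes(expression: pd.DataFrame, n: int) -> pd.DataFrame:
    """Default pre-networking gene filter: the n most variable genes."""
    var = expression.var(axis=1, ddof=1)
    keep = var.sort_values(ascending=False).index[:n]
    return expression.loc[keep]


def save_matrix(path, matrix, gene_ids: list[str], **params) -> None:
    """Persist a square gene matrix as compressed binary + JSON sidecar."""
    np.savez_compressed(path, values=matrix)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump({"gene_ids": gene_ids, **params}, fh)
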