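"""Module detection on the TOM dendrogram: a hybrid dynamic tree cut.

This is a compact hybrid variant of adaptive dendrogram cutting:

1. a static cut of the average-linkage tree at ``height_cutoff``
   produces candidate branches;
2. each branch is recursively split where the merge-height gap between
   a parent and its children is large relative to the parent height,
   with the sensitivity controlled by ``deep_split`` (0 = never split,
   4 = most aggressive);
3. clusters smaller than ``min_size`` are dissolved to "gray";
4. an optional assignment stage attaches each gray gene to its nearest
   module when its mean dissimilarity to that module is no larger than
   the module's own internal spread.

It follows the spirit, not the letter, of the canonical hybrid
implementation; behaviour is validated by planted-block recovery
(Adjusted Rand Index against ground truth) rather than label-exact
agreement.  Labels follow the size-rank color convention (largest
module = "turquoise", then "blue", "brown", ...), ties broken by the
smallest member gene id; unassigned genes are "gray".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .network import Dendrogram

__all__ = ["ModuleAssignment", "dynamic_tree_cut", "MODULE_COLORS"]

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]

GRAY = "gray"


@dataclass
class ModuleAssignment:
    """Gene -> color-label map plus the parameters that produced it."""

    labels: pd.Series  # gene id -> color string; "gray" = unassigned
    height_cutoff: float
    deep_split: int
    min_size: int

    @property
    def module_labels(self) -> list[str]:
        sizes = self.labels[self.labels != GRAY].value_counts()
        return sorted(sizes.index, key=lambda lb: (-sizes[lb], lb))

    def module_genes(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def n_gray(self) -> int:
        return int((self.labels == GRAY).sum())

    def to_frame(self) -> pd.DataFrame:
        return self.labels.rename("module").to_frame()


def dynamic_tree_cut(
    dend: Dendrogram,
    dissimilarity: np.ndarray,
    *,
    height_cutoff: float = 0.99,
    deep_split: int = 2,
    min_size: int = 30,
    assign_outliers: bool = True,
) -> ModuleAssignment:
    """Cut the dendrogram into modules (see module docstring).

    Defaults: height_cutoff 0.99, deep_split 2, min_size 30.
    """
    if min_size < 2:
        raise ValueError("min_size must be >= 2")
    if not (0 < height_cutoff <= 1):
        raise ValueError("height_cutoff must lie in (0, 1]")
    if not (0 <= deep_split <= 4):
        raise ValueError("deep_split must lie in 0..4")

    n = len(dend.gene_ids)
    d = np.asarray(dissimilarity, dtype=float)
    if d.shape != (n, n):
        raise ValueError("dissimilarity shape does not match dendrogram leaves")

    static = hierarchy.fcluster(dend.linkage, t=height_cutoff, criterion="distance")
    root, nodes = hierarchy.to_tree(dend.linkage, rd=True)

    # gap threshold: larger deep_split -> smaller gap needed -> more splits
    gap_frac = 0.45 - 0.1 * deep_split  # ds=2 -> 0.25

    clusters: list[np.ndarray] = []
    for cid in np.unique(static):
        members = np.flatnonzero(static == cid)
        if len(members) < 2:
            clusters.append(members)
            continue
        node = _subtree_root(nodes, members, n)
        if node is None or deep_split == 0:
            clusters.append(members)
        else:
            clusters.extend(_adaptive_split(node, gap_frac, min_size))

    labels = np.full(n, GRAY, dtype=object)
    kept = [c for c in clusters if len(c) >= min_size]
    kept.sort(key=lambda c: (-len(c), min(np.asarray(dend.gene_ids)[c])))
    for i, members in enumerate(kept):
        labels[members] = MODULE_COLORS[i % len(MODULE_COLORS)]

    if assign_outliers and kept:
        labels = _assign_outliers(labels, d)

    return ModuleAssignment(
        labels=pd.Series(labels, index=dend.gene_ids, name="module"),
        height_cutoff=height_cutoff,
        deep_split=deep_split,
        min_size=min_size,
    )


def _subtree_root(nodes, members: np.ndarray, n_leaves: int):
    """Smallest dendrogram node whose leaf set equals ``members``."""
    member_set = set(int(m) for m in members)
    best = None
    for node in nodes:
        if node.get_count() != len(member_set):
            continue
        leaves = set(node.pre_order(lambda x: x.id))
        if leaves == member_set:
            if best is None or node.get_count() <= best.get_count():
                best = node
    return best


def _adaptive_split(node, gap_frac: float, min_size: int) -> list[np.ndarray]:
    """Recursively split a branch where the parent-child merge-height gap
    is at least ``gap_frac`` of the parent height and both children could
    form a module on their own."""
    leaves = np.asarray(node.pre_order(lambda x: x.id))
    if node.is_leaf() or len(leaves) < 2 * min_size:
        return [leaves]
    left, right = node.get_left(), node.get_right()
    if left.get_count() < min_size or right.get_count() < min_size:
        return [leaves]
    child_h = max(left.dist, right.dist)
    if node.dist <= 0 or (node.dist - child_h) < gap_frac * node.dist:
        return [leaves]
    return _adaptive_split(left, gap_frac, min_size) + _adaptive_split(right, gap_frac, min_size)


def _assign_outliers(labels: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Attach gray genes whose mean dissimilarity to the nearest module
    does not exceed that module's internal spread (90th percentile of
    members' mean within-module dissimilarity)."""
    labels = labels.copy()
    module_names = [lb for lb in np.unique(labels) if lb != GRAY]
    idx_by_mod = {lb: np.flatnonzero(labels == lb) for lb in module_names}
    thresholds = {}
    for lb, idx in idx_by_mod.items():
        sub = d[np.ix_(idx, idx)]
        mean_within = (sub.sum(axis=1)) / (len(idx) - 1)
        thresholds[lb] = np.percentile(mean_within, 90)
    gray_idx = np.flatnonzero(labels == GRAY)
    for g in gray_idx:
        best_lb, best_d = None, np.inf
        for lb, idx in idx_by_mod.items():
            md = float(d[g, idx].mean())
            if md < best_d:
                best_lb, best_d = lb, md
        if best_lb is not None and best_d <= thresholds[best_lb]:
            labels[g] = best_lb
    return labels


def relabel_by_size(labels: pd.Series) -> pd.Series:
    """Re-apply the size-rank color convention to an arbitrary labeling."""
    out = pd.Series(GRAY, index=labels.index, dtype=object)
    sizes = labels[labels != GRAY].value_counts()
    ordered = sorted(
        sizes.index,
        key=lambda lb: (-sizes[lb], min(labels.index[labels == lb])),
    )
    for i, lb in enumerate(ordered):
        out[labels == lb] = MODULE_COLORS[i % len(MODULE_COLORS)]
    return out
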