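"""Top-down spatial segmentation by bisecting k-means under correlation distance.

Starting from a single cluster containing every spectrum, the leaf with the
largest within-cluster cost is repeatedly split in two by k-means until the
requested number of leaves exists.  Distance between spectra is correlation
distance d(a, b) = 1 - Pearson(a, b): rows are z-scored across features,
where squared Euclidean distance equals 2 p (1 - r), so a Euclidean k-means
on standardized rows realizes the correlation geometry, and a zero-variance
row (z-vector 0) falls back to plain Euclidean assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .core import PeakMatrix

__all__ = ["SegmentationNode", "SegmentationTree", "bisecting_kmeans"]

_N_RESTARTS = 10


@dataclass
class SegmentationNode:
    """One node of the binary segmentation tree."""

    indices: np.ndarray           # member spectrum row indices
    cost: float                   # sum of correlation distances to centroid
    centroid: np.ndarray          # mean of standardized member vectors
    children: tuple["SegmentationNode", "SegmentationNode"] | None = None
    leaf_id: int | None = None    # creation-order id while a leaf

    @property
    def is_leaf(self) -> bool:
        return self.children is None


@dataclass
class SegmentationTree:
    root: SegmentationNode
    n_spectra: int

    def leaves(self) -> list[SegmentationNode]:
        out: list[SegmentationNode] = []

        def walk(node: SegmentationNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return out

    def labels(self) -> np.ndarray:
        """Leaf id per spectrum (ids assigned in creation order)."""
        lab = np.empty(self.n_spectra, dtype=int)
        for leaf in self.leaves():
            lab[leaf.indices] = leaf.leaf_id
        return lab

    def to_frame(self, meta: pd.DataFrame) -> pd.DataFrame:
        """Cluster map: one row per spectrum (section, x, y, leaf)."""
        out = meta[["section", "x", "y"]].copy()
        out["leaf"] = self.labels()
        return out


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    flat = sd[:, 0] == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} spectra have zero variance across features; "
            "using Euclidean fallback for their assignment"
        )
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    Z[flat] = 0.0
    return Z


def _node_cost(Z: np.ndarray, centroid: np.ndarray) -> float:
    """Sum over members of 1 - Pearson(member, centroid).

    Members or centroids without variance contribute 0 by convention.
    """
    zc = centroid - centroid.mean()
    nc = np.linalg.norm(zc)
    if nc == 0:
        return 0.0
    rows = Z - Z.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    ok = norms > 0
    r = np.zeros(Z.shape[0])
    r[ok] = rows[ok] @ zc / (norms[ok] * nc)
    return float(np.sum(1.0 - r[ok]))


def bisecting_kmeans(matrix: PeakMatrix | np.ndarray, n_leaves: int, seed: int = 0) -> SegmentationTree:
    """Segment spectra into ``n_leaves`` clusters by recursive bisection.

    Each bisection runs seeded k-means (k = 2, k-means++ initialization,
    10 restarts, best inertia kept) on the standardized member rows of the
    leaf with the largest within-cluster cost.  Total within-cluster cost is
    non-increasing over splits, and a spectrum's assignment is invariant to
    positive scaling of its feature vector.
    """
    X = matrix.intensity if isinstance(matrix, PeakMatrix) else np.asarray(matrix, dtype=float)
    if n_leaves < 1:
        raise ValueError("n_leaves must be >= 1")
    if X.shape[0] < n_leaves:
        raise ValueError(f"cannot form {n_leaves} leaves from {X.shape[0]} spectra")
    Z = _standardize_rows(X)

    seeds = np.random.SeedSequence(seed).generate_state(max(n_leaves - 1, 1))
    all_idx = np.arange(X.shape[0])
    root = SegmentationNode(all_idx, _node_cost(Z[all_idx], Z[all_idx].mean(axis=0)),
                            Z[all_idx].mean(axis=0), leaf_id=0)
    tree = SegmentationTree(root, X.shape[0])
    next_id = 1
    for split_i in range(n_leaves - 1):
        leaves = [lf for lf in tree.leaves() if lf.indices.size >= 2]
        if not leaves:
            raise ValueError("no splittable leaf remains (all singletons)")
        target = max(leaves, key=lambda lf: (lf.cost, -lf.leaf_id))
        members = target.indices
        km = KMeans(
            n_clusters=2,
            init="k-means++",
            n_init=_N_RESTARTS,
            random_state=int(seeds[split_i] % (2**31)),
        ).fit(Z[members])
        assign = km.labels_
        if assign.min() == assign.max():  # degenerate split: force a separation
            assign = np.zeros(members.size, dtype=int)
            assign[-1] = 1
        kids = []
        for side in (0, 1):
            idx = members[assign == side]
            centroid = Z[idx].mean(axis=0)
            kids.append(SegmentationNode(idx, _node_cost(Z[idx], centroid), centroid))
        kids[0].leaf_id = target.leaf_id
        kids[1].leaf_id = next_id
        next_id += 1
        target.children = (kids[0], kids[1])
        target.leaf_id = None
    return tree
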