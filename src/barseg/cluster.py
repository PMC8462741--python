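"""Grouping molecules by bisulfite-accessibility pattern.

Binary conversion profiles are compared by Hamming distance and grouped by
complete-linkage agglomerative clustering; the number of groups can be
suggested by the gap statistic.  Identical profiles are deduplicated and
clustered once with multiplicity weights — exactly equivalent to clustering
the expanded matrix, since duplicates sit at distance zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io import MutationMatrix

logger = logging.getLogger(__name__)


@dataclass
class ClusterAssignment:
    """Per-sequence cluster labels in 1..k with weighted sizes and
    strand-prefixed names like ``C_1909`` (top) / ``G_5670`` (bottom)."""

    labels: np.ndarray
    k: int
    sizes: np.ndarray
    names: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.all((self.labels >= 1) & (self.labels <= self.k)):
            raise ValueError("labels must lie in 1..k")

    def name_of(self, label: int) -> str:
        return self.names[label - 1]


def hamming_distance(x, y) -> int:
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    return int(np.count_nonzero(x != y))


def _dedup(calls: np.ndarray, weights: np.ndarray):
    """Canonically (lexicographically) sorted distinct rows, multiplicities,
    and the map from original rows to distinct-row index."""
    uniq, inverse = np.unique(calls, axis=0, return_inverse=True)
    mult = np.zeros(uniq.shape[0])
    np.add.at(mult, inverse, weights)
    return uniq, mult, inverse


def _complete_linkage_labels(uniq: np.ndarray, k: int) -> np.ndarray:
    """Complete-linkage labels (1..k) for the distinct rows."""
    if uniq.shape[0] == 1:
        return np.ones(1, dtype=int)
    d = pdist(uniq, metric="hamming") * uniq.shape[1]  # integer Hamming counts
    Z = linkage(d, method="complete")
    return fcluster(Z, t=k, criterion="maxclust")


def complete_linkage_cluster(matrix: MutationMatrix, k: int) -> ClusterAssignment:
    """Cluster sequences into k groups by complete-linkage Hamming distance.

    Clusters are relabeled 1..k by descending weighted size (ties by first
    canonical row) to make names deterministic.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    uniq, mult, inverse = _dedup(matrix.calls, matrix.weights)
    if k > uniq.shape[0]:
        raise ValueError(f"k={k} exceeds number of distinct sequences ({uniq.shape[0]})")
    raw = _complete_linkage_labels(uniq, k)
    sizes_raw = np.zeros(raw.max())
    np.add.at(sizes_raw, raw - 1, mult)
    order = np.argsort(-sizes_raw, kind="stable")  # descending size, stable ties
    relabel = np.empty_like(order)
    relabel[order] = np.arange(1, order.size + 1)
    labels_uniq = relabel[raw - 1]
    labels = labels_uniq[inverse]
    sizes = sizes_raw[order]
    prefix = "C" if matrix.strand == "top" else "G"
    names = [f"{prefix}_{int(round(s))}" for s in sizes]
    return ClusterAssignment(labels=labels, k=int(raw.max()), sizes=sizes, names=names)


def within_dispersion(uniq: np.ndarray, mult: np.ndarray, labels: np.ndarray) -> float:
    """Weighted within-cluster dispersion W_k = sum_r D_r / (2 n_r), with
    D_r the weighted sum of pairwise Hamming distances inside cluster r."""
    if uniq.shape[0] == 1:
        return 0.0
    D = squareform(pdist(uniq, metric="hamming") * uniq.shape[1])
    W = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        w = mult[idx]
        n_r = w.sum()
        if idx.size > 1 and n_r > 0:
            W += float(w @ D[np.ix_(idx, idx)] @ w) / (2.0 * n_r)
    return W


@dataclass
class GapResult:
    k: int
    ks: np.ndarray
    gap: np.ndarray
    se: np.ndarray
    log_w: np.ndarray


def gap_statistic(
    matrix: MutationMatrix, k_max: int = 10, B: int = 50, seed: int | None = None
) -> GapResult:
    """Select the number of clusters by the gap statistic.

    Reference datasets resample each column as independent Bernoulli at its
    empirical weighted frequency (a binary-data analogue of the uniform
    reference box).  Selection rule: smallest k with
    gap(k) >= gap(k+1) - se(k+1).
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if B < 10:
        raise ValueError("B must be >= 10")
    rng = np.random.default_rng(seed)
    uniq, mult, _ = _dedup(matrix.calls, matrix.weights)
    if uniq.shape[0] == 1:
        logger.warning("all sequences identical; gap statistic degenerate, k=1")
        ks = np.array([1])
        return GapResult(k=1, ks=ks, gap=np.zeros(1), se=np.zeros(1), log_w=np.zeros(1))

    k_max = min(k_max, uniq.shape[0])
    ks = np.arange(1, k_max + 1)
    col_freq = matrix.weights @ matrix.calls / matrix.weights.sum()
    S = int(round(matrix.weights.sum()))

    def log_w_curve(u, m):
        out = np.empty(ks.size)
        for idx, k in enumerate(ks):
            labels = (
                np.ones(u.shape[0], dtype=int) if k == 1
                else _complete_linkage_labels(u, k)
            )
            out[idx] = np.log(max(within_dispersion(u, m, labels), 1e-12))
        return out

    log_w = log_w_curve(uniq, mult)
    ref = np.empty((B, ks.size))
    for b in range(B):
        sim = (rng.random((S, matrix.n_sites)) < col_freq).astype(np.uint8)
        u, m, _ = _dedup(sim, np.ones(S))
        ref[b] = log_w_curve(u, m)
    gap = ref.mean(axis=0) - log_w
    se = ref.std(axis=0) * np.sqrt(1.0 + 1.0 / B)

    selected = int(ks[-1])
    for idx in range(ks.size - 1):
        if gap[idx] >= gap[idx + 1] - se[idx + 1]:
            selected = int(ks[idx])
            break
    return GapResult(k=selected, ks=ks, gap=gap, se=se, log_w=log_w)
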