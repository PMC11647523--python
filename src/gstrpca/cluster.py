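"""Cell clustering on the reconstructed tensor and partition-agreement
metrics.

The reconstructed tensor X* = L + alpha*E (alpha defaults to 1, so X* is the
full reconstruction) is flattened into one cells x features embedding by
transposing the vertical concatenation of its slices; k-means with multiple
restarts partitions the cells; and agreement with ground-truth labels is
scored with ACC, NMI, ARI and AMI.

The four metrics are implemented from their definitions (contingency table,
entropies, hypergeometric expected mutual information); ACC matches
predicted clusters to true classes one-to-one by optimal assignment on the
contingency table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.special import gammaln
from sklearn.cluster import KMeans

from .gsvd import joint_gsvd
from .tensor import DomainError, IrregularTensor, axpy


@dataclass
class ClusteringResult:
    """Predicted labels, the embedding they came from, and the four metric
    values against ground truth (ACC/NMI/AMI in [0,1], ARI in [-1,1])."""

    labels_pred: np.ndarray
    embedding: np.ndarray
    k: int
    seed: int
    metrics: dict[str, float] = field(default_factory=dict)


def build_embedding(
    L: IrregularTensor,
    E: IrregularTensor,
    alpha: float = 1.0,
    d: int | None = None,
) -> np.ndarray:
    """Cells x features matrix from the reconstruction X* = L + alpha*E.

    With ``d`` given, the embedding is instead the rank-d cell scores from
    the shared right factor of X*'s joint GSVD (V_d scaled by the
    slice-summed spectrum), i.e. a joint-subspace projection.
    """
    xstar = axpy(alpha, E, L)
    if d is None:
        return np.vstack(xstar.slices).T
    if not (1 <= d <= xstar.n_cols):
        raise DomainError(f"projection dimension d={d} outside [1, {xstar.n_cols}]")
    f = joint_gsvd(xstar, d)
    scale = np.sum(np.stack(f.sigma_list), axis=0)
    return f.V * scale


def kmeans_cells(embedding: np.ndarray, k: int, seed: int = 0) -> np.ndarray:
    """k-means++ with 20 restarts, best inertia kept; deterministic per seed."""
    m = embedding.shape[0]
    if not (2 <= k <= m):
        raise DomainError(f"k={k} outside [2, {m}]")
    km = KMeans(n_clusters=k, n_init=20, random_state=seed)
    return km.fit_predict(embedding)


# ---------------------------------------------------------------------------
# Partition-agreement metrics, from their definitions
# ---------------------------------------------------------------------------


def _contingency(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    if len(a) != len(b):
        raise DomainError(f"label length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise DomainError("empty labelings")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    r, c = ai.max() + 1, bi.max() + 1
    table = np.zeros((r, c), dtype=np.int64)
    np.add.at(table, (ai, bi), 1)
    return table


def clustering_accuracy(labels_true, labels_pred) -> float:
    """Best label-agreement fraction over one-to-one cluster-class
    matchings, by optimal assignment on the contingency table."""
    table = _contingency(np.asarray(labels_true), np.asarray(labels_pred))
    rows, cols = linear_sum_assignment(-table)
    return float(table[rows, cols].sum() / table.sum())


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts[counts > 0] / n
    return float(-np.sum(p * np.log(p)))


def _mutual_information(table: np.ndarray) -> float:
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)
    nz = table > 0
    nij = table[nz].astype(float)
    outer = np.outer(a, b)[nz].astype(float)
    return float(np.sum((nij / n) * (np.log(nij * n) - np.log(outer))))


def nmi(labels_true, labels_pred) -> float:
    """Normalized mutual information I(U;V)/sqrt(H(U) H(V))."""
    table = _contingency(np.asarray(labels_true), np.asarray(labels_pred))
    if table.shape == (1, 1):
        return 1.0
    mi = _mutual_information(table)
    if mi == 0.0:
        return 0.0
    h_u = _entropy(table.sum(axis=1))
    h_v = _entropy(table.sum(axis=0))
    return float(mi / np.sqrt(h_u * h_v))


def ari(labels_true, labels_pred) -> float:
    """Adjusted Rand index with the permutation-model chance correction.

    Degenerate cases: identical trivial partitions (one cluster, or all
    singletons, on both sides) score 1; a many-cluster truth against a
    single predicted cluster scores 0 by the formula itself.
    """
    table = _contingency(np.asarray(labels_true), np.asarray(labels_pred))
    n = table.sum()
    a = table.sum(axis=1)
    b = table.sum(axis=0)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = float(np.sum(comb2(table)))
    sum_a = float(np.sum(comb2(a)))
    sum_b = float(np.sum(comb2(b)))
    total = comb2(float(n))
    expected = sum_a * sum_b / total if total > 0 else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def _expected_mutual_information(table: np.ndarray) -> float:
    """Hypergeometric-model E[I] over random tables with fixed margins."""
    n = int(table.sum())
    a = table.sum(axis=1).astype(int)
    b = table.sum(axis=0).astype(int)
    log_n = np.log(n)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(1, ai + bj - n)
            hi = min(ai, bj)
            for nij in range(lo, hi + 1):
                term = (nij / n) * (np.log(nij) + log_n - np.log(ai) - np.log(bj))
                lpr = (
                    gammaln(ai + 1)
                    + gammaln(bj + 1)
                    + gammaln(n - ai + 1)
                    + gammaln(n - bj + 1)
                    - gammaln(n + 1)
                    - gammaln(nij + 1)
                    - gammaln(ai - nij + 1)
                    - gammaln(bj - nij + 1)
                    - gammaln(n - ai - bj + nij + 1)
                )
                emi += term * np.exp(lpr)
    return float(emi)


def ami(labels_true, labels_pred) -> float:
    """Adjusted mutual information with the arithmetic-mean normalizer:
    (I - E[I]) / (mean(H(U), H(V)) - E[I])."""
    table = _contingency(np.asarray(labels_true), np.asarray(labels_pred))
    r, c = table.shape
    if r == c == 1:
        return 1.0
    mi = _mutual_information(table)
    emi = _expected_mutual_information(table)
    h_u = _entropy(table.sum(axis=1))
    h_v = _entropy(table.sum(axis=0))
    denom = 0.5 * (h_u + h_v) - emi
    eps = np.finfo(float).eps
    denom = min(denom, -eps) if denom < 0 else max(denom, eps)
    return float((mi - emi) / denom)


def evaluate_clustering(
    L: IrregularTensor,
    E: IrregularTensor,
    labels_true,
    k: int | None = None,
    alpha: float = 1.0,
    seed: int = 0,
    d: int | None = None,
) -> ClusteringResult:
    """Embed, cluster with k-means, and score against ground truth."""
    labels_true = np.asarray(labels_true)
    if k is None:
        k = len(np.unique(labels_true))
    emb = build_embedding(L, E, alpha=alpha, d=d)
    pred = kmeans_cells(emb, k, seed)
    metrics = {
        "acc": clustering_accuracy(labels_true, pred),
        "nmi": nmi(labels_true, pred),
        "ari": ari(labels_true, pred),
        "ami": ami(labels_true, pred),
    }
    return ClusteringResult(
        labels_pred=pred, embedding=emb, k=k, seed=seed, metrics=metrics
    )
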