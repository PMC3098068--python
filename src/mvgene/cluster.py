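"""Multi-view gene clustering: consensus functions and kernel fusion.

Late integration runs K-means per view and merges the resulting partitions
with a consensus function (CSPA, HGPA, MCLA, QMI, EACAL, AdacVote); early
integration fuses view kernels and clusters once, either by hierarchical
linkage on the Hilbert-space distance of the averaged kernel or by OKKC
(optimized kernel K-means: alternate kernel K-means with a convex
re-weighting of the trace-normalized kernels).  External validation uses
the Rand Index and normalized mutual information against disease labels,
with the all-pairs two-disease protocol: every unordered disease pair is a
binary clustering task after removing genes carrying both labels.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from ._qp import project_capped_simplex
from .kernels import KernelMatrix, combine_kernels, linear_kernel, uniform_weights
from .prioritize import FusionWeights
from .views import MultiViewDataset, View

__all__ = [
    "Partition",
    "CoAssociation",
    "HilbertDistance",
    "OkkcState",
    "PartitionAgreement",
    "ClusterEvalReport",
    "kmeans_partition",
    "coassociation",
    "consensus_combine",
    "hilbert_distance",
    "linkage_partition",
    "kernel_kmeans",
    "okkc",
    "agreement",
    "disease_pairs",
    "pairwise_disease_eval",
]

CONSENSUS_METHODS = ("CSPA", "HGPA", "MCLA", "QMI", "EACAL", "AdacVote")


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Partition:
    """Cluster labels in 1..k for an ordered gene set."""

    labels: np.ndarray
    k: int
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels, dtype=int)
        object.__setattr__(self, "labels", lab)
        if lab.ndim != 1 or lab.size == 0:
            raise ValueError("labels must be a non-empty vector")
        if lab.min() < 1 or lab.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if self.gene_ids is not None and len(self.gene_ids) != lab.size:
            raise ValueError("gene ids do not match label vector")

    @property
    def n(self) -> int:
        return self.labels.size

    def onehot(self) -> np.ndarray:
        H = np.zeros((self.n, self.k))
        H[np.arange(self.n), self.labels - 1] = 1.0
        return H


@dataclass(frozen=True)
class CoAssociation:
    """Fraction of partitions co-clustering each gene pair (diagonal 1)."""

    matrix: np.ndarray
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m, m.T):
            raise ValueError("co-association matrix must be symmetric")
        if not np.allclose(np.diag(m), 1.0):
            raise ValueError("co-association diagonal must be 1")


@dataclass(frozen=True)
class HilbertDistance:
    """Pairwise feature-space distances d(x, z) = √(K_xx − 2K_xz + K_zz)."""

    matrix: np.ndarray
    gene_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if not np.allclose(m, m.T, atol=1e-8) or np.any(np.diag(m) > 1e-8) or m.min() < 0:
            raise ValueError("not a valid distance matrix")


@dataclass(frozen=True)
class OkkcState:
    """Diagnostics of an OKKC run."""

    weights: FusionWeights
    betas: np.ndarray | None  # per-class kernel-ridge duals (k × n)
    lam: float
    k: int
    objective_trace: tuple[float, ...]
    n_iter: int


@dataclass(frozen=True)
class PartitionAgreement:
    """Pair counts and the derived Rand Index / NMI.

    a: pairs together in both partitions; b: apart in both; c: together in
    the first, apart in the second; d: apart in the first, together in the
    second.  RI = (a + b) / (a + b + c + d); NMI = M(C, P) / √(E(C)·E(P)).
    """

    a: int
    b: int
    c: int
    d: int
    ri: float
    mutual_information: float
    entropy_c: float
    entropy_p: float
    nmi: float


# --------------------------------------------------------------------------
# seeded numpy K-means (tiny problems dominate, so avoid per-call overhead)
# --------------------------------------------------------------------------


def _kmeans_once(X: np.ndarray, k: int, rng: np.random.Generator,
                 max_iter: int = 100) -> tuple[np.ndarray, float]:
    n = X.shape[0]
    # k-means++ seeding
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[int(rng.integers(n))]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[int(rng.integers(n))]
        else:
            centers[j] = X[int(rng.choice(n, p=d2 / total))]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        for j in range(k):  # re-seed emptied clusters at the farthest point
            if not np.any(new_labels == j):
                far = int(dist[np.arange(n), new_labels].argmax())
                new_labels[far] = j
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            centers[j] = X[labels == j].mean(axis=0)
    wcss = float(((X - centers[labels]) ** 2).sum())
    return labels + 1, wcss


def _kmeans(X: np.ndarray, k: int, rng: np.random.Generator,
            n_restarts: int = 10) -> np.ndarray:
    best_labels, best_wcss = None, np.inf
    for _ in range(n_restarts):
        labels, wcss = _kmeans_once(X, k, rng)
        if wcss < best_wcss - 1e-12:
            best_labels, best_wcss = labels, wcss
    return best_labels


def kmeans_partition(view: View, k: int, seed: int = 0, n_restarts: int = 10,
                     gene_ids: Sequence[str] | None = None) -> Partition:
    """Euclidean K-means on gene rows, best of ``n_restarts`` by WCSS."""
    X = view.rows(gene_ids) if gene_ids is not None else view.weights
    ids = tuple(gene_ids) if gene_ids is not None else view.gene_ids
    if k < 1 or k > len({tuple(r) for r in np.round(X, 12)}):
        raise ValueError("k must be between 1 and the number of distinct rows")
    if k == 1:
        return Partition(labels=np.ones(X.shape[0], dtype=int), k=1, gene_ids=ids)
    rng = np.random.default_rng(seed)
    return Partition(labels=_kmeans(X, k, rng, n_restarts), k=k, gene_ids=ids)


# --------------------------------------------------------------------------
# consensus functions
# --------------------------------------------------------------------------


def _check_aligned(partitions: Sequence[Partition]) -> int:
    if not partitions:
        raise ValueError("no partitions supplied")
    n = partitions[0].n
    ids = partitions[0].gene_ids
    for p in partitions[1:]:
        if p.n != n or p.gene_ids != ids:
            raise ValueError("partitions are not aligned on the same gene set")
    return n


def coassociation(partitions: Sequence[Partition]) -> CoAssociation:
    """Entry (i, j): fraction of partitions placing genes i and j together."""
    n = _check_aligned(partitions)
    acc = np.zeros((n, n))
    for p in partitions:
        acc += (p.labels[:, None] == p.labels[None, :]).astype(float)
    return CoAssociation(matrix=acc / len(partitions), gene_ids=partitions[0].gene_ids)


def _spectral_partition(S: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-way cut of a similarity graph: normalized spectral embedding + K-means."""
    S = np.clip(np.asarray(S, float), 0.0, None)
    d = S.sum(axis=1)
    d[d <= 0] = 1.0
    dinv = 1.0 / np.sqrt(d)
    L = dinv[:, None] * S * dinv[None, :]
    w, V = np.linalg.eigh(0.5 * (L + L.T))
    emb = V[:, -k:]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return _kmeans(emb / norms, k, rng)


def _greedy_align(labels: np.ndarray, k_from: int, ref_labels: np.ndarray,
                  k_ref: int) -> dict[int, int]:
    """Greedy cluster→reference-column matching by overlap counts."""
    C = np.zeros((k_from, k_ref))
    for a, b in zip(labels, ref_labels):
        C[a - 1, b - 1] += 1
    mapping: dict[int, int] = {}
    used: set[int] = set()
    flat = sorted(
        ((C[i, j], -i, -j, i, j) for i in range(k_from) for j in range(k_ref)),
        reverse=True,
    )
    for _, _, _, i, j in flat:
        if i not in mapping and j not in used:
            mapping[i] = j
            used.add(j)
    free = [j for j in range(k_ref) if j not in used]
    for i in range(k_from):
        if i not in mapping:
            mapping[i] = free.pop(0) if free else int(C[i].argmax())
    return mapping


def _canonicalize(p: Partition) -> Partition:
    """Relabel clusters by first appearance so label ids carry no information."""
    mapping: dict[int, int] = {}
    out = np.empty_like(p.labels)
    for i, l in enumerate(p.labels):
        if l not in mapping:
            mapping[l] = len(mapping) + 1
        out[i] = mapping[l]
    return Partition(labels=out, k=p.k, gene_ids=p.gene_ids)


def consensus_combine(partitions: Sequence[Partition], k: int, method: str,
                      seed: int = 0) -> Partition:
    """Combine an ensemble of partitions into one consolidated partition.

    Inputs are canonicalized first, so the result is invariant to any
    relabeling of the input partitions' cluster ids.
    """
    if method not in CONSENSUS_METHODS:
        raise ValueError(f"unknown consensus method {method!r}")
    if len(partitions) < 2:
        raise ValueError("consensus needs at least two partitions")
    if k < 2:
        raise ValueError("k must be at least 2")
    n = _check_aligned(partitions)
    partitions = [_canonicalize(p) for p in partitions]
    if all(p.k >= p.n for p in partitions):
        raise ValueError("degenerate ensemble: every partition is all singletons")
    rng = np.random.default_rng(seed)
    ids = partitions[0].gene_ids

    if method == "CSPA":
        S = coassociation(partitions).matrix
        labels = _spectral_partition(S, k, rng)
    elif method == "HGPA":
        # star-expanded hyperedge graph: each cluster is one hyperedge,
        # weighted inversely by its size
        H = np.hstack([p.onehot() for p in partitions])
        sizes = H.sum(axis=0)
        sizes[sizes == 0] = 1.0
        S = (H / sizes) @ H.T
        labels = _spectral_partition(S, k, rng)
    elif method == "MCLA":
        H = np.hstack([p.onehot() for p in partitions])  # n × total clusters
        inter = H.T @ H
        sizes = H.sum(axis=0)
        union = sizes[:, None] + sizes[None, :] - inter
        union[union <= 0] = 1.0
        jac = inter / union
        meta = _spectral_partition(jac, k, rng)  # meta-cluster the hyperedges
        assoc = np.zeros((n, k))
        for j in range(k):
            cols = meta == j + 1
            if cols.any():
                assoc[:, j] = H[:, cols].mean(axis=1)
        labels = assoc.argmax(axis=1) + 1
        for j in range(k):  # keep every requested cluster non-empty if possible
            if not np.any(labels == j + 1) and assoc[:, j].max() > 0:
                labels[int(assoc[:, j].argmax())] = j + 1
    elif method == "QMI":
        # category-utility feature space: centered one-hot encodings
        B = np.hstack([p.onehot() - p.onehot().mean(axis=0) for p in partitions])
        labels = _kmeans(B, k, rng)
    elif method == "EACAL":
        D = 1.0 - coassociation(partitions).matrix
        np.fill_diagonal(D, 0.0)
        Z = sch.linkage(squareform(D, checks=False), method="average")
        labels = sch.fcluster(Z, t=k, criterion="maxclust")
    else:  # AdacVote
        entropies = []
        for p in partitions:
            freq = np.bincount(p.labels)[1:] / p.n
            freq = freq[freq > 0]
            entropies.append(float(-(freq * np.log(freq)).sum()))
        order = sorted(range(len(partitions)), key=lambda i: (-entropies[i], i))
        k_ref = max(max(p.k for p in partitions), k)
        ref = np.zeros((n, k_ref))
        first = partitions[order[0]]
        ref[np.arange(n), first.labels - 1] = 1.0
        for step, pi in enumerate(order[1:], start=1):
            p = partitions[pi]
            cur = ref.argmax(axis=1) + 1
            mapping = _greedy_align(p.labels, p.k, cur, k_ref)
            aligned = np.zeros((n, k_ref))
            aligned[np.arange(n), [mapping[l - 1] for l in p.labels]] = 1.0
            ref = (step * ref + aligned) / (step + 1)
        votes = ref.argmax(axis=1)
        # compress the voted clusters onto 1..k by size rank
        uniq, inv, counts = np.unique(votes, return_inverse=True, return_counts=True)
        by_size = np.argsort(-counts, kind="stable")
        rank_of = np.empty_like(by_size)
        rank_of[by_size] = np.arange(uniq.size)
        labels = np.minimum(rank_of[inv], k - 1) + 1

    return Partition(labels=np.asarray(labels, int), k=k, gene_ids=ids)


# --------------------------------------------------------------------------
# kernel fusion clustering
# --------------------------------------------------------------------------


def hilbert_distance(kernels: Sequence[KernelMatrix],
                     weights: FusionWeights | Sequence[float] | None = None,
                     trace_normalize: bool = False) -> HilbertDistance:
    """Distance matrix in the fused feature space.

    d(x, z) = √(K(x,x) − 2K(x,z) + K(z,z)) on the μ-weighted combined
    kernel.  For a single linear kernel on unit-norm rows this is exactly
    the Euclidean distance between the normalized profiles.
    """
    mu = weights.mu if isinstance(weights, FusionWeights) else weights
    K = combine_kernels(kernels, mu, trace_normalize=trace_normalize).gram
    diag = np.diag(K)
    d2 = diag[:, None] + diag[None, :] - 2.0 * K
    if d2.min() < -1e-10 * max(1.0, abs(diag).max()):
        raise FloatingPointError(f"negative squared distance {d2.min():.3g}")
    D = np.sqrt(np.clip(d2, 0.0, None))
    np.fill_diagonal(D, 0.0)
    return HilbertDistance(matrix=0.5 * (D + D.T), gene_ids=kernels[0].gene_ids)


def linkage_partition(dist: HilbertDistance, method: str, k: int) -> Partition:
    """Cut an agglomerative dendrogram (single/complete/average/ward) at k."""
    if method not in ("single", "complete", "average", "ward"):
        raise ValueError(f"unknown linkage method {method!r}")
    Z = sch.linkage(squareform(dist.matrix, checks=False), method=method)
    labels = sch.fcluster(Z, t=k, criterion="maxclust")
    return Partition(labels=labels, k=k, gene_ids=dist.gene_ids)


def kernel_kmeans(kernel: KernelMatrix, k: int, seed: int = 0,
                  n_restarts: int = 10, max_iter: int = 100) -> Partition:
    """Seeded kernel K-means (feature-space Lloyd iterations).

    Distances to cluster means are computed from the Gram matrix alone;
    emptied clusters are re-seeded at the point farthest from its centroid.
    """
    K = kernel.gram
    n = K.shape[0]
    if not 1 <= k <= n:
        raise ValueError("k out of range")
    diag = np.diag(K)
    rng = np.random.default_rng(seed)
    best_labels, best_obj = None, np.inf
    for _ in range(n_restarts):
        labels = _kernel_kmeans_once(K, diag, k, rng, max_iter)
        obj = _kernel_distortion(K, diag, labels, k)
        if obj < best_obj - 1e-12:
            best_labels, best_obj = labels, obj
    return Partition(labels=best_labels, k=k, gene_ids=kernel.gene_ids)


def _cluster_stats(K: np.ndarray, labels: np.ndarray, k: int):
    n = K.shape[0]
    H = np.zeros((n, k))
    H[np.arange(n), labels - 1] = 1.0
    counts = H.sum(axis=0)
    counts[counts == 0] = 1.0
    m = (K @ H) / counts  # n × k: mean similarity to each cluster
    S = np.einsum("nk,nj->kj", H, K @ H).diagonal() / counts**2
    return m, S


def _kernel_kmeans_once(K: np.ndarray, diag: np.ndarray, k: int,
                        rng: np.random.Generator, max_iter: int,
                        init_labels: np.ndarray | None = None) -> np.ndarray:
    n = K.shape[0]
    if init_labels is None:
        labels = rng.integers(1, k + 1, size=n)
        for j in range(1, k + 1):  # ensure every cluster starts non-empty
            if not np.any(labels == j):
                labels[int(rng.integers(n))] = j
    else:
        labels = init_labels.copy()
    for _ in range(max_iter):
        m, S = _cluster_stats(K, labels, k)
        dist = diag[:, None] - 2.0 * m + S[None, :]
        new_labels = dist.argmin(axis=1) + 1
        for j in range(1, k + 1):
            if not np.any(new_labels == j):
                far = int(dist[np.arange(n), new_labels - 1].argmax())
                new_labels[far] = j
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return labels


def _kernel_distortion(K: np.ndarray, diag: np.ndarray, labels: np.ndarray,
                       k: int) -> float:
    m, S = _cluster_stats(K, labels, k)
    idx = labels - 1
    return float(diag.sum() - 2.0 * m[np.arange(K.shape[0]), idx].sum()
                 + S[idx].sum())


def _separation(K_norm: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Between-cluster separation Tr(Aᵀ K̃ A) for the normalized indicator A."""
    tot = 0.0
    for j in range(1, k + 1):
        mask = labels == j
        nj = mask.sum()
        if nj:
            tot += K_norm[np.ix_(mask, mask)].sum() / nj
    return float(tot)


def okkc(
    kernels: Sequence[KernelMatrix],
    k: int,
    lam: float = 1e-2,
    mu_min: float = 0.0,
    seed: int = 0,
    max_iter: int = 50,
    n_restarts: int = 10,
) -> tuple[Partition, OkkcState]:
    """Optimized kernel K-means clustering over a convex kernel combination.

    Alternates (i) kernel K-means on the current μ-combined trace-normalized
    kernel and (ii) a closed-form convex re-weighting maximizing the
    between-cluster separation Σ_i μ_i Tr(Aᵀ(K_i/r_i)A) − λ‖μ‖² subject to
    Σμ = 1, μ ≥ μ_min.  Both half-steps decrease the regularized distortion
    1 − Σ_i μ_i Tr(Aᵀ(K_i/r_i)A) + λ‖μ‖², recorded in ``objective_trace``.
    With μ_min = 1/N the weighting step is skipped and the result is exactly
    kernel K-means on the averagely combined (trace-normalized) kernel.
    """
    N = len(kernels)
    if N == 0 or k < 2:
        raise ValueError("need at least one kernel and k ≥ 2")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if not -1e-12 <= mu_min <= 1.0 / N + 1e-12:
        raise ValueError("mu_min must be in [0, 1/N]")
    Ks = np.stack([kk.gram / kk.trace_r for kk in kernels])
    ids = kernels[0].gene_ids

    if abs(mu_min - 1.0 / N) <= 1e-12:
        avg = combine_kernels(kernels, uniform_weights(N), trace_normalize=True)
        part = kernel_kmeans(avg, k, seed=seed, n_restarts=n_restarts)
        mu = uniform_weights(N)
        sep = np.array([_separation(Ks[i], part.labels, k) for i in range(N)])
        obj = 1.0 - float(mu @ sep) + lam * float(mu @ mu)
        betas = _ridge_betas(np.tensordot(mu, Ks, axes=1), part.labels, k, lam)
        state = OkkcState(weights=FusionWeights(mu=mu, mu_min=mu_min), betas=betas,
                          lam=lam, k=k, objective_trace=(obj,), n_iter=1)
        return part, state

    rng = np.random.default_rng(seed)
    mu = uniform_weights(N)
    diag_cache = None
    labels = None
    trace: list[float] = []
    for it in range(max_iter):
        Kmu = np.tensordot(mu, Ks, axes=1)
        diag_cache = np.diag(Kmu)
        if labels is None:
            best, best_obj = None, np.inf
            for _ in range(n_restarts):
                cand = _kernel_kmeans_once(Kmu, diag_cache, k, rng, 100)
                o = _kernel_distortion(Kmu, diag_cache, cand, k)
                if o < best_obj - 1e-12:
                    best, best_obj = cand, o
            new_labels = best
        else:
            new_labels = _kernel_kmeans_once(Kmu, diag_cache, k, rng, 100,
                                             init_labels=labels)
        sep = np.array([_separation(Ks[i], new_labels, k) for i in range(N)])
        trace.append(1.0 - float(mu @ sep) + lam * float(mu @ mu))
        new_mu = project_capped_simplex(sep / (2.0 * lam), upper=1.0,
                                        lower=max(mu_min, 0.0))
        trace.append(1.0 - float(new_mu @ sep) + lam * float(new_mu @ new_mu))
        converged = labels is not None and np.array_equal(new_labels, labels) \
            and np.allclose(new_mu, mu, atol=1e-9)
        labels, mu = new_labels, new_mu
        if converged:
            break
    part = Partition(labels=labels, k=k, gene_ids=ids)
    betas = _ridge_betas(np.tensordot(mu, Ks, axes=1), labels, k, lam)
    state = OkkcState(weights=FusionWeights(mu=mu, mu_min=mu_min), betas=betas,
                      lam=lam, k=k, objective_trace=tuple(trace), n_iter=it + 1)
    return part, state


def _ridge_betas(Kmu: np.ndarray, labels: np.ndarray, k: int, lam: float) -> np.ndarray:
    """Per-class kernel-ridge dual vectors on ±1 class indicators."""
    n = Kmu.shape[0]
    A = Kmu + lam * np.eye(n)
    L = np.stack([(labels == j + 1) * 2.0 - 1.0 for j in range(k)], axis=1)
    return np.linalg.solve(A, L).T


# --------------------------------------------------------------------------
# external validation
# --------------------------------------------------------------------------


def agreement(partition: Partition, labels: Partition) -> PartitionAgreement:
    """Pair-counting agreement (Rand Index) and NMI between two partitions."""
    if partition.n != labels.n or (
        partition.gene_ids is not None
        and labels.gene_ids is not None
        and partition.gene_ids != labels.gene_ids
    ):
        raise ValueError("partitions are not aligned")
    n = partition.n
    C = np.zeros((partition.k, labels.k))
    for i, j in zip(partition.labels, labels.labels):
        C[i - 1, j - 1] += 1

    def _pairs(x: np.ndarray) -> float:
        return float((x * (x - 1) / 2).sum())

    a = _pairs(C)
    same_c = _pairs(C.sum(axis=1))
    same_p = _pairs(C.sum(axis=0))
    total = n * (n - 1) / 2
    c = same_c - a
    d = same_p - a
    b = total - a - c - d
    ri = (a + b) / total if total else 1.0

    p_ij = C / n
    p_i = p_ij.sum(axis=1)
    p_j = p_ij.sum(axis=0)
    nz = p_ij > 0
    mi = float((p_ij[nz] * np.log(p_ij[nz] / np.outer(p_i, p_j)[nz])).sum())
    e_c = float(-(p_i[p_i > 0] * np.log(p_i[p_i > 0])).sum())
    e_p = float(-(p_j[p_j > 0] * np.log(p_j[p_j > 0])).sum())
    if e_c <= 0 or e_p <= 0:
        # degenerate single-cluster partitions: identical → 1, else 0
        nmi = 1.0 if (e_c <= 0 and e_p <= 0) else 0.0
    else:
        nmi = mi / np.sqrt(e_c * e_p)
    return PartitionAgreement(
        a=int(round(a)), b=int(round(b)), c=int(round(c)), d=int(round(d)),
        ri=float(ri), mutual_information=mi, entropy_c=e_c, entropy_p=e_p,
        nmi=float(min(max(nmi, 0.0), 1.0)),
    )


# --------------------------------------------------------------------------
# all-pairs two-disease evaluation protocol
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ClusterEvalReport:
    """RI/NMI summary over all disease pairs × repetitions."""

    method: str
    ri: np.ndarray
    nmi: np.ndarray
    tasks: tuple[tuple[str, str, int], ...]
    per_view: Mapping[str, tuple[np.ndarray, np.ndarray]] | None = None
    skipped: tuple[tuple[str, str], ...] = ()
    config: Mapping[str, object] = field(default_factory=dict)

    @property
    def mean_ri(self) -> float:
        return float(self.ri.mean())

    @property
    def std_ri(self) -> float:
        return float(self.ri.std(ddof=1)) if self.ri.size > 1 else 0.0

    @property
    def mean_nmi(self) -> float:
        return float(self.nmi.mean())

    @property
    def std_nmi(self) -> float:
        return float(self.nmi.std(ddof=1)) if self.nmi.size > 1 else 0.0

    def view_mean_ri(self) -> dict[str, float]:
        if self.per_view is None:
            return {}
        return {name: float(ri.mean()) for name, (ri, _) in self.per_view.items()}


def disease_pairs(diseases: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered disease pairs (C(n, 2) binary clustering tasks)."""
    return list(itertools.combinations(sorted(diseases), 2))


def _pair_genes(dataset: MultiViewDataset, d1: str, d2: str) -> list[str]:
    """Genes of either disease, dropping genes labeled with both."""
    out = []
    for g, ds in dataset.labels.items():
        has1, has2 = d1 in ds, d2 in ds
        if has1 != has2:
            out.append(g)
    return sorted(out)


def pairwise_disease_eval(
    dataset: MultiViewDataset,
    method_spec: Mapping[str, object],
    n_reps: int = 20,
    seed: int = 0,
    k: int = 2,
) -> ClusterEvalReport:
    """Score a clustering method on every two-disease task of the benchmark.

    ``method_spec["kind"]`` selects the pipeline:

    - ``"single-view"`` — K-means per view; per-view RI/NMI reported;
    - ``"consensus"`` — per-view K-means + a consensus function
      (``method_spec["method"]`` in CSPA/HGPA/MCLA/QMI/EACAL/AdacVote);
    - ``"linkage-fusion"`` — averaged-kernel Hilbert distance + linkage
      (``method_spec["linkage"]``);
    - ``"okkc"`` — OKKC with ``method_spec.get("mu_min", 0.0)`` and
      ``method_spec.get("lambda", 1e-2)``.
    """
    kind = method_spec.get("kind")
    diseases = dataset.diseases
    if len(diseases) < 2:
        raise ValueError("need at least two diseases")
    pairs = disease_pairs(diseases)
    views = dataset.views

    ri_all: list[float] = []
    nmi_all: list[float] = []
    tasks: list[tuple[str, str, int]] = []
    skipped: list[tuple[str, str]] = []
    per_view: dict[str, tuple[list[float], list[float]]] | None = (
        {v.name: ([], []) for v in views} if kind == "single-view" else None
    )

    for pi, (d1, d2) in enumerate(pairs):
        genes = _pair_genes(dataset, d1, d2)
        if len(genes) < 4:
            warnings.warn(f"pair ({d1}, {d2}) has fewer than 4 exclusive genes; skipped",
                          stacklevel=2)
            skipped.append((d1, d2))
            continue
        truth = Partition(
            labels=np.array([1 if d1 in dataset.labels[g] else 2 for g in genes]),
            k=2, gene_ids=tuple(genes),
        )
        Xs = [v.rows(genes) for v in views]
        sub_views = [
            View(name=v.name, gene_ids=tuple(genes), term_ids=v.term_ids,
                 weights=X, weighting=v.weighting)
            for v, X in zip(views, Xs)
        ]
        if kind in ("linkage-fusion", "okkc"):
            kernels = [linear_kernel(sv, psd_clip=False) for sv in sub_views]
        for rep in range(n_reps):
            task_seed = np.random.SeedSequence([seed, pi, rep]).generate_state(1)[0]
            if kind == "single-view":
                for sv in sub_views:
                    part = kmeans_partition(sv, k, seed=task_seed)
                    ag = agreement(part, truth)
                    per_view[sv.name][0].append(ag.ri)
                    per_view[sv.name][1].append(ag.nmi)
                tasks.append((d1, d2, rep))
                continue
            if kind == "consensus":
                base = [kmeans_partition(sv, k, seed=task_seed) for sv in sub_views]
                part = consensus_combine(base, k, method=str(method_spec["method"]),
                                         seed=task_seed)
            elif kind == "linkage-fusion":
                dist = hilbert_distance(kernels)
                part = linkage_partition(dist, str(method_spec.get("linkage", "ward")), k)
            elif kind == "okkc":
                part, _ = okkc(kernels, k,
                               lam=float(method_spec.get("lambda", 1e-2)),
                               mu_min=float(method_spec.get("mu_min", 0.0)),
                               seed=int(task_seed))
            else:
                raise ValueError(f"unknown method kind {kind!r}")
            ag = agreement(part, truth)
            ri_all.append(ag.ri)
            nmi_all.append(ag.nmi)
            tasks.append((d1, d2, rep))

    config = dict(method_spec) | {"n_reps": n_reps, "seed": seed, "k": k}
    if kind == "single-view":
        pv = {
            name: (np.asarray(r), np.asarray(m)) for name, (r, m) in per_view.items()
        }
        best = max(pv, key=lambda nm: pv[nm][0].mean())
        return ClusterEvalReport(
            method="single-view", ri=pv[best][0], nmi=pv[best][1],
            tasks=tuple(tasks), per_view=pv, skipped=tuple(skipped), config=config,
        )
    return ClusterEvalReport(
        method=str(method_spec.get("method", kind)), ri=np.asarray(ri_all),
        nmi=np.asarray(nmi_all), tasks=tuple(tasks), skipped=tuple(skipped),
        config=config,
    )
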