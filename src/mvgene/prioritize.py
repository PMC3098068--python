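"""Gene prioritization on single views and by multi-view integration.

Single-view ranking scores a candidate by the Pearson correlation between
its profile and the disease model (the mean profile of the training genes).
Multi-view integration comes in two flavours:

* *ensemble ranking* — combine per-view scores by average/max, or combine
  per-view rank ratios through the joint cumulative distribution of uniform
  order statistics (the Q statistic, evaluated by the V_k recursion with
  V_0 = 1) and convert Q to a p-value under a simulated null calibrated
  with a beta (N ≤ 5) or gamma (N > 5) fit;
* *kernel fusion* — a one-class SVM over a convex, trace-regularized
  combination of view kernels; the kernel weights μ are the dual variables
  of the quadratic constraints, sum to one, and can be floored at μ_min
  (μ_min = 1/N reproduces the uniform combination).

Benchmarking uses the leave-one-out protocol: each disease gene in turn is
the "defector", hidden among randomly drawn candidate genes, and the error
is 1 − AUC of its recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.stats

from ._qp import one_svm_fusion_qp
from .kernels import KernelMatrix, linear_kernel
from .views import MultiViewDataset, View

__all__ = [
    "RankingList",
    "QStatistic",
    "QCalibration",
    "FusionWeights",
    "OneSvmModel",
    "LooReport",
    "build_model",
    "score_correlation",
    "rank",
    "fuse_scores",
    "q_statistic",
    "q_statistic_batch",
    "calibrate_q",
    "q_pvalue",
    "fit_one_svm_fusion",
    "score_one_svm",
    "loo_benchmark",
]


# --------------------------------------------------------------------------
# ranking containers
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RankingList:
    """Candidates ordered by decreasing score, with rank ratios p/n."""

    candidate_ids: tuple[str, ...]
    scores: np.ndarray
    rank_ratios: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.candidate_ids)
        if self.scores.shape != (n,) or self.rank_ratios.shape != (n,):
            raise ValueError("misaligned ranking fields")
        if np.any(self.rank_ratios <= 0) or np.any(self.rank_ratios > 1):
            raise ValueError("rank ratios must lie in (0, 1]")

    def ratio_of(self, gene_id: str) -> float:
        return float(self.rank_ratios[self.candidate_ids.index(gene_id)])


@dataclass(frozen=True)
class QStatistic:
    value: float
    n_sources: int
    ratios: tuple[float, ...]  # sorted ascending
    v_coeffs: tuple[float, ...]  # V_0 .. V_N, V_0 = 1


@dataclass(frozen=True)
class QCalibration:
    """Null distribution fit of Q under uniform random rank ratios."""

    n_sources: int
    family: str  # "beta" or "gamma"
    params: tuple[float, ...]
    n_samples: int
    seed: int

    def cdf(self, q: float | np.ndarray) -> float | np.ndarray:
        if self.family == "beta":
            return scipy.stats.beta.cdf(q, *self.params)
        return scipy.stats.gamma.cdf(q, *self.params)


@dataclass(frozen=True)
class FusionWeights:
    """Convex kernel weights μ with a per-kernel floor μ_min."""

    mu: np.ndarray
    mu_min: float = 0.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float)
        object.__setattr__(self, "mu", mu)
        if abs(mu.sum() - 1.0) > 1e-6:
            raise ValueError(f"kernel weights must sum to 1 (got {mu.sum():.8f})")
        if np.any(mu < self.mu_min - 1e-8):
            raise ValueError("a kernel weight violates the mu_min floor")


@dataclass(frozen=True)
class OneSvmModel:
    alphas: np.ndarray  # M non-negative dual variables
    weights: FusionWeights
    nu: float
    training_ids: tuple[str, ...]
    combined_kernel: KernelMatrix  # Ω over training + candidate genes
    t_value: float  # optimal objective of the minimax program


@dataclass(frozen=True)
class LooReport:
    """Leave-one-out 1 − AUC summary (mean over defectors × repetitions)."""

    method: str
    errors: np.ndarray  # one entry per (disease, defector, repetition)
    tasks: tuple[tuple[str, str, int], ...]  # (disease, defector, rep)
    per_view: Mapping[str, np.ndarray] | None = None
    config: Mapping[str, object] = field(default_factory=dict)

    @property
    def mean_error(self) -> float:
        return float(self.errors.mean())

    @property
    def std_error(self) -> float:
        return float(self.errors.std(ddof=1)) if self.errors.size > 1 else 0.0

    def view_means(self) -> dict[str, float]:
        if self.per_view is None:
            return {}
        return {name: float(e.mean()) for name, e in self.per_view.items()}

    def best_single_view(self) -> tuple[str, float]:
        means = self.view_means()
        if not means:
            raise ValueError("report has no per-view errors")
        name = min(means, key=means.get)
        return name, means[name]


# --------------------------------------------------------------------------
# single-view scoring
# --------------------------------------------------------------------------


def build_model(training_profiles: np.ndarray) -> np.ndarray:
    """Disease model: the arithmetic mean of the training gene profiles."""
    P = np.atleast_2d(np.asarray(training_profiles, dtype=float))
    if P.shape[0] < 1:
        raise ValueError("empty training set")
    nonzero = np.any(P != 0, axis=1)
    if not nonzero.any():
        raise ValueError("degenerate model: all training profiles are zero")
    return P.mean(axis=0)


def _center_normalize(X: np.ndarray) -> np.ndarray:
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    out = np.zeros_like(Xc)
    ok = norms[:, 0] > 0
    out[ok] = Xc[ok] / norms[ok]
    return out


def score_correlation(model: np.ndarray, candidates: np.ndarray) -> np.ndarray:
    """Pearson correlation of each candidate row with the model vector.

    Constant (zero-variance) candidates or a constant model score 0 by
    convention.
    """
    model = np.asarray(model, dtype=float)
    C = np.atleast_2d(np.asarray(candidates, dtype=float))
    if C.shape[1] != model.size:
        raise ValueError("candidate dimensionality does not match the model")
    m = _center_normalize(model[None, :])[0]
    Z = _center_normalize(C)
    return Z @ m


def _rank_order(scores: np.ndarray, candidate_ids: Sequence[str]) -> np.ndarray:
    """Indices sorting by descending score, ties broken by ascending id."""
    ids = np.asarray(candidate_ids)
    return np.lexsort((ids, -np.asarray(scores, dtype=float)))


def rank(scores: np.ndarray, candidate_ids: Sequence[str]) -> RankingList:
    """Rank candidates by descending score; rank ratio = position / n."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if n < 1:
        raise ValueError("nothing to rank")
    order = _rank_order(scores, candidate_ids)
    ratios = np.empty(n)
    ratios[order] = np.arange(1, n + 1) / n
    ordered = tuple(candidate_ids[i] for i in order)
    return RankingList(
        candidate_ids=ordered, scores=scores[order], rank_ratios=ratios[order]
    )


def fuse_scores(score_lists: Sequence[np.ndarray], method: str = "average") -> np.ndarray:
    """Element-wise mean or max of aligned per-view score vectors."""
    if len(score_lists) < 2:
        raise ValueError("fusion needs at least two score vectors")
    S = np.vstack([np.asarray(s, dtype=float) for s in score_lists])
    if method == "average":
        return S.mean(axis=0)
    if method == "max":
        return S.max(axis=0)
    raise ValueError(f"unknown fusion method {method!r}")


# --------------------------------------------------------------------------
# order statistics
# --------------------------------------------------------------------------


def q_statistic_batch(ratios: np.ndarray) -> np.ndarray:
    """Vectorized Q statistic for a (batch × N) array of rank ratios.

    Q is the probability that N uniform order statistics fall jointly below
    the sorted observed ratios, evaluated by the recursion
    V_k = Σ_{i=1..k} (−1)^{i−1} V_{k−i} r_{N−k+1}^i / i!  with V_0 = 1 and
    Q = N! · V_N.
    """
    R = np.atleast_2d(np.asarray(ratios, dtype=float))
    if np.any(R <= 0) or np.any(R > 1):
        raise ValueError("rank ratios must lie in (0, 1]")
    R = np.sort(R, axis=1)
    b, N = R.shape
    V = np.zeros((b, N + 1))
    V[:, 0] = 1.0
    for k in range(1, N + 1):
        r = R[:, N - k]  # r_{N-k+1}
        acc = np.zeros(b)
        for i in range(1, k + 1):
            acc += (-1.0) ** (i - 1) * V[:, k - i] * r**i / math.factorial(i)
        V[:, k] = acc
    q = math.factorial(N) * V[:, N]
    return np.clip(q, 0.0, 1.0)


def q_statistic(ratios: Sequence[float]) -> QStatistic:
    """Q statistic of one gene's rank ratios across the N views."""
    r = np.sort(np.asarray(ratios, dtype=float))
    if r.ndim != 1 or r.size < 1:
        raise ValueError("need a 1-d vector of rank ratios")
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("rank ratios must lie in (0, 1]")
    N = r.size
    V = [1.0]
    for k in range(1, N + 1):
        rk = r[N - k]
        V.append(
            sum(
                (-1.0) ** (i - 1) * V[k - i] * rk**i / math.factorial(i)
                for i in range(1, k + 1)
            )
        )
    q = float(np.clip(math.factorial(N) * V[N], 0.0, 1.0))
    return QStatistic(value=q, n_sources=N, ratios=tuple(r), v_coeffs=tuple(V))


def calibrate_q(N: int, n_samples: int = 50_000, seed: int = 0) -> QCalibration:
    """Fit the null distribution of Q under uniform random rank ratios.

    Beta for N ≤ 5, gamma for N > 5, both by maximum likelihood with the
    location pinned at 0.
    """
    if n_samples < 10_000:
        raise ValueError("calibration needs at least 10^4 samples")
    rng = np.random.default_rng(seed)
    ratios = rng.uniform(1e-12, 1.0, size=(n_samples, N))
    q = q_statistic_batch(ratios)
    q = np.clip(q, 1e-300, 1.0)
    if N <= 5:
        a, b, loc, scale = scipy.stats.beta.fit(q, floc=0.0, fscale=1.0)
        params: tuple[float, ...] = (a, b, loc, scale)
        family = "beta"
    else:
        a, loc, scale = scipy.stats.gamma.fit(q, floc=0.0)
        params = (a, loc, scale)
        family = "gamma"
    if not all(np.isfinite(params)):
        raise RuntimeError(f"degenerate Q calibration for N={N}: params={params}")
    return QCalibration(
        n_sources=N, family=family, params=params, n_samples=n_samples, seed=seed
    )


def q_pvalue(q: QStatistic | float | np.ndarray, cal: QCalibration):
    """Left-tail p-value of a Q statistic under the calibrated null."""
    if isinstance(q, QStatistic):
        if q.n_sources != cal.n_sources:
            raise ValueError("calibration was fitted for a different number of views")
        return float(cal.cdf(q.value))
    return cal.cdf(q)


# --------------------------------------------------------------------------
# one-class SVM kernel fusion
# --------------------------------------------------------------------------


def fit_one_svm_fusion(
    kernels: Sequence[KernelMatrix],
    training_ids: Sequence[str],
    nu: float = 0.5,
    mu_min: float = 0.0,
) -> OneSvmModel:
    """Fit the one-class-SVM kernel-fusion model.

    ``kernels`` are centered PSD Gram matrices over training + candidate
    genes, all on the same gene ordering.  Each kernel's quadratic form is
    regularized by its trace r_j; the returned μ are the dual variables of
    the quadratic constraints (Σμ = 1, μ ≥ μ_min).
    """
    if len(kernels) < 1:
        raise ValueError("no kernels supplied")
    ids = kernels[0].gene_ids
    for k in kernels:
        if k.gene_ids != ids:
            raise ValueError("kernels are not aligned")
        k.validate_psd()
    index = {g: i for i, g in enumerate(ids)}
    tr_idx = np.array([index[g] for g in training_ids])
    M = tr_idx.size
    if M < 2:
        raise ValueError("need at least two training genes")
    H_list = [k.gram[np.ix_(tr_idx, tr_idx)] / k.trace_r for k in kernels]
    alpha, mu, t = one_svm_fusion_qp(H_list, nu=nu, M=M, mu_min=mu_min)
    omega = np.zeros_like(kernels[0].gram)
    for w, k in zip(mu, kernels):
        omega += w * k.gram / k.trace_r
    return OneSvmModel(
        alphas=alpha,
        weights=FusionWeights(mu=mu, mu_min=mu_min),
        nu=nu,
        training_ids=tuple(training_ids),
        combined_kernel=KernelMatrix(gram=omega, gene_ids=ids, name="omega"),
        t_value=t,
    )


def score_one_svm(model: OneSvmModel, candidate_ids: Sequence[str]) -> np.ndarray:
    """Score candidates with the fused kernel: Σ_i α_i Ω(x, x_i), normalized.

    The raw weighted sum is divided by ‖w‖_Ω · √Ω(x, x) (a cosine in the
    fused feature space) so scores lie in [−1, +1]; residual floating-point
    overshoot is clipped.  Candidates with vanishing self-similarity score 0.
    """
    K = model.combined_kernel
    index = {g: i for i, g in enumerate(K.gene_ids)}
    try:
        cand_idx = np.array([index[g] for g in candidate_ids])
    except KeyError as e:
        raise KeyError(f"candidate {e.args[0]!r} was not in the fitted kernels") from e
    tr_idx = np.array([index[g] for g in model.training_ids])
    raw = model.alphas @ K.gram[np.ix_(tr_idx, cand_idx)]
    w_norm = math.sqrt(max(model.t_value, 0.0))
    self_sim = np.clip(np.diag(K.gram)[cand_idx], 0.0, None)
    denom = w_norm * np.sqrt(self_sim)
    scores = np.zeros(cand_idx.size)
    ok = denom > 1e-12
    scores[ok] = raw[ok] / denom[ok]
    return np.clip(scores, -1.0, 1.0)


# --------------------------------------------------------------------------
# leave-one-out benchmark
# --------------------------------------------------------------------------


def _error_from_scores(cand_scores: np.ndarray, defector_score: float) -> float:
    """1 − AUC with the defector as sole positive, midrank tie handling."""
    above = np.count_nonzero(cand_scores > defector_score)
    ties = np.count_nonzero(cand_scores == defector_score)
    return (above + 0.5 * ties) / cand_scores.size


def loo_benchmark(
    dataset: MultiViewDataset,
    method: str,
    n_candidates: int = 99,
    n_reps: int = 20,
    seed: int = 0,
    nu: float = 0.5,
    mu_min: float | None = None,
    calibration_samples: int = 50_000,
) -> LooReport:
    """Leave-one-out 1 − AUC benchmark over every disease of the dataset.

    For every repetition and every disease gene ("defector"), the remaining
    disease genes form the training set and the test set is the defector
    plus ``n_candidates`` genes drawn without replacement from the unlabeled
    pool (re-drawn per defector per repetition).  The error of a task is
    1 − AUC with the defector as the only positive.

    ``method`` is one of ``single-view`` (per-view errors reported),
    ``average``, ``max``, ``order-statistics`` or ``one-svm``.
    """
    methods = {"single-view", "average", "max", "order-statistics", "one-svm"}
    if method not in methods:
        raise ValueError(f"method must be one of {sorted(methods)}")
    views = dataset.views
    n_views = len(views)
    gene_index = {g: i for i, g in enumerate(dataset.gene_ids)}
    pool = np.array([gene_index[g] for g in dataset.unlabeled_genes])
    if pool.size < n_candidates:
        raise ValueError(
            f"candidate pool ({pool.size}) smaller than n_candidates ({n_candidates})"
        )
    zero_doc = set().union(*(v.zero_doc_genes for v in views))
    rng = np.random.default_rng(seed)

    if method == "one-svm":
        if mu_min is None:
            mu_min = 1.0 / n_views
        kernels = [linear_kernel(v, psd_clip=True) for v in views]
        traces = np.array([k.trace_r for k in kernels])
        grams = np.stack([k.gram for k in kernels])

    Z = None
    if method != "one-svm":
        Z = [np.ascontiguousarray(_center_normalize(v.weights)) for v in views]
        raw = [v.weights for v in views]

    cal = None
    if method == "order-statistics":
        cal = calibrate_q(n_views, n_samples=calibration_samples, seed=seed % (2**31))

    errors: list[float] = []
    tasks: list[tuple[str, str, int]] = []
    per_view: dict[str, list[float]] | None = (
        {v.name: [] for v in views} if method == "single-view" else None
    )
    cand_ids_arr = np.asarray(dataset.gene_ids)

    # cache of per-(disease, defector) 1-SVM solutions (candidate-independent
    # because kernels are centered once over the full gene universe)
    svm_cache: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, float]] = {}

    for disease in dataset.diseases:
        genes = [g for g in dataset.disease_genes(disease) if g not in zero_doc]
        if len(genes) < 2:
            raise ValueError(f"disease {disease!r} has fewer than two usable genes")
        gidx = np.array([gene_index[g] for g in genes])
        for rep in range(n_reps):
            for j, defector in enumerate(genes):
                train_idx = np.delete(gidx, j)
                cand = rng.choice(pool, size=n_candidates, replace=False)
                test_idx = np.concatenate(([gidx[j]], cand))
                test_ids = cand_ids_arr[test_idx]

                if method == "one-svm":
                    key = (disease, j)
                    if key not in svm_cache:
                        H_list = [
                            grams[v][np.ix_(train_idx, train_idx)] / traces[v]
                            for v in range(n_views)
                        ]
                        svm_cache[key] = one_svm_fusion_qp(
                            H_list, nu=nu, M=train_idx.size, mu_min=mu_min
                        )
                    alpha, mu, t = svm_cache[key]
                    scale = mu / traces
                    cross = np.einsum(
                        "v,vtc->tc", scale, grams[:, train_idx[:, None], test_idx]
                    )
                    raw_s = alpha @ cross
                    self_sim = np.clip(
                        np.einsum("v,vc->c", scale, grams[:, test_idx, test_idx]),
                        0.0,
                        None,
                    )
                    denom = math.sqrt(max(t, 0.0)) * np.sqrt(self_sim)
                    scores = np.zeros(test_idx.size)
                    ok = denom > 1e-12
                    scores[ok] = raw_s[ok] / denom[ok]
                    errors.append(_error_from_scores(scores[1:], scores[0]))
                    tasks.append((disease, defector, rep))
                    continue

                view_scores = np.empty((n_views, test_idx.size))
                for v in range(n_views):
                    model = raw[v][train_idx].mean(axis=0)
                    m = _center_normalize(model[None, :])[0]
                    view_scores[v] = Z[v][test_idx] @ m

                if method == "single-view":
                    for v, view in enumerate(views):
                        per_view[view.name].append(
                            _error_from_scores(view_scores[v, 1:], view_scores[v, 0])
                        )
                    tasks.append((disease, defector, rep))
                    continue

                if method in ("average", "max"):
                    fused = fuse_scores(list(view_scores), method=method)
                else:  # order-statistics
                    ratios = np.empty_like(view_scores)
                    for v in range(n_views):
                        order = _rank_order(view_scores[v], test_ids)
                        rr = np.empty(test_idx.size)
                        rr[order] = np.arange(1, test_idx.size + 1) / test_idx.size
                        ratios[v] = rr
                    qs = q_statistic_batch(ratios.T)
                    fused = -np.asarray(q_pvalue(qs, cal))
                errors.append(_error_from_scores(fused[1:], fused[0]))
                tasks.append((disease, defector, rep))

    config = {
        "method": method,
        "n_candidates": n_candidates,
        "n_reps": n_reps,
        "seed": seed,
        "nu": nu,
        "mu_min": mu_min,
    }
    if method == "single-view":
        pv = {name: np.asarray(e) for name, e in per_view.items()}
        best = min(pv, key=lambda k: pv[k].mean())
        return LooReport(
            method=method, errors=pv[best], tasks=tuple(tasks), per_view=pv, config=config
        )
    return LooReport(
        method=method, errors=np.asarray(errors), tasks=tuple(tasks), config=config
    )
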