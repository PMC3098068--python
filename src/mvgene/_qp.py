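"""Small convex solvers used by the kernel-fusion methods.

Two primitives:

* a projected-gradient (FISTA) solver for quadratic programs over the
  capped simplex {x : lower ≤ x ≤ upper, Σx = 1} — the dual feasible set of
  a ν-one-class SVM;
* a minimax solver for the one-class-SVM multiple-kernel program
  max_{μ ∈ Δ(μ_min)} min_{α ∈ A} αᵀ(Σ_j μ_j H_j)α, solved on the concave
  outer dual with Danskin gradients, where H_j are trace-normalized training
  Gram matrices.  The optimal μ are the dual variables of the quadratic
  constraints of the equivalent QCLP and sum to one.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize

__all__ = ["project_capped_simplex", "solve_qp_capped_simplex", "one_svm_fusion_qp"]


def project_capped_simplex(
    v: np.ndarray, upper: float, lower: float = 0.0
) -> np.ndarray:
    """Euclidean projection onto {x : lower ≤ x ≤ upper, Σ x = 1}.

    Solved by bisection on the shift τ in x = clip(v − τ, lower, upper).
    """
    v = np.asarray(v, dtype=float)
    n = v.size
    if lower * n > 1.0 + 1e-12 or upper * n < 1.0 - 1e-12:
        raise ValueError("capped simplex is empty for these bounds")
    lo = v.min() - upper - 1.0
    hi = v.max() - lower + 1.0
    for _ in range(100):
        tau = 0.5 * (lo + hi)
        s = np.clip(v - tau, lower, upper).sum()
        if s > 1.0:
            lo = tau
        else:
            hi = tau
    return np.clip(v - 0.5 * (lo + hi), lower, upper)


def solve_qp_capped_simplex(
    H: np.ndarray,
    upper: float,
    lower: float = 0.0,
    x0: np.ndarray | None = None,
    max_iter: int = 500,
    tol: float = 1e-11,
) -> tuple[np.ndarray, float]:
    """Minimize xᵀHx over the capped simplex (H PSD) with FISTA.

    Returns (x*, x*ᵀHx*).
    """
    H = np.asarray(H, dtype=float)
    n = H.shape[0]
    x = project_capped_simplex(
        np.full(n, 1.0 / n) if x0 is None else np.asarray(x0, float), upper, lower
    )
    # Lipschitz constant of the gradient 2Hx
    L = 2.0 * max(float(np.linalg.norm(H, 2)), 1e-12)
    y = x.copy()
    t = 1.0
    f_prev = float(x @ H @ x)
    for _ in range(max_iter):
        grad = 2.0 * (H @ y)
        x_new = project_capped_simplex(y - grad / L, upper, lower)
        t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
        y = x_new + ((t - 1.0) / t_new) * (x_new - x)
        f = float(x_new @ H @ x_new)
        if f > f_prev:  # adaptive restart
            y = x_new.copy()
            t_new = 1.0
        if abs(f_prev - f) <= tol * max(1.0, abs(f_prev)) and np.allclose(
            x, x_new, atol=1e-12
        ):
            x = x_new
            f_prev = f
            break
        x, t, f_prev = x_new, t_new, f
    return x, float(x @ H @ x)


def one_svm_fusion_qp(
    H_list: list[np.ndarray],
    nu: float,
    M: int,
    mu_min: float = 0.0,
    inner_iter: int = 800,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Solve the ν-one-class multiple-kernel minimax program.

    Parameters
    ----------
    H_list:
        Trace-normalized training Gram matrices G_j / r_j (PSD, M × M).
    nu:
        One-class regularization; α is constrained to 0 ≤ α ≤ 1/(νM),
        Σα = 1, so part of the training set may be treated as outliers.
    M:
        Number of training genes.
    mu_min:
        Lower bound on each kernel weight, 0 ≤ mu_min ≤ 1/N.  ``1/N``
        forces the exactly uniform combination.

    Returns
    -------
    (alpha, mu, t):
        Dual variables α, kernel weights μ (Σμ = 1, μ ≥ mu_min) and the
        optimal objective t = αᵀ(Σ μ_j H_j)α.
    """
    N = len(H_list)
    if N == 0:
        raise ValueError("no kernels supplied")
    if not 0.0 < nu <= 1.0:
        raise ValueError("nu must be in (0, 1]")
    if not -1e-12 <= mu_min <= 1.0 / N + 1e-12:
        raise ValueError("mu_min must be in [0, 1/N]")
    upper = 1.0 / (nu * M)
    if upper * M < 1.0 - 1e-12:
        raise ValueError("infeasible: nu too large for this training size")

    H_arr = np.stack([np.asarray(H, float) for H in H_list])

    def inner(mu: np.ndarray, x0=None) -> tuple[np.ndarray, float, np.ndarray]:
        Hmu = np.tensordot(mu, H_arr, axes=1)
        alpha, t = solve_qp_capped_simplex(Hmu, upper, x0=x0, max_iter=inner_iter)
        quads = np.einsum("i,nij,j->n", alpha, H_arr, alpha)
        return alpha, t, quads

    uniform = np.full(N, 1.0 / N)
    if N == 1 or abs(mu_min - 1.0 / N) <= 1e-12:
        alpha, t, _ = inner(uniform)
        return alpha, uniform, t

    # Concave outer maximization over μ with Danskin gradient q_j = αᵀH_jα.
    state = {"alpha": None}

    def neg_g(mu: np.ndarray):
        mu = project_capped_simplex(mu, upper=1.0, lower=mu_min)
        alpha, t, quads = inner(mu, x0=state["alpha"])
        state["alpha"] = alpha
        return -t, -quads

    res = minimize(
        neg_g,
        uniform,
        jac=True,
        method="SLSQP",
        bounds=[(mu_min, 1.0)] * N,
        constraints=[{"type": "eq", "fun": lambda m: m.sum() - 1.0,
                      "jac": lambda m: np.ones(N)}],
        options={"maxiter": 200, "ftol": 1e-12},
    )
    mu = project_capped_simplex(res.x, upper=1.0, lower=max(mu_min, 0.0))
    alpha, t, _ = inner(mu, x0=state["alpha"])
    return alpha, mu, float(t)
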