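"""Linear kernels over gene profiles and their convex combinations.

Gene-by-term profiles live in very high dimension, so all similarity is
computed through linear Gram matrices: rows are normalized to unit Euclidean
norm, the Gram matrix is double-centered, and tiny negative eigenvalues from
floating-point centering are clipped to keep the matrix positive
semidefinite.  Kernel-fusion methods consume convex combinations of such
kernels, optionally trace-normalized (each kernel divided by its trace r so
that no single view dominates by scale alone).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .views import View

__all__ = [
    "KernelMatrix",
    "linear_kernel",
    "center_gram",
    "combine_kernels",
    "uniform_weights",
]

PSD_TOL = 1e-8


@dataclass(frozen=True)
class KernelMatrix:
    """Symmetric PSD Gram matrix over an ordered gene set."""

    gram: np.ndarray
    gene_ids: tuple[str, ...]
    centered: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        g = np.asarray(self.gram, dtype=float)
        object.__setattr__(self, "gram", g)
        if g.shape != (len(self.gene_ids),) * 2:
            raise ValueError("gram shape does not match gene ids")
        if not np.allclose(g, g.T, atol=1e-8):
            raise ValueError("kernel matrix is not symmetric")

    @property
    def trace_r(self) -> float:
        """Trace of the Gram matrix — the r regularizer in kernel fusion."""
        return float(np.trace(self.gram))

    def validate_psd(self, tol: float = PSD_TOL) -> None:
        w = np.linalg.eigvalsh(self.gram)
        if w.min() < -tol * max(1.0, w.max()):
            raise ValueError(f"kernel {self.name!r} is not PSD (λmin={w.min():.3g})")

    def submatrix(self, gene_ids: Sequence[str]) -> "KernelMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        idx = np.array([index[g] for g in gene_ids])
        return KernelMatrix(
            gram=self.gram[np.ix_(idx, idx)],
            gene_ids=tuple(gene_ids),
            centered=self.centered,
            name=self.name,
        )


def center_gram(gram: np.ndarray) -> np.ndarray:
    """Double-center a Gram matrix (feature-space mean removal)."""
    row = gram.mean(axis=0, keepdims=True)
    col = gram.mean(axis=1, keepdims=True)
    return gram - row - col + gram.mean()


def linear_kernel(
    view: View,
    gene_ids: Sequence[str] | None = None,
    unit_norm: bool = True,
    center: bool = True,
    psd_clip: bool = True,
) -> KernelMatrix:
    """Centered linear kernel of (unit-normalized) gene rows of one view.

    ``psd_clip`` repairs numerically negative eigenvalues by clipping at 0;
    for large gene sets where centering alone guarantees PSD up to roundoff,
    it may be disabled for speed.
    """
    ids = tuple(gene_ids) if gene_ids is not None else view.gene_ids
    X = view.rows(ids) if gene_ids is not None else view.weights
    X = np.asarray(X, dtype=float)
    if unit_norm:
        norms = np.linalg.norm(X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        X = X / norms
    K = X @ X.T
    if center:
        K = center_gram(K)
    if psd_clip:
        w, V = np.linalg.eigh(K)
        if w.min() < -1e-10:
            K = (V * np.clip(w, 0.0, None)) @ V.T
        K = 0.5 * (K + K.T)
    return KernelMatrix(gram=K, gene_ids=ids, centered=center, name=view.name)


def uniform_weights(n: int) -> np.ndarray:
    return np.full(n, 1.0 / n)


def combine_kernels(
    kernels: Sequence[KernelMatrix],
    weights: Sequence[float] | None = None,
    trace_normalize: bool = False,
) -> KernelMatrix:
    """μ-weighted convex combination Σ μ_j K_j (optionally Σ μ_j K_j / r_j)."""
    if not kernels:
        raise ValueError("no kernels to combine")
    ids = kernels[0].gene_ids
    for k in kernels[1:]:
        if k.gene_ids != ids:
            raise ValueError("kernels are not aligned on the same gene ordering")
    mu = uniform_weights(len(kernels)) if weights is None else np.asarray(weights, float)
    if mu.shape != (len(kernels),) or np.any(mu < -1e-12):
        raise ValueError("weights must be non-negative, one per kernel")
    out = np.zeros_like(kernels[0].gram)
    for w, k in zip(mu, kernels):
        scale = w / k.trace_r if trace_normalize else w
        out += scale * k.gram
    return KernelMatrix(
        gram=out,
        gene_ids=ids,
        centered=all(k.centered for k in kernels),
        name="combined",
    )
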