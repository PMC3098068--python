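"""Latent semantic indexing of gene-by-term views.

Truncated sparse SVD of the gene-by-term matrix, with a spectrum-fraction
rule for the number of retained latent factors: keep the smallest k such
that the (k+1)-th spectrum value falls below ``fraction`` (default 0.05%)
of the sum of all computed values.  The rule can be applied to the singular
values themselves (default) or to their squares (the eigenvalues of the
Gram matrix) via ``on="squared"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from .views import View

__all__ = ["LsiDecomposition", "decompose", "select_rank", "project", "reduce_views"]

DEFAULT_FRACTION = 0.0005  # 0.05% of the summed spectrum


@dataclass(frozen=True)
class LsiDecomposition:
    """Top-r singular triplets of one view, plus the selected rank."""

    singular_values: np.ndarray  # non-increasing, non-negative
    gene_factors: np.ndarray  # genes × r, orthonormal columns
    term_factors: np.ndarray  # terms × r, orthonormal columns
    term_ids: tuple[str, ...]
    k_selected: int
    threshold_fraction: float = DEFAULT_FRACTION

    def __post_init__(self) -> None:
        s = np.asarray(self.singular_values, dtype=float)
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("singular values must be non-increasing")
        if not 1 <= self.k_selected <= s.size:
            raise ValueError("k_selected out of range")


def select_rank(singular_values: np.ndarray, fraction: float = DEFAULT_FRACTION,
                on: str = "singular") -> int:
    """Smallest k whose next spectrum value drops below fraction × spectrum sum.

    ``on="squared"`` applies the rule to squared values (Gram eigenvalues).
    If no value falls below the threshold, all computed factors are kept and
    a warning is emitted.
    """
    s = np.asarray(singular_values, dtype=float)
    if s.size == 0 or np.any(s < 0) or np.any(np.diff(s) > 1e-12):
        raise ValueError("need a non-empty, non-negative, non-increasing spectrum")
    if on == "squared":
        s = s**2
    elif on != "singular":
        raise ValueError(f"unknown spectrum scale {on!r}")
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero spectrum")
    below = np.nonzero(s < fraction * total)[0]
    if below.size == 0:
        warnings.warn(
            "no spectrum value below the threshold; keeping all computed factors",
            stacklevel=2,
        )
        return int(s.size)
    return int(below[0])


def decompose(view: View, max_rank: int | None = None,
              fraction: float = DEFAULT_FRACTION, on: str = "singular") -> LsiDecomposition:
    """Top-``max_rank`` sparse singular triplets of the view's weight matrix.

    Default ``max_rank`` is min(genes, terms, 500) − 1, mirroring a sparse
    eigensolver applied to a large term matrix where the full spectrum is
    out of reach.
    """
    n, m = view.weights.shape
    limit = min(n, m) - 1
    if max_rank is None:
        max_rank = min(n, m, 500) - 1
    if not 1 <= max_rank <= limit:
        raise ValueError(f"max_rank must be in [1, {limit}]")
    X = sp.csr_matrix(view.weights)
    u, s, vt = svds(X, k=max_rank, random_state=0)
    order = np.argsort(s)[::-1]
    u, s, vt = u[:, order], s[order], vt[order]
    k = select_rank(s, fraction=fraction, on=on)
    return LsiDecomposition(
        singular_values=s,
        gene_factors=u,
        term_factors=vt.T,
        term_ids=view.term_ids,
        k_selected=k,
        threshold_fraction=fraction,
    )


def project(view: View, dec: LsiDecomposition, k: int | None = None) -> View:
    """Express gene rows in the latent basis (term factors × singular scaling).

    The projection of row x is Vᵀx per latent factor — equivalently the gene
    factor row scaled by the singular values when the decomposition was
    computed from this very matrix.  Downstream code treats the result as an
    ordinary view.
    """
    if view.term_ids != dec.term_ids:
        raise ValueError("decomposition was computed on a different term space")
    k = dec.k_selected if k is None else k
    if not 1 <= k <= dec.singular_values.size:
        raise ValueError("k out of range")
    latent = view.weights @ dec.term_factors[:, :k]
    return View(
        name=f"{view.name}-lsi{k}",
        gene_ids=view.gene_ids,
        term_ids=tuple(f"factor{j:03d}" for j in range(k)),
        weights=latent,
        weighting="idf",  # latent factors are real-valued, never raw counts
        zero_doc_genes=view.zero_doc_genes,
    )


def reduce_views(views, max_rank: int | None = None,
                 fraction: float = DEFAULT_FRACTION):
    """LSI-reduce a sequence of views with the spectrum-fraction rule."""
    out = []
    for v in views:
        dec = decompose(v, max_rank=max_rank, fraction=fraction)
        out.append(project(v, dec))
    return out
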