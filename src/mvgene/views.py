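"""Gene-by-term views: aggregation, IDF weighting, merging, concept mapping.

A view is one vocabulary's perspective on a shared gene set: the gene-by-term
matrix obtained by averaging a gene's document vectors and re-weighting terms
by inverse document frequency (IDF).  All views of a multi-view dataset share
the same gene ordering, which is what makes late integration (rank ensembles,
consensus clustering) and early integration (kernel fusion) well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .corpus import Corpus, DocTermMatrix, SynonymTable, Vocabulary, index_corpus, vocabulary_union

__all__ = [
    "View",
    "MultiViewDataset",
    "aggregate_gene_profiles",
    "idf_transform",
    "merge_views",
    "map_concepts",
    "build_view",
    "build_views",
]


@dataclass(frozen=True)
class View:
    """One gene-by-term (or gene-by-concept / gene-by-factor) matrix.

    ``weighting`` is ``"count"`` for raw averaged counts and ``"idf"`` after
    IDF re-weighting; LSI projections reuse the container with latent factor
    ids as ``term_ids``.
    """

    name: str
    gene_ids: tuple[str, ...]
    term_ids: tuple[str, ...]
    weights: np.ndarray
    weighting: str = "count"
    zero_doc_genes: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (len(self.gene_ids), len(self.term_ids)):
            raise ValueError(
                f"view {self.name!r}: weight shape {w.shape} does not match "
                f"({len(self.gene_ids)}, {len(self.term_ids)})"
            )
        if self.weighting == "count" and w.size and w.min() < 0:
            raise ValueError(f"view {self.name!r}: negative entries under count weighting")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_terms(self) -> int:
        return len(self.term_ids)

    def rows(self, gene_ids: Sequence[str]) -> np.ndarray:
        index = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            idx = [index[g] for g in gene_ids]
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"gene {e.args[0]!r} not in view {self.name!r}") from e
        return self.weights[idx]


@dataclass(frozen=True)
class MultiViewDataset:
    """N aligned views over one gene universe plus gene→disease labels."""

    views: tuple[View, ...]
    labels: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        if not self.views:
            raise ValueError("a multi-view dataset needs at least one view")
        g0 = self.views[0].gene_ids
        for v in self.views[1:]:
            if v.gene_ids != g0:
                raise ValueError(f"view {v.name!r} has a different gene ordering")
        missing = set(self.labels) - set(g0)
        if missing:
            raise ValueError(f"labeled genes missing from views: {sorted(missing)[:5]}")

    @property
    def n_views(self) -> int:
        return len(self.views)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return self.views[0].gene_ids

    @property
    def diseases(self) -> tuple[str, ...]:
        out: set[str] = set()
        for ds in self.labels.values():
            out.update(ds)
        return tuple(sorted(out))

    def disease_genes(self, disease: str) -> tuple[str, ...]:
        return tuple(sorted(g for g, ds in self.labels.items() if disease in ds))

    @property
    def unlabeled_genes(self) -> tuple[str, ...]:
        return tuple(g for g in self.gene_ids if g not in self.labels)

    def with_views(self, views: Sequence[View]) -> "MultiViewDataset":
        return MultiViewDataset(views=tuple(views), labels=self.labels)


def aggregate_gene_profiles(
    doc_term: DocTermMatrix,
    gene_doc_map: Mapping[str, frozenset[str]],
    name: str = "view",
) -> View:
    """Average each gene's document vectors into a gene-by-term profile.

    A gene's row is the arithmetic mean of its documents' rows.  Genes
    mapped to no document get an all-zero row and are flagged in
    ``zero_doc_genes`` (they should not enter training sets, but may appear
    as ranking candidates).
    """
    doc_index = {d: i for i, d in enumerate(doc_term.doc_ids)}
    gene_ids = tuple(sorted(gene_doc_map))
    dense = doc_term.counts.toarray()
    profiles = np.zeros((len(gene_ids), len(doc_term.term_ids)))
    zero_doc: set[str] = set()
    for gi, g in enumerate(gene_ids):
        docs = gene_doc_map[g]
        if not docs:
            zero_doc.add(g)
            continue
        try:
            rows = [doc_index[d] for d in docs]
        except KeyError as e:
            raise KeyError(f"gene {g!r} maps to unknown document {e.args[0]!r}") from e
        profiles[gi] = dense[rows].mean(axis=0)
    return View(
        name=name,
        gene_ids=gene_ids,
        term_ids=doc_term.term_ids,
        weights=profiles,
        weighting="count",
        zero_doc_genes=frozenset(zero_doc),
    )


def idf_transform(view: View, doc_term: DocTermMatrix) -> View:
    """Re-weight term columns by inverse document frequency.

    idf(t) = ln(D / df_t) with D the number of documents and df_t the number
    of documents containing t, both computed on the doc-by-term matrix the
    view was aggregated from.  Terms occurring in no document get weight 0;
    no smoothing is applied (a term in every document is zeroed out, which is
    the intended behaviour: it carries no discriminative information).
    """
    if view.term_ids != doc_term.term_ids:
        raise ValueError("doc_term term space does not match the view")
    df = doc_term.document_frequency().astype(float)
    D = float(doc_term.n_docs)
    idf = np.zeros_like(df)
    pos = df > 0
    idf[pos] = np.log(D / df[pos])
    return replace(view, weights=view.weights * idf[None, :], weighting="idf")


def build_view(
    corpus: Corpus,
    vocab: Vocabulary,
    weighting: str = "idf",
    name: str | None = None,
) -> View:
    """Index → aggregate → (optionally) IDF-weight, in one call."""
    dt = index_corpus(corpus, vocab)
    view = aggregate_gene_profiles(dt, corpus.gene_doc_map, name=name or vocab.name)
    if weighting == "idf":
        view = idf_transform(view, dt)
    elif weighting != "count":
        raise ValueError(f"unknown weighting {weighting!r}")
    return view


def build_views(
    corpus: Corpus,
    vocabs: Sequence[Vocabulary],
    labels: Mapping[str, frozenset[str]],
    weighting: str = "idf",
) -> MultiViewDataset:
    views = tuple(build_view(corpus, v, weighting=weighting) for v in vocabs)
    return MultiViewDataset(views=views, labels=labels)


def merge_views(
    vocabs: Sequence[Vocabulary],
    corpus: Corpus,
    weighting: str = "idf",
    name: str | None = None,
) -> View:
    """Index with the de-duplicated union of several vocabularies.

    This is the "merge-N" baseline: one large vocabulary instead of N views.
    """
    if len(vocabs) < 2:
        raise ValueError("merging needs at least two vocabularies")
    union = vocabulary_union(vocabs, name=name or f"merge-{len(vocabs)}")
    return build_view(corpus, union, weighting=weighting)


def map_concepts(view: View, synonyms: SynonymTable, name: str | None = None) -> View:
    """Aggregate synonym term columns into unified concept columns.

    Columns of terms sharing a concept id are summed; unmapped terms keep a
    singleton concept of their own.  Mapping must precede IDF weighting
    (occurrence counts are what aggregate meaningfully).
    """
    if view.weighting != "count":
        warnings.warn(
            "map_concepts should be applied to raw counts (mapping precedes IDF)",
            stacklevel=2,
        )
    concepts = sorted({synonyms.concept_of(t) for t in view.term_ids})
    cindex = {c: j for j, c in enumerate(concepts)}
    out = np.zeros((view.n_genes, len(concepts)))
    for j, t in enumerate(view.term_ids):
        out[:, cindex[synonyms.concept_of(t)]] += view.weights[:, j]
    return View(
        name=name or f"{view.name}-concept",
        gene_ids=view.gene_ids,
        term_ids=tuple(concepts),
        weights=out,
        weighting=view.weighting,
        zero_doc_genes=view.zero_doc_genes,
    )
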