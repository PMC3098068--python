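"""Corpora, controlled vocabularies and document indexing.

A *controlled vocabulary* (CV) is a fixed list of normalized terms derived
from a bio-ontology.  Indexing a document collection with one CV yields a
document-by-term count matrix; every CV therefore defines one *view* of the
same gene set.  Real pipelines index MEDLINE abstracts with ontology-derived
vocabularies; here the corpus abstraction is format-agnostic so synthetic
corpora and on-disk TSV corpora go through the same code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Vocabulary",
    "Corpus",
    "SynonymTable",
    "DocTermMatrix",
    "index_corpus",
    "no_voc_vocabulary",
]


@dataclass(frozen=True)
class Vocabulary:
    """A named controlled vocabulary: unique, pre-normalized term strings.

    Parameters
    ----------
    name:
        Short identifier, e.g. ``"GO"`` or ``"MeSH-disease"``.
    terms:
        Unique lowercased terms.  Order is preserved and defines column
        order of any matrix indexed with this vocabulary.
    parent:
        Name of the complete vocabulary this one is a subset of, if any.
    """

    name: str
    terms: tuple[str, ...]
    parent: str | None = None

    def __post_init__(self) -> None:
        if len(self.terms) == 0:
            raise ValueError(f"vocabulary {self.name!r} is empty")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError(f"vocabulary {self.name!r} has duplicate terms")

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class Corpus:
    """A document collection plus the gene→document mapping.

    ``documents`` maps a document id to its term→count bag; ``gene_doc_map``
    maps a gene id to the ids of documents describing it (the synthetic
    analogue of a GeneRIF gene→publication mapping).
    """

    documents: Mapping[str, Mapping[str, int]]
    gene_doc_map: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        missing = {
            d for docs in self.gene_doc_map.values() for d in docs
            if d not in self.documents
        }
        if missing:
            raise ValueError(f"gene_doc_map references unknown documents: {sorted(missing)[:5]}")
        for did, bag in self.documents.items():
            for term, c in bag.items():
                if c < 0 or int(c) != c:
                    raise ValueError(f"negative/non-integer count for {term!r} in {did!r}")

    @property
    def doc_ids(self) -> tuple[str, ...]:
        return tuple(sorted(self.documents))

    def all_terms(self) -> tuple[str, ...]:
        seen: set[str] = set()
        for bag in self.documents.values():
            seen.update(bag)
        return tuple(sorted(seen))


@dataclass(frozen=True)
class SynonymTable:
    """Total map from term string to unified concept id."""

    mapping: Mapping[str, str] = field(default_factory=dict)

    def concept_of(self, term: str) -> str:
        # unmapped terms keep their own singleton concept
        return self.mapping.get(term, term)


@dataclass(frozen=True)
class DocTermMatrix:
    """Sparse document-by-term count matrix with explicit row/column ids."""

    counts: sp.csr_matrix
    doc_ids: tuple[str, ...]
    term_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.counts.shape != (len(self.doc_ids), len(self.term_ids)):
            raise ValueError("matrix shape does not match id lists")

    @property
    def n_docs(self) -> int:
        return len(self.doc_ids)

    def document_frequency(self) -> np.ndarray:
        """Number of documents in which each term occurs at least once."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()


def index_corpus(corpus: Corpus, vocab: Vocabulary) -> DocTermMatrix:
    """Index every document of ``corpus`` with the terms of ``vocab``.

    Entry (d, t) is the occurrence count of vocabulary term t in document d;
    corpus tokens absent from the vocabulary are ignored.  An empty corpus
    yields an empty (0 × |vocab|) matrix.
    """
    term_index = {t: j for j, t in enumerate(vocab.terms)}
    doc_ids = corpus.doc_ids
    rows: list[int] = []
    cols: list[int] = []
    vals: list[int] = []
    for i, did in enumerate(doc_ids):
        for term, c in corpus.documents[did].items():
            j = term_index.get(term)
            if j is not None and c > 0:
                rows.append(i)
                cols.append(j)
                vals.append(int(c))
    counts = sp.csr_matrix(
        (vals, (rows, cols)), shape=(len(doc_ids), len(vocab.terms)), dtype=float
    )
    return DocTermMatrix(counts=counts, doc_ids=doc_ids, term_ids=vocab.terms)


def no_voc_vocabulary(corpus: Corpus, name: str = "no-voc") -> Vocabulary:
    """Baseline vocabulary equal to the full set of distinct corpus tokens."""
    return Vocabulary(name=name, terms=corpus.all_terms())


def vocabulary_union(vocabs: Iterable[Vocabulary], name: str = "merged") -> Vocabulary:
    """De-duplicated union of several vocabularies (sorted for determinism)."""
    terms: set[str] = set()
    for v in vocabs:
        terms.update(v.terms)
    return Vocabulary(name=name, terms=tuple(sorted(terms)))
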