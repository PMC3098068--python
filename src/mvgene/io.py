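"""On-disk formats: TSV corpora, plain-text vocabularies, MatrixMarket views.

A view is persisted as a MatrixMarket coordinate file plus two TSV label
files (row gene ids, column term ids) and a small JSON sidecar carrying the
name, weighting and provenance.  Corpora are two TSVs: (doc_id, term, count)
and (gene_id, doc_id).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .corpus import Corpus, Vocabulary
from .views import View

__all__ = [
    "save_view", "load_view",
    "save_corpus", "load_corpus",
    "save_vocabulary", "load_vocabulary",
    "save_ranking_tsv", "save_partition_tsv",
]


def save_view(view: View, directory: str | Path, sidecar: dict | None = None) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    sio.mmwrite(d / "weights.mtx", sp.coo_matrix(view.weights))
    pd.Series(view.gene_ids).to_csv(d / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(view.term_ids).to_csv(d / "terms.tsv", sep="\t", index=False, header=False)
    meta = {
        "name": view.name,
        "weighting": view.weighting,
        "zero_doc_genes": sorted(view.zero_doc_genes),
    } | (sidecar or {})
    (d / "view.json").write_text(json.dumps(meta, indent=1))
    return d


def load_view(directory: str | Path) -> View:
    d = Path(directory)
    meta = json.loads((d / "view.json").read_text())
    m = sio.mmread(d / "weights.mtx")
    weights = m.toarray() if sp.issparse(m) else np.asarray(m)
    genes = pd.read_csv(d / "genes.tsv", sep="\t", header=None)[0].astype(str)
    terms = pd.read_csv(d / "terms.tsv", sep="\t", header=None)[0].astype(str)
    return View(
        name=meta["name"],
        gene_ids=tuple(genes),
        term_ids=tuple(terms),
        weights=weights,
        weighting=meta.get("weighting", "count"),
        zero_doc_genes=frozenset(meta.get("zero_doc_genes", [])),
    )


def save_corpus(corpus: Corpus, directory: str | Path) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = [
        (did, term, int(c))
        for did in corpus.doc_ids
        for term, c in sorted(corpus.documents[did].items())
    ]
    pd.DataFrame(rows, columns=["doc_id", "term", "count"]).to_csv(
        d / "documents.tsv", sep="\t", index=False
    )
    # empty documents carry no count rows; keep the full id list explicitly
    pd.Series(corpus.doc_ids).to_csv(d / "doc_ids.tsv", sep="\t", index=False,
                                     header=False)
    gmap = [
        (g, did) for g in sorted(corpus.gene_doc_map)
        for did in sorted(corpus.gene_doc_map[g])
    ]
    pd.DataFrame(gmap, columns=["gene_id", "doc_id"]).to_csv(
        d / "gene_doc_map.tsv", sep="\t", index=False
    )
    return d


def load_corpus(directory: str | Path) -> Corpus:
    d = Path(directory)
    docs_df = pd.read_csv(d / "documents.tsv", sep="\t", dtype={"doc_id": str, "term": str})
    documents: dict[str, dict[str, int]] = {}
    ids_file = d / "doc_ids.tsv"
    if ids_file.exists():
        for did in pd.read_csv(ids_file, sep="\t", header=None)[0].astype(str):
            documents[did] = {}
    for did, term, c in docs_df.itertuples(index=False):
        documents.setdefault(did, {})[term] = int(c)
    gmap_df = pd.read_csv(d / "gene_doc_map.tsv", sep="\t", dtype=str)
    gene_doc_map: dict[str, set[str]] = {}
    for g, did in gmap_df.itertuples(index=False):
        gene_doc_map.setdefault(g, set()).add(did)
    return Corpus(
        documents=documents,
        gene_doc_map={g: frozenset(s) for g, s in gene_doc_map.items()},
    )


def save_vocabulary(vocab: Vocabulary, path: str | Path) -> Path:
    p = Path(path)
    p.write_text("\n".join(vocab.terms) + "\n", encoding="utf-8")
    return p


def load_vocabulary(path: str | Path, name: str | None = None) -> Vocabulary:
    p = Path(path)
    terms = tuple(t for t in p.read_text(encoding="utf-8").splitlines() if t)
    return Vocabulary(name=name or p.stem, terms=terms)


def save_ranking_tsv(ranking, path: str | Path, p_values=None) -> Path:
    df = pd.DataFrame(
        {
            "gene_id": ranking.candidate_ids,
            "score": ranking.scores,
            "rank": np.arange(1, len(ranking.candidate_ids) + 1),
            "rank_ratio": ranking.rank_ratios,
        }
    )
    if p_values is not None:
        df["p_value"] = np.asarray(p_values)
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def save_partition_tsv(partition, path: str | Path) -> Path:
    ids = partition.gene_ids or [f"g{i}" for i in range(partition.n)]
    pd.DataFrame({"gene_id": ids, "cluster": partition.labels}).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)
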