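"""Experiment orchestration: config → pipeline → JSON report.

Ties generation, view construction, optional LSI reduction and the two
evaluation protocols (leave-one-out prioritization error; all-pairs
two-disease clustering) into a single seeded, reproducible run, and offers
paired-t-test comparison across method reports.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import yaml

from . import __version__
from .cluster import ClusterEvalReport, pairwise_disease_eval
from .generate import generate_benchmark
from .lsi import reduce_views
from .prioritize import LooReport, loo_benchmark
from .views import MultiViewDataset, build_views

__all__ = ["ExperimentConfig", "EvalReport", "run_experiment", "compare_methods"]


@dataclass(frozen=True)
class ExperimentConfig:
    """Declarative description of one experiment."""

    task: str  # "prioritize" | "cluster"
    n_diseases: int = 10
    genes_per_disease: int = 20
    n_views: int = 9
    relevance: Sequence[float] | float = 1.0
    overlap_frac: float = 0.3
    vocab_sizes: Sequence[int] | int = 100
    n_background_genes: int = 200
    multilabel_frac: float = 0.05
    reduction: str = "none"  # "none" | "lsi"
    lsi_fraction: float = 0.0005
    method: Mapping[str, object] = field(default_factory=dict)
    n_reps: int = 20
    n_candidates: int = 99
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("prioritize", "cluster"):
            raise ValueError("task must be 'prioritize' or 'cluster'")
        if self.reduction not in ("none", "lsi"):
            raise ValueError("reduction must be 'none' or 'lsi'")

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass(frozen=True)
class EvalReport:
    """Uniform report wrapper with per-repetition detail and provenance."""

    task: str
    method: str
    metrics: Mapping[str, tuple[float, float]]  # name -> (mean, std)
    per_task: Mapping[str, list[float]]
    per_view: Mapping[str, Mapping[str, float]] | None
    config_hash: str
    seed: int
    n_reps: int
    runtimes: Mapping[str, float] = field(default_factory=dict)
    version: str = __version__

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "task": self.task,
            "method": self.method,
            "metrics": {k: {"mean": m, "std": s} for k, (m, s) in self.metrics.items()},
            "per_task": self.per_task,
            "per_view": self.per_view,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "n_reps": self.n_reps,
            "runtimes_s": self.runtimes,
            "version": self.version,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_tsv(self, path: str | Path) -> Path:
        rows = [
            {"metric": k, "mean": m, "std": s} for k, (m, s) in self.metrics.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return Path(path)


def _prepare_dataset(config: ExperimentConfig) -> MultiViewDataset:
    bench = generate_benchmark(
        n_diseases=config.n_diseases,
        genes_per_disease=config.genes_per_disease,
        n_views=config.n_views,
        relevance=config.relevance,
        overlap_frac=config.overlap_frac,
        vocab_sizes=config.vocab_sizes,
        seed=config.seed,
        n_background_genes=config.n_background_genes,
        multilabel_frac=config.multilabel_frac,
    )
    dataset = build_views(
        bench.corpus, bench.vocabularies, bench.dataset.labels, weighting="idf"
    )
    if config.reduction == "lsi":
        reduced = reduce_views(dataset.views, fraction=config.lsi_fraction)
        dataset = dataset.with_views(reduced)
    return dataset


def run_experiment(config: ExperimentConfig, out_dir: str | Path | None = None) -> EvalReport:
    """Execute the configured pipeline end to end, deterministically."""
    runtimes: dict[str, float] = {}
    t0 = time.perf_counter()
    dataset = _prepare_dataset(config)
    runtimes["generate_views"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    if config.task == "prioritize":
        method = str(config.method.get("method", "single-view"))
        rep: LooReport = loo_benchmark(
            dataset,
            method=method,
            n_candidates=config.n_candidates,
            n_reps=config.n_reps,
            seed=config.seed,
            nu=float(config.method.get("nu", 0.5)),
            mu_min=config.method.get("mu_min"),
        )
        metrics = {"error": (rep.mean_error, rep.std_error)}
        per_task = {"error": [float(e) for e in rep.errors]}
        per_view = (
            {name: {"error": float(e.mean())} for name, e in rep.per_view.items()}
            if rep.per_view
            else None
        )
        method_name = method
    else:
        crep: ClusterEvalReport = pairwise_disease_eval(
            dataset, config.method, n_reps=config.n_reps, seed=config.seed
        )
        metrics = {
            "RI": (crep.mean_ri, crep.std_ri),
            "NMI": (crep.mean_nmi, crep.std_nmi),
        }
        per_task = {
            "RI": [float(x) for x in crep.ri],
            "NMI": [float(x) for x in crep.nmi],
        }
        per_view = (
            {
                name: {"RI": float(r.mean()), "NMI": float(m.mean())}
                for name, (r, m) in crep.per_view.items()
            }
            if crep.per_view
            else None
        )
        method_name = crep.method
    runtimes["evaluate"] = time.perf_counter() - t0

    report = EvalReport(
        task=config.task,
        method=method_name,
        metrics=metrics,
        per_task=per_task,
        per_view=per_view,
        config_hash=config.config_hash(),
        seed=config.seed,
        n_reps=config.n_reps,
        runtimes=runtimes,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "report.json")
        report.to_tsv(out / "report.tsv")
    return report


def compare_methods(reports: Sequence[EvalReport], metric: str | None = None) -> pd.DataFrame:
    """Paired t-tests between methods on their per-task metric vectors.

    Rows are method pairs; identical inputs yield p = 1 (flagged NaN t).
    """
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    metric = metric or next(iter(reports[0].per_task))
    series = []
    for r in reports:
        if metric not in r.per_task:
            raise ValueError(f"report {r.method!r} lacks metric {metric!r}")
        series.append(np.asarray(r.per_task[metric], dtype=float))
    n = series[0].size
    if any(s.size != n for s in series):
        raise ValueError("reports have different repetition structures")
    rows = []
    for i in range(len(reports)):
        for j in range(i + 1, len(reports)):
            diff = series[i] - series[j]
            if np.allclose(diff, 0.0):
                t, p = float("nan"), 1.0
            else:
                t, p = scipy.stats.ttest_rel(series[i], series[j])
            rows.append(
                {
                    "method_a": reports[i].method,
                    "method_b": reports[j].method,
                    "metric": metric,
                    "mean_a": float(series[i].mean()),
                    "mean_b": float(series[j].mean()),
                    "t": float(t),
                    "p_value": float(p),
                }
            )
    return pd.DataFrame(rows)
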