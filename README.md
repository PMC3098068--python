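# mvgene

Multi-view text mining for disease-gene prioritization and clustering.

## The problem

Literature mining describes each gene by a *gene-by-term profile*: index a
corpus of gene-related publications with a controlled vocabulary (CV) drawn
from a bio-ontology, average the document vectors of each gene's
publications, and weight terms by inverse document frequency,
idf(t) = ln(D / df_t).  Every vocabulary yields a different *view* of the
same gene set, and no single view is reliably the best for a given disease
question.  `mvgene` treats the views as a multi-view learning problem: build
N gene-by-term matrices over one shared gene ordering, optionally compress
each with latent semantic indexing (LSI), and integrate them for the two
canonical disease-gene tasks:

**Prioritization** — rank candidate genes by similarity to a disease
training set:

* per view, Pearson correlation with the mean training profile;
* ensemble integration of per-view rankings by average, max, or order
  statistics: for rank ratios r₁ ≤ … ≤ r_N the Q statistic
  Q = N!·V_N, with V_k = Σ_{i=1..k} (−1)^{i−1} V_{k−i} r_{N−k+1}^i / i!
  and V₀ = 1, converted to a p-value under a simulated null (beta fit for
  N ≤ 5, gamma for N > 5);
* kernel fusion: a one-class SVM over Ω = Σ_j μ_j K_j / r_j, where K_j is
  the centered linear kernel of view j and r_j its trace.  The weights μ
  (Σμ_j = 1, μ_j ≥ μ_min) are the duals of the quadratic constraints of a
  QCLP solved as max_{μ} min_{α} αᵀ(Σ_j μ_j G_j/r_j)α with the ν-one-class
  constraints 0 ≤ α_i ≤ 1/(νM), Σα_i = 1.  μ_min = 1/N forces uniform
  averaging; μ_min = 0 allows sparse view selection.

**Clustering** — partition disease genes so that within-disease similarity
exceeds between-disease similarity:

* late integration: K-means per view + six consensus functions (CSPA,
  HGPA, MCLA, QMI, EACAL, AdacVote);
* early integration: hierarchical linkage on the Hilbert-space distance
  d(x,z) = √(K(x,x) − 2K(x,z) + K(z,z)) of the averaged kernel, and OKKC
  (alternating kernel K-means and convex kernel re-weighting).

Benchmarking follows two protocols: leave-one-out prioritization error
(1 − AUC of recovering a held-out "defector" gene hidden among 99 random
candidates) and all-pairs two-disease clustering (every unordered disease
pair is a binary task, genes carrying both labels removed, scored by Rand
Index and normalized mutual information).

Real pipelines index MEDLINE with ontology-derived vocabularies; `mvgene`
ships a synthetic generator that emulates that world — disease term topics,
gene→document maps, overlapping vocabularies of tunable relevance, a small
fraction of multi-label genes — so that every stage is testable offline.

## Worked example

```python
from mvgene.generate import generate_benchmark, RELEVANT_VIEW_RELEVANCE
from mvgene.views import build_views
from mvgene.prioritize import loo_benchmark

bench = generate_benchmark(
    n_diseases=10, genes_per_disease=20, n_views=9,
    relevance=[RELEVANT_VIEW_RELEVANCE] * 5 + [0.0] * 4,
    vocab_sizes=100, seed=0, n_background_genes=200,
)
dataset = build_views(bench.corpus, bench.vocabularies, bench.dataset.labels)

single = loo_benchmark(dataset, "single-view", n_candidates=99, n_reps=5, seed=0)
fused = loo_benchmark(dataset, "one-svm", n_candidates=99, n_reps=5, seed=0,
                      mu_min=1 / 9)

for name, err in sorted(single.view_means().items()):
    print(f"view {name}: LOO error = {err:.4f}")
print(f"best single view: {single.best_single_view()[1]:.4f}")
print(f"1-SVM kernel fusion (mu_min = 1/9): {fused.mean_error:.4f}")
```

Output:

```
view V00: LOO error = 0.1136
view V01: LOO error = 0.2076
view V02: LOO error = 0.2725
view V03: LOO error = 0.1070
view V04: LOO error = 0.1502
view V05: LOO error = 0.4782
view V06: LOO error = 0.5058
view V07: LOO error = 0.5106
view V08: LOO error = 0.4876
best single view: 0.1070
1-SVM kernel fusion (mu_min = 1/9): 0.0000
```

The five relevant views rank the held-out disease gene imperfectly (errors
0.11–0.27), the four noise views sit at chance (≈ 0.5), and the uniformly
weighted kernel fusion of all nine — including the noise — recovers every
defector at the top of its candidate list: the multi-view gain the toolkit
exists to measure.

The same pipeline is scriptable from the shell:

```bash
mvgene generate --diseases 10 --views 9 --relevance 0.12 --seed 0 --out-dir bench/
mvgene prioritize --method-json '{"method": "one-svm", "mu_min": 0.111}' --seed 7
mvgene cluster    --method-json '{"kind": "okkc", "mu_min": 0.0}' --seed 7
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from freshly generated seeded inputs: the mean Rand Index of
1000 pairs of independent uniform binary partitions of 200 items; the sum
of the kernel weights returned by the one-class-SVM fusion optimizer on a
3-kernel, 120-gene instance (ν = 0.5, μ_min = 0, 20 training genes); and
the maximum absolute fused prioritization score over 100 candidate genes
under that model.  Results are written as JSON to `--out`.

See `docs/methods.md` for the models, the synthetic world, numerical
choices and known limitations.
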