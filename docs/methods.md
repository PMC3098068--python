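# Methods

This note documents the models implemented in `mvgene`, the assumptions
behind the synthetic benchmark, the numerical choices that matter, and what
a green test does and does not establish.

## Views and weighting

A view is the gene-by-term matrix obtained by indexing one corpus with one
controlled vocabulary: entry (d, t) of the document-by-term matrix counts
occurrences of vocabulary term t in document d; a gene's profile is the
arithmetic mean of its documents' rows; term columns are then scaled by
idf(t) = ln(D / df_t), with D the number of documents and df_t the number
of documents containing t.

* No smoothing is applied: a term present in every document gets weight 0,
  which is intended — such a term carries no discriminative signal.  Terms
  absent from the corpus also get 0.
* Document frequency is computed on the document-by-term matrix of the
  same vocabulary.  Whether df should instead be corpus-wide is genuinely
  underdetermined; the per-vocabulary choice keeps each view self-contained
  and is exposed through the API (pass any `DocTermMatrix` to
  `idf_transform`).
* Genes mapped to zero documents keep an all-zero profile and are flagged
  (`View.zero_doc_genes`); they are excluded from training sets but may
  appear as ranking candidates, where their Pearson score is 0 by the
  zero-variance convention.
* Baselines: merging N vocabularies into their de-duplicated union
  (`merge_views`), collapsing synonym terms onto unified concepts before
  IDF (`map_concepts`; column sums are conserved), and a no-vocabulary
  baseline that indexes on the full corpus token set (`no_voc_vocabulary`).

## Latent semantic indexing

`lsi.decompose` computes the top-r singular triplets of a view with a
sparse solver (default r = min(genes, terms, 500) − 1).  The retained rank
is the smallest k whose (k+1)-th spectrum value falls below a fraction
(default 0.05%) of the sum of all computed values; if nothing falls below,
all computed factors are kept with a warning.  The rule can be applied to
the singular values (default) or to their squares — the eigenvalues of the
Gram matrix — via `on="squared"`; the two conventions disagree in general
and the choice is exposed rather than hidden.  Projection maps gene rows
onto the term factors; at full computed rank (≥ matrix rank) it preserves
pairwise gene distances to numerical precision, so distance-based
clustering is unchanged.

## Prioritization

The disease model on one view is the mean training profile; candidates are
scored by Pearson correlation (zero-variance rows score 0).  Rankings are
descending by score with ties broken by ascending gene id; the rank ratio
of the gene at position p among n candidates is p/n.

**Order statistics.**  For one gene's rank ratios r₁ ≤ … ≤ r_N across N
views, Q = N!·V_N with V_k = Σ_{i=1..k} (−1)^{i−1} V_{k−i} r_{N−k+1}^i/i!,
V₀ = 1 — the joint cumulative probability that N uniform order statistics
fall below the observed ratios.  Q is mapped to a p-value through a null
calibrated by simulation (≥ 10⁴ uniform draws): a beta fit for N ≤ 5 and a
gamma fit for N > 5, both by maximum likelihood with location 0.  Genes are
ranked by ascending p-value.

**Kernel fusion.**  Each view contributes a linear kernel on unit-norm
rows, double-centered, with negative eigenvalues clipped at 0 (tolerance
1e-10).  The one-class-SVM fusion program is solved in minimax form,

    t* = max_{μ ∈ Δ, μ ≥ μ_min}  min_{0 ≤ α ≤ 1/(νM), Σα = 1}
         αᵀ ( Σ_j μ_j G_j / r_j ) α ,

where G_j is the training submatrix of kernel j and r_j its full-kernel
trace.  The inner problem is solved by accelerated projected gradient
(FISTA) with exact projection onto the capped simplex (bisection on the
shift); the outer concave problem by SLSQP with Danskin gradients
q_j = αᵀ(G_j/r_j)α.  The returned μ are the duals of the quadratic
constraints of the equivalent QCLP; μ_min = 1/N short-circuits to the
uniform combination and a single inner solve.  Relaxing μ_min enlarges the
feasible set of the outer maximization, so the optimal t is non-decreasing
as μ_min decreases (t at μ_min = 0 ≥ t at μ_min = 1/N).

* ν defaults to 0.5.  The one-class literature parameterizes ν as the
  outlier fraction bound; 0.5 is the conventional midpoint when no
  disease-specific tuning is possible, and it keeps the α-cap 1/(νM)
  comfortably feasible for training sets of ≥ 2 genes.
* Scoring: s(x) = Σ_i α_i Ω(x, x_i) / (‖w‖_Ω · √Ω(x, x)) — a cosine in
  the fused feature space, with ‖w‖²_Ω = t.  This is the only bounded
  normalization consistent with scores in [−1, +1]; residual
  floating-point overshoot is clipped, and candidates with vanishing
  self-similarity score 0.

**Leave-one-out benchmark.**  For every repetition, every disease gene in
turn is removed from its training set and hidden among `n_candidates`
(default 99) genes drawn without replacement from the unlabeled pool —
re-drawn per defector per repetition.  The task error is 1 − AUC with the
defector as sole positive, computed with midrank tie handling; the report
averages over defectors × repetitions.  Multi-label genes are benchmarked
once per disease they belong to.  For the kernel-fusion method the kernels
are centered once over the full gene universe (which contains all
candidates) rather than per training∪candidate subset; this makes the
per-defector fit independent of the candidate draw and is what allows the
full 20-seed benchmark to run on one CPU in minutes.

## Clustering

Base partitions come from a seeded numpy K-means (k-means++ seeding, best
of 10 restarts by within-cluster sum of squares; emptied clusters re-seeded
at the farthest point).  The six consensus functions operate on
canonicalized partitions (clusters relabeled by first appearance), which
makes every method invariant to input relabeling:

* **CSPA** — spectral k-way partition of the co-association matrix.
* **HGPA** — spectral partition of the star-expanded hyperedge graph
  (every cluster is one hyperedge, weighted by 1/|cluster|).  The original
  formulations cut these graphs with METIS/hMETIS; spectral partitioning
  with seeded K-means on the embedding removes the compiled dependency and
  is a documented deviation.
* **MCLA** — meta-cluster the cluster indicator vectors by spectral
  partitioning of their Jaccard similarity; genes join the meta-cluster in
  which they participate most.
* **QMI** — K-means in the centered one-hot indicator concatenation (the
  category-utility feature space).
* **EACAL** — average-linkage dendrogram on 1 − co-association, cut to k.
* **AdacVote** — cumulative voting against an adaptive reference in
  decreasing order of partition entropy, clusters aligned by greedy
  overlap matching; ties are content-determined via canonicalization.

Kernel fusion clustering uses the Hilbert-space distance
d(x,z) = √(K(x,x) − 2K(x,z) + K(z,z)) of the (optionally μ-weighted)
combined kernel — for linear kernels on unit-norm rows this is the
Euclidean distance on the normalized profiles — followed by
single/complete/average/ward linkage.

**OKKC.**  Alternates (i) kernel K-means (Lloyd iterations in feature
space, warm-started from the previous labels) on the current combined
kernel Σ_i μ_i K_i/r_i and (ii) a convex re-weighting step

    μ = argmax_{μ ∈ Δ, μ ≥ μ_min}  Σ_i μ_i Tr(Aᵀ (K_i/r_i) A) − λ‖μ‖² ,

where A is the normalized cluster-indicator matrix — a closed-form
projection of s/(2λ) onto the lower-bounded simplex.  Because the kernels
are trace-normalized, the total scatter is constant (Σμ_i = 1), so both
half-steps decrease the regularized distortion
1 − Σ_i μ_i Tr(Aᵀ(K_i/r_i)A) + λ‖μ‖², which is recorded in
`objective_trace` and asserted monotone.  λ defaults to 1e-2: small enough
that weights concentrate on informative kernels, large enough to keep the
step strictly concave.  With μ_min = 1/N the weighting step is skipped and
the algorithm is exactly kernel K-means on the averagely combined
(trace-normalized) kernel, sharing the seed path so the equivalence is
bit-identical.  The exact form of the published kernel-fusion QCQP for
this step is not recoverable from the available text; the regularized
separation step above is this package's own design and satisfies every
stated contract (trace normalization, between-cluster objective, simplex
and floor constraints, monotone convergence, μ_min = 1/N equivalence).

**Validation.**  Pair counts a (together/together), b (apart/apart),
c (together/apart), d (apart/together) are computed from the contingency
table; RI = (a+b)/(a+b+c+d); NMI = M(C,P)/√(E(C)·E(P)) (geometric-mean
normalization).  If either partition has zero entropy, NMI is defined as 1
when both are the identical trivial partition and 0 otherwise.  The
all-pairs protocol enumerates every unordered disease pair (C(29,2) = 406
at the canonical benchmark size), removes genes labeled with both diseases
of a pair, clusters the remainder into k = 2, and averages RI/NMI over
pairs × repetitions; pairs left with fewer than 4 genes are skipped with a
warning.

## The synthetic world

The generator plants one term topic per disease (30 informative tokens),
maps each gene to 1 + Poisson(4) documents of Poisson(50) tokens, half of
which come from the gene's disease topic(s) and half from a background
pool; unlabeled background genes draw purely background text and serve as
the candidate pool (default 200).  5% of labeled genes carry a second
disease label.  A view's *relevance* is the fraction of its vocabulary
sampled from the informative token pool (0 = pure noise, 1 = fully
informative); vocabularies overlap pairwise by roughly the requested
fraction through shared-pool sizing.  Everything is a pure function of
(config, seed).

Because synthetic documents are far cleaner than real abstracts, a fully
informative vocabulary saturates the benchmark (LOO error 0.000), which
would make method comparisons degenerate.  The shipped constant
`RELEVANT_VIEW_RELEVANCE = 0.12` was therefore calibrated — once, against
the operating regime real literature views exhibit (best single-view LOO
error ≈ 0.08, single-view RI between chance and ~0.9) — and frozen; it is
the default meaning of "a relevant view" in benchmarks and tests.

What the generator does **not** emulate: term burstiness and document
length heterogeneity of real abstracts, correlated vocabularies that share
hierarchical structure, genes with literature volumes spanning orders of
magnitude, and disease topics of unequal specificity.  A green multi-view
gain test therefore establishes that the integration machinery extracts
complementary signal and resists pure-noise views under clean topic
structure — not that any particular error level is attainable on real
MEDLINE-indexed data.

## Known limitations and observed failure modes

* **EACAL under pure-noise views.**  With 4 of 9 base partitions pure
  noise, an ambiguous gene's co-association with its true cluster can drop
  below the between-cluster level; average linkage then merges that gene
  last and the k = 2 cut degenerates to singleton-vs-rest (RI ≈ 0.5 for
  the task).  On the 20-seed gain benchmark EACAL pools at RI ≈ 0.82–0.84
  against a best single view of ≈ 0.885, while ward-linkage fusion
  (≈ 0.98) and OKKC (≈ 0.99) are unaffected.  The implementation follows
  the stated contract (cut the average-linkage dendrogram to k); guarding
  the cut (minimum cluster sizes, lifetime-based cuts) would change the
  method, so the behaviour is documented rather than patched.
* The QCLP solver assumes PSD kernels; kernels assembled outside
  `linear_kernel` must be centered and repaired by the caller
  (`KernelMatrix.validate_psd` checks to 1e-8).
* `fit_one_svm_fusion` recovers μ through the outer maximization; when
  several kernels are exactly interchangeable the μ split among them is
  solver-determined (their sum, and the fitted model, are unique).
* Consensus functions expect a modest number of partitions (one per view);
  very large ensembles would favour sparse co-association updates not
  implemented here.
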