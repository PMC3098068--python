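"""Clustering: K-means, consensus functions, kernel fusion, validation."""

import itertools
import warnings

import numpy as np
import pytest
from sklearn.metrics import normalized_mutual_info_score, rand_score

from mvgene.cluster import (
    CONSENSUS_METHODS,
    Partition,
    agreement,
    coassociation,
    consensus_combine,
    disease_pairs,
    hilbert_distance,
    kernel_kmeans,
    kmeans_partition,
    linkage_partition,
    okkc,
    pairwise_disease_eval,
)
from mvgene.kernels import KernelMatrix, combine_kernels, linear_kernel, uniform_weights
from mvgene.views import View


def _view(X, name="v"):
    return View(
        name=name,
        gene_ids=tuple(f"g{i:03d}" for i in range(X.shape[0])),
        term_ids=tuple(f"t{j}" for j in range(X.shape[1])),
        weights=X,
        weighting="idf",
    )


def _blobs(rng, n_per=10, sep=8.0, dim=5):
    a = rng.normal(size=(n_per, dim))
    b = rng.normal(size=(n_per, dim)) + sep
    return np.vstack([a, b]), np.array([1] * n_per + [2] * n_per)


class TestKmeans:
    def test_separated_blobs_recovered(self):
        X, truth = _blobs(np.random.default_rng(0))
        part = kmeans_partition(_view(X), 2, seed=1)
        ref = Partition(labels=truth, k=2, gene_ids=part.gene_ids)
        assert agreement(part, ref).ri == 1.0

    def test_seed_determinism(self):
        X, _ = _blobs(np.random.default_rng(1), sep=1.0)
        p1 = kmeans_partition(_view(X), 3, seed=9)
        p2 = kmeans_partition(_view(X), 3, seed=9)
        np.testing.assert_array_equal(p1.labels, p2.labels)

    def test_k_one_puts_everything_together(self):
        X, _ = _blobs(np.random.default_rng(2))
        part = kmeans_partition(_view(X), 1, seed=0)
        assert set(part.labels) == {1}

    def test_k_larger_than_distinct_rows_rejected(self):
        X = np.ones((4, 3))
        with pytest.raises(ValueError):
            kmeans_partition(_view(X), 2, seed=0)


class TestCoassociation:
    def test_identical_partitions_give_binary_matrix(self):
        p = Partition(labels=np.array([1, 1, 2, 2]), k=2)
        co = coassociation([p, p, p])
        assert set(np.unique(co.matrix)) <= {0.0, 1.0}

    def test_partial_agreement_fraction(self):
        p1 = Partition(labels=np.array([1, 1, 2]), k=2)
        p2 = Partition(labels=np.array([1, 2, 2]), k=2)
        co = coassociation([p1, p2, p1, p2])
        assert co.matrix[0, 1] == pytest.approx(0.5)

    def test_diagonal_is_one(self):
        p = Partition(labels=np.array([1, 2, 1]), k=2)
        assert np.allclose(np.diag(coassociation([p]).matrix), 1.0)


class TestConsensus:
    @pytest.mark.parametrize("method", CONSENSUS_METHODS)
    def test_unanimous_ensemble_is_reproduced(self, method):
        labels = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        parts = [Partition(labels=labels, k=3) for _ in range(4)]
        out = consensus_combine(parts, 3, method=method, seed=0)
        ref = Partition(labels=labels, k=3)
        assert agreement(out, ref).ri == 1.0

    @pytest.mark.parametrize("method", CONSENSUS_METHODS)
    def test_relabeling_invariance(self, method):
        rng = np.random.default_rng(3)
        parts = [
            Partition(labels=rng.integers(1, 4, size=12), k=3) for _ in range(5)
        ]
        swapped = [
            Partition(labels=np.array([{1: 2, 2: 3, 3: 1}[l] for l in p.labels]), k=3)
            for p in parts
        ]
        a = consensus_combine(parts, 2, method=method, seed=7)
        b = consensus_combine(swapped, 2, method=method, seed=7)
        assert agreement(a, b).ri == 1.0

    def test_eacal_recovers_coassociation_blocks(self):
        # 6 genes, ensemble whose co-association is two exact blocks
        p1 = Partition(labels=np.array([1, 1, 1, 2, 2, 2]), k=2)
        p2 = Partition(labels=np.array([2, 2, 2, 1, 1, 1]), k=2)
        out = consensus_combine([p1, p2, p1], 2, method="EACAL", seed=0)
        assert agreement(out, p1).ri == 1.0

    def test_consensus_beats_median_view_on_planted_data(self):
        rng = np.random.default_rng(4)
        gains = []
        for seed in range(5):
            srng = np.random.default_rng(seed)
            X, truth = _blobs(srng, n_per=15, sep=2.5)
            ref = Partition(labels=truth, k=2)
            parts, ris = [], []
            for v in range(9):
                Xv = X + srng.normal(scale=0.5 if v < 5 else 25.0, size=X.shape)
                p = kmeans_partition(_view(Xv), 2, seed=seed * 10 + v)
                parts.append(p)
                ris.append(agreement(p, ref).ri)
            cons = consensus_combine(parts, 2, method="EACAL", seed=seed)
            gains.append(agreement(cons, ref).ri - float(np.median(ris)))
        assert np.mean(gains) >= 0.0

    def test_validation_errors(self):
        p = Partition(labels=np.array([1, 2]), k=2)
        with pytest.raises(ValueError):
            consensus_combine([p], 2, method="CSPA")
        with pytest.raises(ValueError):
            consensus_combine([p, p], 2, method="nope")
        singletons = Partition(labels=np.array([1, 2, 3]), k=3)
        with pytest.raises(ValueError):
            consensus_combine([singletons, singletons], 2, method="CSPA")


class TestHilbertAndLinkage:
    def test_distance_equals_euclidean_for_linear_kernel(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 6))
        X /= np.linalg.norm(X, axis=1, keepdims=True)
        view = _view(X)
        ker = linear_kernel(view, unit_norm=False, center=True, psd_clip=False)
        D = hilbert_distance([ker]).matrix
        ref = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
        np.testing.assert_allclose(D, ref, atol=1e-10)

    def test_orthogonal_unit_vectors_are_sqrt2_apart(self):
        X = np.eye(2)
        ker = linear_kernel(_view(X), unit_norm=False, center=False, psd_clip=False)
        D = hilbert_distance([ker]).matrix
        assert D[0, 1] == pytest.approx(np.sqrt(2.0))

    def test_zero_self_distance(self, idf_dataset):
        kers = [linear_kernel(v, gene_ids=list(idf_dataset.gene_ids[:15]))
                for v in idf_dataset.views]
        D = hilbert_distance(kers).matrix
        assert np.allclose(np.diag(D), 0.0)

    @pytest.mark.parametrize("method", ["single", "complete", "average", "ward"])
    def test_linkage_separates_tight_groups(self, method):
        X, truth = _blobs(np.random.default_rng(6), sep=10.0)
        ker = linear_kernel(_view(X), unit_norm=False, psd_clip=False)
        part = linkage_partition(hilbert_distance([ker]), method, 2)
        ref = Partition(labels=truth, k=2, gene_ids=part.gene_ids)
        assert agreement(part, ref).ri == 1.0

    def test_k_equals_n_gives_singletons(self):
        X = np.random.default_rng(7).normal(size=(5, 3))
        ker = linear_kernel(_view(X), psd_clip=False)
        part = linkage_partition(hilbert_distance([ker]), "average", 5)
        assert len(set(part.labels)) == 5


class TestOkkc:
    @pytest.fixture(scope="class")
    def pair_kernels(self, idf_dataset):
        genes = [
            g for g, ds in idf_dataset.labels.items()
            if ds & {"D00", "D01"} and len(ds) == 1
        ]
        subs = [
            View(v.name, tuple(genes), v.term_ids, v.rows(genes), v.weighting)
            for v in idf_dataset.views
        ]
        return [linear_kernel(sv, psd_clip=False) for sv in subs], genes

    def test_uniform_floor_equals_average_kernel_kmeans(self, pair_kernels):
        kers, _ = pair_kernels
        N = len(kers)
        part, state = okkc(kers, 2, mu_min=1.0 / N, seed=13)
        avg = combine_kernels(kers, uniform_weights(N), trace_normalize=True)
        ref = kernel_kmeans(avg, 2, seed=13)
        np.testing.assert_array_equal(part.labels, ref.labels)
        np.testing.assert_allclose(state.weights.mu, 1.0 / N)

    def test_weights_sum_to_one_and_respect_floor(self, pair_kernels):
        kers, _ = pair_kernels
        for mu_min in (0.0, 0.5 / len(kers)):
            _, state = okkc(kers, 2, mu_min=mu_min, seed=3)
            assert state.weights.mu.sum() == pytest.approx(1.0, abs=1e-9)
            assert (state.weights.mu >= mu_min - 1e-9).all()

    def test_objective_monotone_non_increasing(self, pair_kernels):
        kers, _ = pair_kernels
        _, state = okkc(kers, 2, mu_min=0.0, seed=5)
        obj = np.asarray(state.objective_trace)
        assert np.all(np.diff(obj) <= 1e-6)

    def test_informative_kernel_dominates_noise(self, pair_kernels):
        kers, genes = pair_kernels
        rng0 = np.random.default_rng(100)
        wins = 0
        for seed in range(5):
            noise_view = _view(rng0.normal(size=(len(genes), 30)), name="noise")
            noise = linear_kernel(
                View("noise", tuple(genes), noise_view.term_ids,
                     noise_view.weights, "idf"),
                psd_clip=False,
            )
            _, state = okkc([kers[0], noise], 2, mu_min=0.0, seed=seed)
            wins += state.weights.mu[0] > 0.5
        assert wins >= 4

    def test_invalid_parameters(self, pair_kernels):
        kers, _ = pair_kernels
        with pytest.raises(ValueError):
            okkc(kers, 1)
        with pytest.raises(ValueError):
            okkc(kers, 2, lam=0.0)
        with pytest.raises(ValueError):
            okkc(kers, 2, mu_min=0.9)


def _brute_force_pairs(l1, l2):
    a = b = c = d = 0
    for i, j in itertools.combinations(range(len(l1)), 2):
        same1, same2 = l1[i] == l1[j], l2[i] == l2[j]
        a += same1 and same2
        b += (not same1) and (not same2)
        c += same1 and (not same2)
        d += (not same1) and same2
    return a, b, c, d


class TestAgreement:
    def test_identical_partitions(self):
        p = Partition(labels=np.array([1, 2, 1, 3]), k=3)
        ag = agreement(p, p)
        assert ag.ri == 1.0 and ag.nmi == 1.0

    def test_six_gene_worked_case(self):
        l1 = np.array([1, 1, 2, 2, 3, 3])
        l2 = np.array([1, 1, 2, 2, 2, 2])
        a, b, c, d = _brute_force_pairs(l1, l2)
        ag = agreement(Partition(l1, 3), Partition(l2, 2))
        assert (ag.a, ag.b, ag.c, ag.d) == (a, b, c, d)
        assert ag.ri == pytest.approx((a + b) / 15)

    def test_matches_sklearn_on_random_partitions(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            l1 = rng.integers(1, 5, size=60)
            l2 = rng.integers(1, 4, size=60)
            ag = agreement(Partition(l1, 4), Partition(l2, 3))
            assert ag.ri == pytest.approx(rand_score(l1, l2), abs=1e-12)
            assert ag.nmi == pytest.approx(
                normalized_mutual_info_score(l1, l2, average_method="geometric"),
                abs=1e-10,
            )

    def test_independent_random_partitions_have_low_nmi(self):
        rng = np.random.default_rng(9)
        nmis = []
        for _ in range(50):
            l1 = rng.integers(1, 3, size=200)
            l2 = rng.integers(1, 3, size=200)
            nmis.append(agreement(Partition(l1, 2), Partition(l2, 2)).nmi)
        assert np.mean(nmis) < 0.05

    def test_misaligned_partitions_rejected(self):
        with pytest.raises(ValueError):
            agreement(Partition(np.array([1, 2]), 2), Partition(np.array([1, 2, 1]), 2))


class TestPairwiseProtocol:
    def test_pair_enumeration_counts(self):
        assert len(disease_pairs([f"D{i}" for i in range(5)])) == 10
        assert len(disease_pairs([f"D{i}" for i in range(29)])) == 406

    def test_planted_benchmark_single_view(self, idf_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pairwise_disease_eval(
                idf_dataset, {"kind": "single-view"}, n_reps=2, seed=0
            )
        means = rep.view_mean_ri()
        # informative views near-perfect, noise views near chance
        assert max(means["V00"], means["V01"]) > 0.9
        assert 0.4 <= means["V02"] <= 0.62

    def test_overlapping_genes_are_removed(self, idf_dataset):
        both = [g for g, ds in idf_dataset.labels.items() if len(ds) == 2]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = pairwise_disease_eval(
                idf_dataset, {"kind": "linkage-fusion", "linkage": "ward"},
                n_reps=1, seed=0,
            )
        assert rep.ri.size == len(rep.tasks)
        # a double-labeled gene must never enter its pair's task
        from mvgene.cluster import _pair_genes

        for g in both:
            d1, d2 = sorted(idf_dataset.labels[g])
            assert g not in _pair_genes(idf_dataset, d1, d2)

    def test_determinism(self, idf_dataset):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = pairwise_disease_eval(
                idf_dataset, {"kind": "okkc", "mu_min": 0.0}, n_reps=1, seed=4
            )
            b = pairwise_disease_eval(
                idf_dataset, {"kind": "okkc", "mu_min": 0.0}, n_reps=1, seed=4
            )
        np.testing.assert_array_equal(a.ri, b.ri)
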