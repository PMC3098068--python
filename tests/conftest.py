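import pytest

from mvgene.generate import generate_benchmark
from mvgene.views import build_views


@pytest.fixture(scope="session")
def small_bench():
    """3 diseases × 10 genes, 4 views (two informative, two pure noise)."""
    return generate_benchmark(
        n_diseases=3,
        genes_per_disease=10,
        n_views=4,
        relevance=[1.0, 1.0, 0.0, 0.0],
        overlap_frac=0.3,
        vocab_sizes=80,
        seed=7,
        n_background_genes=60,
    )


@pytest.fixture(scope="session")
def idf_dataset(small_bench):
    return build_views(
        small_bench.corpus, small_bench.vocabularies, small_bench.dataset.labels,
        weighting="idf",
    )
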