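import pytest

from markcord.diffmark import diff_test
from markcord.promoter_quant import promoter_windows, quantify_samples
from markcord.synthio import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A 300-gene default-condition dataset shared by read-only tests."""
    return simulate_dataset(SyntheticConfig(seed=11, n_genes=300))


def mark_matrix(ds, mark, window=1000):
    windows = promoter_windows(ds.genes, window, ds.chrom_sizes)
    return quantify_samples(ds.tracks[mark], windows)


def mark_diff(ds, mark, **kw):
    return diff_test(mark_matrix(ds, mark), ds.groups, **kw)


@pytest.fixture(scope="session")
def small_diff(small_dataset):
    return mark_diff(small_dataset, "H3K4me3")
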