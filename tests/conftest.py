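import pytest

from bactmap import synthetic, tss


@pytest.fixture(scope="session")
def dataset():
    """Default toy dataset, seed 1, shared across read-only tests."""
    return synthetic.make_dataset(seed=1)


@pytest.fixture(scope="session")
def tss_result(dataset):
    return tss.call_tss(dataset.primary_starts, dataset.annotation)
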