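import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle():
    """A compact planted dataset shared by read-only tests.

    200 cells, 80 X-linked SNPs, 3 clonal + 2 pre-XCI + 2 artefact
    mitochondrial variants; clones of 15 cells nested in XCI groups.
    """
    from xcilineage.simulate import DatasetConfig, simulate_dataset

    cfg = DatasetConfig(n_cells=200, n_x_sites=80, n_clonal=3, n_pre_xci=2,
                        n_artefact=2, clone_sizes=(15, 15, 15))
    return simulate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def small_xci(small_bundle):
    """XCI model + assignment fitted on the shared bundle."""
    from xcilineage.xci_deconv import assign_xci, fit_xci_model

    model = fit_xci_model(small_bundle.acm, seed=0)
    assignment = assign_xci(model, small_bundle.acm, min_variants=30)
    return model, assignment


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
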