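import numpy as np
import pytest

from vunmir.pipeline import run_pipeline
from vunmir.synthetic import SyntheticDesign


@pytest.fixture(scope="session")
def small_design() -> SyntheticDesign:
    """A reduced experiment: 6 planted miRNAs at 30k reads/library, small
    enough for fast end-to-end runs while exercising every pipeline stage."""
    return SyntheticDesign(
        n_mirnas=6,
        n_genotype_specific=1,
        n_drought_up=2,
        n_drought_down=1,
        library_depths=(30_000,) * 4,
        n_decoys=3,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_result(small_design):
    return run_pipeline(small_design)


@pytest.fixture(scope="session")
def default_result():
    """Full pipeline on the default design (20 planted miRNAs, 2e5 reads per
    library).  Session-scoped: computed once, shared by the acceptance and
    property tests."""
    return run_pipeline(SyntheticDesign(seed=1))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)
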