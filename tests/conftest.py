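import numpy as np
import pytest

import braintime as bt


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_noise_series(rng):
    """Two independent white-noise regions, fMRI-like metadata."""
    return bt.ParcellatedSeries(
        subject_id="noise", modality="fmri", sampling_interval=2.6,
        region_labels=["a", "b"], data=rng.normal(size=(2, 2000)),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully separable synthetic cohort, shared across tests."""
    return bt.make_cohort(n_hc=8, n_ad=8, n_regions=12, T=250, seed=7)


@pytest.fixture(scope="session")
def small_cohort_results(small_cohort):
    spec = bt.WindowSpec(length=20, hop=2, shift=1)
    return [bt.subject_irreversibility(s, spec) for s in small_cohort.series]
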