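import numpy as np
import pytest

from emmetropy import synthgen


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort_spec():
    """Two groups with a clear amplitude difference, 5 fish each."""
    return synthgen.CohortSpec(
        n_fish_per_group=5,
        groups=(
            synthgen.GroupTuning("control", 1.0, 0.062, 0.3),
            synthgen.GroupTuning("mutant", 0.7, 0.062, 0.3),
        ),
        noise_sd_omi=0.1,
        seed=99,
    )


@pytest.fixture
def standard_frequencies():
    return synthgen.OMR_FREQUENCIES
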