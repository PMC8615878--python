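import numpy as np
import pytest

from errpot import (CohortConfig, build_features, default_shifts,
                    design_lowpass_fir, generate_cohort, make_erp_template)
from errpot.cohort import SubjectShift


@pytest.fixture(scope="session")
def template():
    return make_erp_template()


@pytest.fixture(scope="session")
def filter_spec():
    return design_lowpass_fir(fs=256.0)


@pytest.fixture(scope="session")
def small_cohort(template):
    """4 subjects x 24 trials with moderate shifts — fast unit-test cohort."""
    config = CohortConfig(n_subjects=4, n_trials=24, seed=11)
    return generate_cohort(config, default_shifts(4, seed=11), template)


@pytest.fixture(scope="session")
def small_features(small_cohort, filter_spec):
    return [build_features(es, spec=filter_spec) for es in small_cohort]


@pytest.fixture(scope="session")
def clean_cohort(template):
    """Noise-free, unshifted single subject: the injected waveform is exact."""
    config = CohortConfig(n_subjects=1, n_trials=16, seed=5, noise_sd=0.0,
                          alpha_amp=0.0)
    return generate_cohort(config, [SubjectShift()], template)[0]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
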