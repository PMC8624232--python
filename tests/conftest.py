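import numpy as np
import pytest
from hypothesis import settings

import bcgfatigue as bf

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")

MASTER_SEED = 20211027  # date-derived constant, fixed for reproducibility


@pytest.fixture(scope="session")
def template():
    return bf.make_default_template()


@pytest.fixture(scope="session")
def quiet_profile():
    """Noiseless, jitter-free, constant-HR profile for exact oracles."""
    def make(hr=72.0, **kw):
        kw.setdefault("drift_fraction", 0.0)
        kw.setdefault("hr_jitter_sd", 0.0)
        kw.setdefault("noise_sd", 0.0)
        kw.setdefault("respiration_amp", 0.0)
        return bf.SubjectProfile("quiet", baseline_hr=hr, **kw)
    return make


@pytest.fixture(scope="session")
def drifting_cohort():
    """Default study-scale cohort: 20 subjects, 120 min, 10% HR decline."""
    return bf.simulate_cohort(n_subjects=20, duration=7200.0, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def drifting_cohort_hrv(drifting_cohort):
    return [bf.hrv_series(bf.hr_series(rec)) for rec in drifting_cohort]
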