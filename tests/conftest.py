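import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vldlc import LipidPanel, default_cohort_spec, sample_bq_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

# Summary-table group means: the canonical hand-check inputs.
HLP3_MEANS = dict(tc=340.0, hdl_c=40.0, tg=375.0, apob=118.0, vldl_c=152.0)
NON_HLP3_MEANS = dict(tc=194.0, hdl_c=47.0, tg=164.0, apob=99.0, vldl_c=26.0)


@pytest.fixture(scope="session")
def hlp3_mean_panel():
    m = HLP3_MEANS
    return LipidPanel(tc=m["tc"], hdl_c=m["hdl_c"], tg=m["tg"], apob=m["apob"])


@pytest.fixture(scope="session")
def non_hlp3_mean_panel():
    m = NON_HLP3_MEANS
    return LipidPanel(tc=m["tc"], hdl_c=m["hdl_c"], tg=m["tg"], apob=m["apob"])


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-record study-like cohort with elevated prevalence (more
    positives for classifier tests) at a fixed seed."""
    return sample_bq_cohort(default_cohort_spec(4_000, 0.03, seed=11))


@pytest.fixture(scope="session")
def study_cohort():
    """The 20,000-record study-scale cohort at the reference seed."""
    return sample_bq_cohort(default_cohort_spec(20_000, 0.005, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(20_24)
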