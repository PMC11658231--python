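import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import ppgr

settings.register_profile(
    "ci", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> ppgr.CohortBundle:
    """12 participants, default study conditions; shared across tests."""
    return ppgr.generate_cohort(ppgr.SimConfig(n_participants=12, seed=42))


@pytest.fixture(scope="session")
def clean_cohort() -> ppgr.CohortBundle:
    """Noise-free cohort: full CGM, no spacing violations or night meals."""
    cfg = ppgr.SimConfig(n_participants=8, seed=9, measurement_noise_sd=0.0,
                         circadian_amplitude=0.0, cgm_dropout=0.0,
                         cgm_gap_rate=0.0, spacing_violation_rate=0.0,
                         night_meal_rate=0.0, ema_nonresponse=0.0)
    return ppgr.generate_cohort(cfg)


def flat_trace(pid="P", start=0.0, n=200, step_s=900.0, value=5.0):
    t = start + step_s * np.arange(n)
    return ppgr.GlucoseTrace(pid, t, np.full(n, value))


@pytest.fixture
def worked_trace():
    """Baseline 5.0 with the 9-point excursion 5,6,7,6,5,5,5,5,5 at 15-min."""
    t = 900.0 * np.arange(9)
    v = np.array([5.0, 6.0, 7.0, 6.0, 5.0, 5.0, 5.0, 5.0, 5.0])
    return ppgr.GlucoseTrace("P", t, v)
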