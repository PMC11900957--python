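import numpy as np
import pytest

from cermetrics import generate_cohort, measure_eye

COHORT_SEED = 11
COHORT_N = 100


@pytest.fixture(scope="session")
def cohort100():
    """Seed-fixed 100-eye synthetic cohort spanning mild to severe droop."""
    return generate_cohort(COHORT_N, droop_range_mm=(0.0, 8.0), seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_measured_twice(cohort100):
    """Two independent measurement passes over the cohort masks, plus truth."""
    run1 = np.array([measure_eye(e.truth.masks).cer_percent for e in cohort100])
    run2 = np.array([measure_eye(e.truth.masks).cer_percent for e in cohort100])
    true = np.array([e.truth.true_cer_percent for e in cohort100])
    return run1, run2, true
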