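import logging

import numpy as np
import pytest

from pepdetect import CohortConfig, generate_cohort

# identification on noisy short epochs routinely reflects poles / falls back
# on the residual-regression Kalman gain; the warnings are expected
logging.getLogger("pepdetect").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny balanced cohort shared by read-only tests."""
    cfg = CohortConfig(
        n_subjects=3,
        events_per_subject=6,
        n_dropped_total=2,
        unpredicted_fraction=0.5,
        effect_size=2.0,
        inter_event_interval_s=(2.0, 2.5),
        seed=42,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
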