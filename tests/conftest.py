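import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

from serodta.dta_core import Study2x2Record, apply_continuity_correction, study_accuracy


@pytest.fixture
def example_record():
    """The canonical worked 2×2 table: sens 0.60, spec 0.85, DOR 8.5."""
    return Study2x2Record(study_id="s1", biomarker="HE4", tp=60, fp=15, fn=40, tn=85)


@pytest.fixture
def example_accuracy(example_record):
    return study_accuracy(example_record)


def simulate_accuracies(cfg):
    """Study-level simulation → per-study accuracy statistics."""
    from serodta.synthetic import simulate_dta_studies

    return [
        study_accuracy(apply_continuity_correction(r)) for r in simulate_dta_studies(cfg)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20241019)
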