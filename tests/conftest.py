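import numpy as np
import pytest

from mtsurv.phantoms import generate_cohort, tiny_phantom_spec
from mtsurv.pipeline import normalize_sample
from mtsurv.survival import SurvivalRecord


@pytest.fixture(scope="session")
def tiny_cohort():
    """A small normalized phantom cohort with ground truth, shared across tests."""
    spec = tiny_phantom_spec(cohort_size=24, seed=42)
    samples, truths = generate_cohort(spec)
    return [normalize_sample(s) for s in samples], truths, spec


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_records(rng, n, censor_frac=0.4, tie_times=False):
    """Censored survival records with exponential times."""
    times = rng.exponential(30.0, size=n)
    if tie_times:
        times = np.round(times / 5.0) * 5.0 + 1.0
    events = (rng.random(n) > censor_frac).astype(int)
    return [SurvivalRecord(float(t), int(e), f"R{i}") for i, (t, e) in enumerate(zip(times, events))]
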