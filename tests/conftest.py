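import numpy as np
import pytest

from nextbg.synthetic_cohort import Admission, BGObservation, Demographics


def make_admission(
    times_minutes,
    glucose,
    admission_id="admX",
    start_minutes=0.0,
    diabetes_dx="none",
):
    """Hand-built admission for rule-level tests."""
    obs = [
        BGObservation(admission_id, float(t), float(g))
        for t, g in zip(times_minutes, glucose)
    ]
    return Admission(
        admission_id=admission_id,
        demographics=Demographics(age=60.0, sex="F", race="White"),
        diabetes_dx=diabetes_dx,
        home_insulin=False,
        observations=obs,
        start_minutes=start_minutes,
    )


@pytest.fixture
def admission_factory():
    return make_admission


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_admission(rng, n_min=4, n_max=40, admission_id="admR"):
    """Random but structurally valid admission (strictly increasing times)."""
    n = int(rng.integers(n_min, n_max + 1))
    gaps = rng.uniform(3.0, 400.0, n - 1)
    t = np.concatenate([[0.0], np.cumsum(gaps)])
    g = rng.uniform(45.0, 450.0, n)
    return make_admission(t, g, admission_id=admission_id, start_minutes=float(rng.uniform(0, 1440)))
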