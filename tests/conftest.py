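import numpy as np
import pytest

from walkpd.evaluation import prepare_cohort_windows
from walkpd.io import EventWindow
from walkpd.synthetic import SimulationConfig


@pytest.fixture(scope="session")
def small_cohort():
    """2 HC + 2 PD, two short days: exercises the whole HAR chain quickly."""
    cfg = SimulationConfig(
        n_hc=2, n_pd=2, day_indices=(0, 1), wear_hours_per_day=0.25, seed=11
    )
    return prepare_cohort_windows(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_window(samples, subject_id="s1", day_index=0, start_time=0, rate=20.0):
    samples = np.asarray(samples, dtype=float)
    return EventWindow(
        subject_id=subject_id,
        day_index=day_index,
        start_time=start_time,
        samples=samples,
        sample_rate=rate,
    )


@pytest.fixture
def window_factory():
    return make_window
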