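import datetime as dt

import numpy as np
import pytest

from promptpa import SimulationConfig, simulate_trial
from promptpa.core import MinuteSeries, classify_intensity

START = dt.date(2021, 6, 7)


def make_series(steps=0.0, heart_rate=80.0, pid="P01", date=START,
                cfg: SimulationConfig | None = None) -> MinuteSeries:
    """Build a participant-day from scalars or full 1440-arrays."""
    cfg = cfg or SimulationConfig()
    s = np.full(1440, float(steps)) if np.isscalar(steps) \
        else np.asarray(steps, dtype=float)
    h = np.full(1440, float(heart_rate)) if np.isscalar(heart_rate) \
        else np.asarray(heart_rate, dtype=float)
    inten = classify_intensity(s, h, cfg.moderate_steps_per_min,
                               cfg.vigorous_steps_per_min, cfg.hr_elevated_bpm)
    return MinuteSeries(pid, date, s, h, inten)


@pytest.fixture(scope="session")
def tiny_trial():
    """Two participants, baseline + one intervention week."""
    return simulate_trial(SimulationConfig(n_participants=2, n_periods=2,
                                           seed=11))


@pytest.fixture()
def series_factory():
    return make_series
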