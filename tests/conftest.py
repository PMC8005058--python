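import numpy as np
import pytest
from hypothesis import settings

import amzi_twin as at

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def layout():
    return at.default_chip_layout()


@pytest.fixture(scope="session")
def sweep():
    return at.SweepConfig()


@pytest.fixture(scope="session")
def zero_noise():
    return at.NoiseBudget(0.0, 0.0, 0.0)


@pytest.fixture(scope="session")
def budget_08pm():
    # three equal components composing to a 3-sigma of 0.8 pm
    s = 0.8 / 3.0 / np.sqrt(3.0)
    return at.NoiseBudget(s, s, s)


def cosine_record(phase, fringes, n_samples=1000, amplitude=0.5, offset=0.6, n_channels=1):
    """Synthetic interferogram record: pure cosine(s) with known phase."""
    j = np.arange(n_samples)
    trace = offset + amplitude * np.cos(2 * np.pi * fringes * j / n_samples + phase)
    return at.RawSweepRecord(
        cycle_index=0, timestamp_s=0.0, samples=np.tile(trace, (n_channels, 1))
    )


def lsq_cosine_phase(trace, fringes):
    """Independent phase oracle: linear least-squares fit of
    a*cos(w j) + b*sin(w j) + c at the known fringe frequency;
    the fitted phase of A*cos(w j + phi) is atan2(-b, a)."""
    n = len(trace)
    j = np.arange(n)
    w = 2 * np.pi * fringes / n
    design = np.column_stack([np.cos(w * j), np.sin(w * j), np.ones(n)])
    (a, b, _), *_ = np.linalg.lstsq(design, trace, rcond=None)
    return np.arctan2(-b, a)


def smooth_step_state(delta_riu, t_step=30.0, tau=5.0, total=60.0, dt=0.1):
    """Analyte state with a first-order bulk-index step (no surface binding)."""
    t = np.arange(0.0, total + dt / 2, dt)
    bulk = np.where(t > t_step, delta_riu * (1 - np.exp(-(t - t_step) / tau)), 0.0)
    return at.AnalyteState(
        time_s=t,
        channel_ids=[1, 2, 3, 4, 5, 6],
        surface_shift_pm=np.zeros((6, len(t))),
        bulk_index_riu=bulk,
    )
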