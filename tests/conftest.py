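import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import linehrf as lh
from linehrf.hrfs import GroundTruthHRF
from linehrf.simulate import NoiseModel

settings.register_profile("ci", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_design():
    return lh.DesignConfig(n_trials=6, tr=1.32, target_fraction=0.5, seed=0)


@pytest.fixture(scope="session")
def line_design():
    return lh.DesignConfig(n_trials=32, tr=0.105, target_fraction=0.0)


def make_noise_free_run(tr: float, n_trials: int = 32, amplitude: float = 2.0,
                        seed: int = 1, snap_to_grid: bool = False):
    """Noise-free synthetic run plus its event table and ground truth."""
    cfg = lh.DesignConfig(n_trials=n_trials, tr=tr, target_fraction=0.0)
    isis = lh.sample_isis(cfg, max(n_trials - 1, 1), seed)
    events = lh.build_event_table(isis, cfg, seed=seed + 1)
    if snap_to_grid:
        events = events.assign(onset=np.round(events["onset"] / tr) * tr)
    hrf = GroundTruthHRF(amplitude=amplitude)
    duration = float(np.ceil((events["onset"].max() + 3 + 30) / tr) * tr)
    raw, _ = lh.simulate_run(events, hrf, NoiseModel(white_sd=0, drift_slope=0),
                             tr, duration, seed=0)
    psc = lh.percent_signal_change(raw, tr)
    return events, psc, hrf


@pytest.fixture(scope="session")
def noise_free_line_run():
    return make_noise_free_run(tr=0.105, snap_to_grid=True)


@pytest.fixture(scope="session")
def noise_free_wb_run():
    return make_noise_free_run(tr=1.32)


def events_from_onsets(onsets, duration=3.0):
    return pd.DataFrame({"onset": np.asarray(onsets, dtype=float),
                         "duration": duration, "trial_type": "stim"})
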