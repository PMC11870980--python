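"""Ground-truth BOLD and behavior simulation.

Stands in for the raw study data: event-related runs with jittered
ISIs, two sampling regimes (whole-brain at TR = 1.32 s, line-scanning
at TR = 0.105 s), a depth-dependent response amplitude declining from
the pial surface to the white-matter boundary, two subject groups, and
target-detection behavior under an equal-variance signal-detection
model.

The forward model is linear: the raw series is a 100-unit baseline
modulated by the superposed percent-signal-change response, plus a
linear drift and stationary AR(1) noise.  Everything is a pure
function of its inputs and a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sp_signal
from scipy.stats import norm

from .design import DesignConfig, _sample_isis, build_event_table, predict_timecourse
from .depth import normalize_depths
from .errors import ConfigurationError, DataError
from .hrfs import GroundTruthHRF, double_gamma_hrf

__all__ = [
    "NoiseModel", "CohortSpec", "SubjectData", "CohortData",
    "simulate_run", "simulate_cohort", "simulate_behavior",
]

#: raw-signal baseline, arbitrary units; nonzero so percent-signal-change
#: conversion is exercised nontrivially
BASELINE_SIGNAL = 100.0


@dataclass(frozen=True)
class NoiseModel:
    """Additive noise on the raw series.

    white_sd is the stationary marginal SD of the AR(1) process in
    percent of baseline; drift_slope is a linear trend in percent of
    baseline per second.
    """

    white_sd: float = 2.0
    ar1_coef: float = 0.3
    drift_slope: float = 0.01

    def __post_init__(self) -> None:
        if not -1.0 < self.ar1_coef < 1.0:
            raise ConfigurationError("ar1_coef must lie in (-1, 1) for stationarity")
        if self.white_sd < 0:
            raise ConfigurationError("white_sd must be non-negative")


# per-group sampling distributions for the ground-truth HRF parameters:
# field -> (mean, sd).  Amplitude matches the line-scanning population
# statistics (M = 1.61, SD = 0.37 percent signal change); the peak delay
# is set so the response to a 3 s stimulus peaks around 5.3 +- 0.6 s.
# Dispersions are held fixed; the undershoot ratio varies mildly.
DEFAULT_GROUP_PARAMS: dict[str, tuple[float, float]] = {
    "peak_delay": (4.5, 0.55),
    "undershoot_delay": (16.0, 1.0),
    "peak_disp": (1.0, 0.0),
    "undershoot_disp": (1.0, 0.0),
    "undershoot_ratio": (1.0 / 6.0, 0.03),
    "amplitude": (1.61, 0.37),
}


@dataclass(frozen=True)
class CohortSpec:
    """Two-group cohort of line-scanning subjects.

    Defaults mirror the study's line-scanning arm: 11 young vs 9 middle
    aged subjects, 3 runs each, TR = 0.105 s, and an amplitude gradient
    of +0.5% of the mid-depth amplitude per percent of depth toward the
    pial surface.  ``group1_params``/``group2_params`` map ground-truth
    HRF fields to (mean, sd); equal dicts give a null cohort.
    """

    n_group1: int = 11
    n_group2: int = 9
    group1_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    group2_params: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_PARAMS))
    depth_amplitude_slope: float = 0.005
    n_depths: int = 10
    n_runs: int = 3
    tr: float = 0.105
    design: DesignConfig | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group1 < 2 or self.n_group2 < 2:
            raise ConfigurationError("group sizes must be >= 2")
        if self.n_depths < 1:
            raise ConfigurationError("n_depths must be >= 1")
        if self.n_runs < 1:
            raise ConfigurationError("n_runs must be >= 1")


@dataclass
class SubjectData:
    subject_id: str
    group: str
    events: list[pd.DataFrame]          # one table per run
    runs: list[np.ndarray]              # (n_depths, n_time) raw-signal matrices
    ground_truth: GroundTruthHRF        # depth-averaged truth (amplitude at 50%)
    depth_amplitudes: np.ndarray
    depths: np.ndarray
    tr: float


@dataclass
class CohortData:
    subjects: list[SubjectData]
    ground_truth_table: pd.DataFrame
    spec: CohortSpec


def _ar1_noise(n: int, noise: NoiseModel, rng: np.random.Generator) -> np.ndarray:
    if noise.white_sd == 0 or n == 0:
        return np.zeros(n)
    a = noise.ar1_coef
    innov_sd = noise.white_sd * np.sqrt(1.0 - a * a)
    e = np.empty(n)
    e[0] = rng.normal(0.0, noise.white_sd)  # stationary start
    if n > 1:
        w = rng.normal(0.0, innov_sd, size=n - 1)
        e[1:] = sp_signal.lfilter([1.0], [1.0, -a], w, zi=[a * e[0]])[0]
    return e


def single_trial_response(hrf: GroundTruthHRF, stim_duration: float, tr: float,
                          kernel_support: float = 24.0) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth response to one isolated trial.

    Returns (lags, values) on the internal fine grid (step <= 0.05 s,
    an integer divisor of ``tr``); the peak equals ``hrf.amplitude``.
    Sampling every ``tr / step``-th value gives the response on the
    scanner's sampling lattice.
    """
    k = max(int(math.ceil(tr / 0.05)), 1)
    dt = tr / k
    grid = np.arange(0.0, kernel_support, dt)
    kernel = double_gamma_hrf(hrf, grid)
    single = pd.DataFrame({"onset": [0.0], "duration": [stim_duration],
                           "trial_type": ["stim"]})
    resp = predict_timecourse(single, kernel, dt,
                              stim_duration + kernel_support + dt)
    if hrf.amplitude != 0 and resp.max() > 0:
        resp = resp * (hrf.amplitude / resp.max())
    return np.arange(resp.size) * dt, resp


def simulate_run(events: pd.DataFrame, hrf: GroundTruthHRF, noise: NoiseModel,
                 tr: float, duration: float, seed: int,
                 kernel_support: float = 24.0) -> tuple[np.ndarray, dict]:
    """Simulate one raw-signal run from an event table.

    The double-gamma kernel (finite support ``[0, kernel_support)``) is
    convolved with the stimulus boxcars on an oversampled internal grid
    (step <= 0.05 s) so event timing is honored regardless of the
    sampling interval, rescaled so the peak of an isolated single-trial
    response equals ``hrf.amplitude`` percent signal change, and then
    decimated to the ``tr`` lattice.  The raw series is ``BASELINE *
    (1 + response/100)`` plus drift and AR(1) noise;
    percent-signal-change conversion against the initial baseline
    recovers the response.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration / tr))
    times = np.arange(n) * tr

    stim = events[events["trial_type"] == "stim"] if len(events) else events
    if len(stim) and hrf.amplitude != 0:
        k = max(int(math.ceil(tr / 0.05)), 1)
        dt = tr / k
        grid = np.arange(0.0, kernel_support, dt)
        kernel = double_gamma_hrf(hrf, grid)
        stim_dur = float(stim["duration"].iloc[0])
        fine = predict_timecourse(events, kernel, dt, duration)
        single_raw = predict_timecourse(
            pd.DataFrame({"onset": [0.0], "duration": [stim_dur],
                          "trial_type": ["stim"]}),
            kernel, dt, stim_dur + kernel_support + dt)
        response = fine[::k][:n] * (hrf.amplitude / single_raw.max())
        if response.size < n:
            response = np.pad(response, (0, n - response.size))
    else:
        response = np.zeros(n)

    raw = BASELINE_SIGNAL * (1.0 + response / 100.0)
    raw = raw + BASELINE_SIGNAL / 100.0 * (noise.drift_slope * times
                                           + _ar1_noise(n, noise, rng))
    meta = {"tr": tr, "duration": duration, "seed": seed,
            "baseline": BASELINE_SIGNAL, "units": "arbitrary"}
    return raw, meta


def _draw_subject_hrf(params: dict, rng: np.random.Generator) -> GroundTruthHRF:
    drawn = {}
    for name, (mean, sd) in params.items():
        value = rng.normal(mean, sd) if sd > 0 else mean
        drawn[name] = value
    # keep the shape family valid for extreme draws
    drawn["peak_delay"] = max(drawn.get("peak_delay", 6.0), 1.0)
    drawn["undershoot_delay"] = max(drawn.get("undershoot_delay", 16.0),
                                    drawn["peak_delay"] + 2.0)
    drawn["undershoot_ratio"] = float(np.clip(drawn.get("undershoot_ratio", 1 / 6), 0.0, 0.9))
    return GroundTruthHRF(**drawn)


def _run_events(design: DesignConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One jittered event table (a single ISI draw; the candidate-search
    optimization is a design-time step, not repeated per simulated run)."""
    isis = _sample_isis(design, max(design.n_trials - 1, 1), rng)
    if design.n_trials == 1:
        isis = isis[:0]
    return build_event_table(isis, design,
                             seed=int(rng.integers(0, 2**31 - 1)))


def simulate_cohort(spec: CohortSpec) -> CohortData:
    """Simulate a full two-group cohort with known ground truth.

    Subject-level HRF parameters are drawn from the group
    distributions; the amplitude at depth d (percent of pial-to-WM
    distance) is ``amplitude * (1 + depth_amplitude_slope * (50 - d))``,
    so a positive slope means stronger responses toward the pial
    surface.  All runs of a subject share its ground truth; noise is
    independent across runs and depths.
    """
    root = np.random.SeedSequence(spec.seed)
    design = spec.design or DesignConfig(tr=spec.tr)
    depths = normalize_depths(spec.n_depths)

    subjects: list[SubjectData] = []
    truth_rows = []
    group_sizes = [("group1", spec.n_group1, spec.group1_params),
                   ("group2", spec.n_group2, spec.group2_params)]
    child_seqs = root.spawn(spec.n_group1 + spec.n_group2)
    idx = 0
    for group, n_subj, params in group_sizes:
        for k in range(n_subj):
            rng = np.random.default_rng(child_seqs[idx])
            subject_id = f"{group}_s{k:02d}"
            hrf = _draw_subject_hrf(params, rng)
            amp_d = hrf.amplitude * (1.0 + spec.depth_amplitude_slope * (50.0 - depths))
            # runs repeat one jittered design so they can be averaged
            # sample-by-sample before deconvolution
            events = _run_events(design, rng)
            last = events[events["trial_type"] == "stim"]["onset"].max()
            duration = float(np.ceil((last + design.stim_duration + 30.0)
                                     / spec.tr) * spec.tr)
            run_events, run_mats = [], []
            for _ in range(spec.n_runs):
                mat = np.empty((spec.n_depths,
                                int(round(duration / spec.tr))))
                for d in range(spec.n_depths):
                    series, _meta = simulate_run(
                        events, replace(hrf, amplitude=float(amp_d[d])),
                        spec.noise, spec.tr, duration,
                        seed=int(rng.integers(0, 2**31 - 1)))
                    mat[d] = series
                run_events.append(events)
                run_mats.append(mat)
            subjects.append(SubjectData(subject_id, group, run_events, run_mats,
                                        hrf, amp_d, depths, spec.tr))
            row = {"subject": subject_id, "group": group,
                   "depth_amplitude_slope": spec.depth_amplitude_slope}
            row.update({f"true_{f}": getattr(hrf, f)
                        for f in ("peak_delay", "undershoot_delay", "peak_disp",
                                  "undershoot_disp", "undershoot_ratio", "amplitude")})
            truth_rows.append(row)
            idx += 1
    return CohortData(subjects, pd.DataFrame(truth_rows), spec)


def simulate_behavior(events: pd.DataFrame, dprime_true: float,
                      criterion: float = 0.0, rt_mean: float = 0.45,
                      rt_sd: float = 0.1, seed: int = 0) -> pd.DataFrame:
    """Simulate target-detection behavior for one run.

    Equal-variance Gaussian signal-detection model: hit probability
    Phi(d'/2 - c), false-alarm probability Phi(-d'/2 - c).  Reaction
    times of responses are lognormal with the requested mean and SD.
    """
    if dprime_true < 0:
        raise DataError("dprime_true must be non-negative")
    rng = np.random.default_rng(seed)
    stim = events[events["trial_type"] == "stim"].reset_index(drop=True)
    targets = events[events["trial_type"] == "target"]
    is_target = np.zeros(len(stim), dtype=bool)
    for t_on in targets["onset"]:
        inside = ((stim["onset"] <= t_on + 1e-9)
                  & (t_on < stim["onset"] + stim["duration"] + 1e-9))
        if inside.any():
            is_target[np.nonzero(inside.to_numpy())[0][0]] = True

    p_hit = norm.cdf(dprime_true / 2.0 - criterion)
    p_fa = norm.cdf(-dprime_true / 2.0 - criterion)
    p = np.where(is_target, p_hit, p_fa)
    responded = rng.random(len(stim)) < p

    sigma2 = np.log1p((rt_sd / rt_mean) ** 2)
    mu = np.log(rt_mean) - sigma2 / 2.0
    rts = np.where(responded,
                   rng.lognormal(mu, np.sqrt(sigma2), size=len(stim)),
                   np.nan)
    return pd.DataFrame({
        "trial": np.arange(len(stim)),
        "onset": stim["onset"],
        "is_target": is_target,
        "response": responded,
        "rt": rts,
    })
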