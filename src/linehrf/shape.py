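"""Shape characterization of an estimated hemodynamic response.

Six parameters summarize an HRF curve: response amplitude, time to
peak, full width at half maximum, rising slope, positive area under
the curve, and post-stimulus undershoot area.  All are read directly
off the sampled curve (grid step 0.05 s by default elsewhere) with
linear interpolation at the half-maximum and zero crossings; no
parametric function is fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .deconv import HRFCurve
from .errors import DataError

__all__ = ["HRFParameters", "extract_parameters", "PARAMETER_NAMES"]

#: canonical column order of shape-parameter tables
PARAMETER_NAMES = ["amplitude", "time_to_peak", "fwhm", "rising_slope",
                   "positive_area", "undershoot_area"]


@dataclass
class HRFParameters:
    """The six HRF shape parameters.

    amplitude in % signal change, timings in seconds, rising_slope in
    %/s, areas in %*s.  ``fwhm`` is NaN with ``fwhm_defined`` False
    when a half-maximum crossing is missing on either side of the
    peak; ``undershoot_area`` is NaN when the undershoot was not
    computed (it is skipped for noisy per-depth curves).
    """

    amplitude: float
    time_to_peak: float
    fwhm: float
    rising_slope: float
    positive_area: float
    undershoot_area: float
    fwhm_defined: bool = True
    undershoot_defined: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def _interp_crossing(t0: float, t1: float, v0: float, v1: float, level: float) -> float:
    return t0 + (level - v0) / (v1 - v0) * (t1 - t0)


def _half_max_width(t: np.ndarray, v: np.ndarray, peak_idx: int,
                    half: float) -> tuple[float, bool]:
    left = None
    for i in range(peak_idx, 0, -1):
        if v[i - 1] < half <= v[i]:
            left = _interp_crossing(t[i - 1], t[i], v[i - 1], v[i], half)
            break
    right = None
    for i in range(peak_idx, v.size - 1):
        if v[i] >= half > v[i + 1]:
            right = _interp_crossing(t[i], t[i + 1], v[i], v[i + 1], half)
            break
    if left is None or right is None:
        return math.nan, False
    return right - left, True


def extract_parameters(curve: HRFCurve, compute_undershoot: bool = True) -> HRFParameters:
    """Extract the six shape parameters from a peristimulus curve.

    The peak is searched over t >= 0 only (the pre-onset window is a
    baseline check, not part of the response).  The rising slope is the
    maximum first-difference derivative between onset and the peak; the
    positive area integrates every positive lobe in [0, window_end];
    the undershoot area is the absolute integral of the negative part
    from the first post-peak zero crossing to the window end.
    """
    t_all, v_all = curve.time, curve.values
    post = t_all >= -1e-12
    t, v = t_all[post], v_all[post]
    if t.size < 3:
        raise DataError("curve needs at least 3 samples at t >= 0")
    if np.all(v <= 0):
        raise DataError("curve has no positive lobe; amplitude undefined")

    peak_idx = int(np.argmax(v))
    amplitude = float(v[peak_idx])
    time_to_peak = float(t[peak_idx])
    fwhm, fwhm_ok = _half_max_width(t, v, peak_idx, amplitude / 2.0)

    if peak_idx == 0:
        rising_slope = math.nan
    else:
        deriv = np.diff(v[:peak_idx + 1]) / np.diff(t[:peak_idx + 1])
        rising_slope = float(deriv.max())

    positive_area = float(np.trapezoid(np.clip(v, 0.0, None), t))

    undershoot_area = math.nan
    if compute_undershoot:
        undershoot_area = 0.0
        for i in range(peak_idx, t.size - 1):
            if v[i] > 0 >= v[i + 1]:
                cross = _interp_crossing(t[i], t[i + 1], v[i], v[i + 1], 0.0)
                tt = np.concatenate([[cross], t[i + 1:]])
                vv = np.concatenate([[0.0], v[i + 1:]])
                undershoot_area = float(abs(np.trapezoid(np.clip(vv, None, 0.0), tt)))
                break

    return HRFParameters(
        amplitude=amplitude,
        time_to_peak=time_to_peak,
        fwhm=fwhm,
        rising_slope=rising_slope,
        positive_area=positive_area,
        undershoot_area=undershoot_area,
        fwhm_defined=fwhm_ok,
        undershoot_defined=compute_undershoot,
    )
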