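"""Parametric hemodynamic response kernels.

The double-gamma family is the standard description of the BOLD impulse
response: a gamma-density positive lobe peaking around 5-6 s minus a
scaled, later gamma density modelling the post-stimulus undershoot.
It serves two roles here: the canonical kernel used when optimizing
event-related designs, and the ground-truth response family of the
synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .errors import DataError

__all__ = ["GroundTruthHRF", "double_gamma_hrf", "canonical_hrf"]


@dataclass(frozen=True)
class GroundTruthHRF:
    """Parameters of a double-gamma hemodynamic response.

    Attributes
    ----------
    peak_delay, undershoot_delay : float
        Delays (s) of the positive lobe and the undershoot; the gamma
        shape is ``delay / dispersion`` so with dispersion 1 the mode of
        the positive lobe sits at ``peak_delay - 1`` seconds.
    peak_disp, undershoot_disp : float
        Dispersions (gamma scale parameters, s).
    undershoot_ratio : float
        Undershoot amplitude relative to the positive lobe.
    amplitude : float
        Maximum of the rendered curve, in percent signal change.  The
        curve is renormalized internally so this holds exactly.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    amplitude: float = 1.0

    def with_amplitude(self, amplitude: float) -> "GroundTruthHRF":
        return replace(self, amplitude=amplitude)


def double_gamma_hrf(params: GroundTruthHRF, grid: np.ndarray) -> np.ndarray:
    """Render a double-gamma kernel on a time grid.

    Parameters
    ----------
    params : GroundTruthHRF
    grid : array of seconds, increasing, starting at 0.

    Returns
    -------
    ndarray of the same length as ``grid``; the maximum equals
    ``params.amplitude`` (identically zero when the amplitude is 0) and
    the value at t = 0 is 0.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise DataError("time grid must be a non-empty 1-D array")
    if np.any(np.diff(grid) <= 0):
        raise DataError("time grid must be strictly increasing")
    if abs(grid[0]) > 1e-9:
        raise DataError("time grid must start at 0")
    if params.peak_disp <= 0 or params.undershoot_disp <= 0:
        raise DataError("gamma dispersions must be positive")
    if params.peak_delay <= 0 or params.undershoot_delay <= 0:
        raise DataError("gamma delays must be positive")

    pos = stats.gamma.pdf(grid, params.peak_delay / params.peak_disp,
                          scale=params.peak_disp)
    neg = stats.gamma.pdf(grid, params.undershoot_delay / params.undershoot_disp,
                          scale=params.undershoot_disp)
    curve = pos - params.undershoot_ratio * neg
    if params.amplitude == 0:
        return np.zeros_like(curve)
    peak = curve.max()
    if peak <= 0:
        raise DataError("degenerate kernel: positive lobe has no positive maximum")
    return curve * (params.amplitude / peak)


def canonical_hrf(tr: float, support: float = 32.0) -> np.ndarray:
    """Default kernel (peak delay 6 s, undershoot 16 s, ratio 1/6) sampled
    every ``tr`` seconds over ``[0, support)``; unit peak."""
    grid = np.arange(0.0, support, tr)
    return double_gamma_hrf(GroundTruthHRF(), grid)
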