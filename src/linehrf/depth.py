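"""Cortical-depth profiles of HRF parameters.

Voxels along the line are mapped to percent cortical depth (0% at the
pial surface, 100% at the white-matter boundary), shape parameters are
extracted per depth, and each parameter is regressed on depth.  The
regression is parameterized around 50% depth so its intercept is the
parameter value in mid-cortex, which is directly comparable across
subjects whose line ROIs span different numbers of voxels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .errors import DataError

__all__ = [
    "DepthProfile", "DepthRegressionResult", "normalize_depths",
    "depth_parameter_profile", "DepthRegression", "fit_depth_regression",
    "most_perpendicular_index",
]


@dataclass
class DepthProfile:
    """One HRF parameter sampled across cortical depth."""

    depths: np.ndarray   # percent of pial->WM distance, increasing
    values: np.ndarray
    parameter: str

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.depths.shape != self.values.shape:
            raise DataError("depths and values must have equal length")
        if self.depths.size and (self.depths.min() < -1e-9
                                 or self.depths.max() > 100 + 1e-9):
            raise DataError("depths must lie in [0, 100]")
        if np.any(np.diff(self.depths) <= 0):
            raise DataError("depths must be strictly increasing")


@dataclass
class DepthRegressionResult:
    slope: float             # parameter units per % depth
    value_at_50: float       # parameter units at mid-depth
    ci95_slope: tuple[float, float]
    ci95_value_at_50: tuple[float, float]
    r_squared: float


def normalize_depths(n_voxels: int) -> np.ndarray:
    """Equally spaced depth coordinates for a line of n voxels,
    spanning 0 (pial) to 100 (WM); one voxel sits at mid-depth."""
    if n_voxels < 1:
        raise DataError("n_voxels must be >= 1")
    if n_voxels == 1:
        return np.array([50.0])
    return np.linspace(0.0, 100.0, n_voxels)


def depth_parameter_profile(hrfs, depths: np.ndarray | None = None) -> dict[str, DepthProfile]:
    """Extract per-depth shape parameters from a list of HRF curves.

    Undershoot area is excluded: per-depth curves are too noisy for a
    reliable undershoot estimate, so it is only computed on the
    depth-averaged response.  Extraction failures are re-raised with
    the offending depth index.
    """
    from .shape import extract_parameters  # local import avoids a cycle

    hrfs = list(hrfs)
    if not hrfs:
        raise DataError("need at least one depth")
    if depths is None:
        depths = normalize_depths(len(hrfs))
    params = []
    for i, curve in enumerate(hrfs):
        try:
            params.append(extract_parameters(curve, compute_undershoot=False))
        except DataError as err:
            raise DataError(f"parameter extraction failed at depth index {i}: {err}")
    names = ["amplitude", "time_to_peak", "fwhm", "rising_slope", "positive_area"]
    return {name: DepthProfile(depths,
                               np.array([getattr(p, name) for p in params]),
                               name)
            for name in names}


class DepthRegression(BaseEstimator):
    """OLS of a parameter on (depth - 50), scikit-learn style.

    Fitted attributes: ``slope_`` (units per % depth), ``value_at_50_``
    (the intercept, i.e. the value at mid-depth), ``ci95_slope_``,
    ``ci95_value_at_50_`` (t-based, n - 2 df) and ``r_squared_``.
    """

    def fit(self, depths: np.ndarray, values: np.ndarray) -> "DepthRegression":
        x = np.asarray(depths, dtype=float) - 50.0
        y = np.asarray(values, dtype=float)
        if x.size != y.size:
            raise DataError("depths and values must have equal length")
        if x.size < 2:
            raise DataError("depth regression needs at least 2 points")
        res = stats.linregress(x, y)
        self.slope_ = float(res.slope)
        self.value_at_50_ = float(res.intercept)
        self.r_squared_ = float(res.rvalue ** 2)
        if x.size >= 3:
            tcrit = stats.t.ppf(0.975, x.size - 2)
            self.ci95_slope_ = (self.slope_ - tcrit * res.stderr,
                                self.slope_ + tcrit * res.stderr)
            self.ci95_value_at_50_ = (self.value_at_50_ - tcrit * res.intercept_stderr,
                                      self.value_at_50_ + tcrit * res.intercept_stderr)
        else:
            self.ci95_slope_ = (np.nan, np.nan)
            self.ci95_value_at_50_ = (np.nan, np.nan)
        return self

    def predict(self, depths: np.ndarray) -> np.ndarray:
        return self.value_at_50_ + self.slope_ * (np.asarray(depths, float) - 50.0)


def fit_depth_regression(profile: DepthProfile) -> DepthRegressionResult:
    """Linear fit of a depth profile; intercept reported at 50% depth."""
    reg = DepthRegression().fit(profile.depths, profile.values)
    return DepthRegressionResult(reg.slope_, reg.value_at_50_,
                                 reg.ci95_slope_, reg.ci95_value_at_50_,
                                 reg.r_squared_)


def most_perpendicular_index(normals: np.ndarray,
                             line_direction: np.ndarray) -> tuple[int, float]:
    """Vertex whose cortical normal is best aligned with the line.

    The angle is ``arccos(|n . d|)`` after normalization, so it is
    invariant to flipping either vector; 0 deg means the line pierces
    the cortex exactly perpendicular to the surface.  Returns
    (argmin index, angle in degrees).
    """
    normals = np.atleast_2d(np.asarray(normals, dtype=float))
    d = np.asarray(line_direction, dtype=float)
    if normals.size == 0:
        raise DataError("normals must be non-empty")
    dn = np.linalg.norm(d)
    norms = np.linalg.norm(normals, axis=1)
    if dn == 0 or np.any(norms == 0):
        raise DataError("zero-length vector")
    cosang = np.abs(normals @ d) / (norms * dn)
    angles = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    idx = int(np.argmin(angles))
    return idx, float(angles[idx])
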