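"""HRF estimation by basis-set deconvolution.

The event-related timecourse is modelled as a linear superposition of a
single, unknown peristimulus response evaluated over a window spanning
3 s before to 27 s after stimulus onset.  Two basis sets parameterize
that response:

* **FIR** — one boxcar indicator per sampling interval inside the
  window (``floor(window / tr)`` bins).  Shape-agnostic, but with many
  free coefficients each estimate pools few samples, so estimates are
  noisy at short sampling intervals.
* **Fourier** — paired sine/cosine harmonics of the window length plus
  a window-boxcar DC term.  The DC term carries the response's mean
  level inside the peristimulus window; the run-level intercept cannot
  absorb it because the superposed window boxcars are not constant in
  time, and without it the zero-mean harmonics cannot represent a
  one-signed response.  The band limit acts as a low-pass prior on
  response shape; the harmonic count is chosen by leave-one-run-out
  cross-validation.

Estimation is ordinary least squares with an intercept and a linear
drift as nuisance regressors.  `Deconvolver` and `LocalizerGLM` follow
the scikit-learn estimator protocol (constructor parameters, ``fit``,
fitted attributes with a trailing underscore); the module-level
functions are thin wrappers kept for scripting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.base import BaseEstimator

from .errors import ConfigurationError, DataError, SingularDesignError

__all__ = [
    "BasisSpec", "HRFCurve", "DeconvolutionFit", "DesignMatrix",
    "percent_signal_change", "make_basis", "build_design_matrix",
    "fit_deconvolution", "reconstruct_hrf", "select_n_regressors_cv",
    "average_runs", "Deconvolver", "LocalizerGLM", "localizer_glm",
]

RANK_TOL = 1e-10


@dataclass(frozen=True)
class BasisSpec:
    """Peristimulus window and basis family for deconvolution."""

    kind: str  # "fir" | "fourier"
    tr: float
    window_start: float = -3.0
    window_end: float = 27.0
    n_regressors: int | None = None  # fourier only; even, >= 2
    include_dc: bool = True  # fourier: add a window-boxcar (DC) term

    def __post_init__(self) -> None:
        if self.kind not in ("fir", "fourier"):
            raise ConfigurationError(f"unknown basis kind {self.kind!r}")
        if self.window_start >= self.window_end:
            raise ConfigurationError("window_start must precede window_end")
        if self.tr <= 0:
            raise ConfigurationError("tr must be positive")
        if self.kind == "fourier":
            n = self.n_regressors
            if n is None or n < 2 or n % 2:
                raise ConfigurationError(
                    "fourier basis needs an even n_regressors >= 2")

    @property
    def window_length(self) -> float:
        return self.window_end - self.window_start

    @property
    def n_functions(self) -> int:
        if self.kind == "fir":
            return int(math.floor(self.window_length / self.tr + 1e-9))
        return int(self.n_regressors) + (1 if self.include_dc else 0)


@dataclass
class HRFCurve:
    """Estimated response on a peristimulus time grid (% signal change)."""

    time: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.time.shape != self.values.shape:
            raise DataError("time and values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise DataError("HRF curve contains non-finite values")


@dataclass
class DesignMatrix:
    """GLM design with signal columns first and nuisance columns flagged."""

    X: np.ndarray
    n_signal: int
    names: list[str]

    @property
    def signal(self) -> np.ndarray:
        return self.X[:, :self.n_signal]

    @property
    def nuisance(self) -> np.ndarray:
        return self.X[:, self.n_signal:]


@dataclass
class DeconvolutionFit:
    coefficients: np.ndarray
    nuisance_coefficients: np.ndarray
    basis: BasisSpec
    residual_variance: float
    r_squared: float


def percent_signal_change(series: np.ndarray, tr: float,
                          baseline_window: float = 20.0) -> np.ndarray:
    """Convert raw signal to percent change from the initial baseline.

    The baseline is the mean over the first ``baseline_window`` seconds
    (default 20 s, the gray-screen period at the start of a run).  Works
    on 1-D series or 2-D matrices (rows = voxels/depths, time on the
    last axis).
    """
    x = np.asarray(series, dtype=float)
    n_base = max(int(math.floor(baseline_window / tr + 1e-9)), 1)
    n_base = min(n_base, x.shape[-1])
    m = x[..., :n_base].mean(axis=-1, keepdims=True)
    if np.any(np.abs(m) < 1e-12 * max(np.abs(x).max(), 1.0)):
        raise DataError("baseline mean is zero or near zero")
    return 100.0 * (x - m) / m


class BasisFunctions:
    """Evaluable basis set; calling with peristimulus offsets returns a
    (n_offsets, n_functions) matrix, zero outside the window."""

    def __init__(self, spec: BasisSpec):
        self.spec = spec

    def __call__(self, offsets: np.ndarray) -> np.ndarray:
        tau = np.asarray(offsets, dtype=float)
        s = self.spec
        out = np.zeros((tau.size, s.n_functions))
        inside = (tau >= s.window_start) & (tau < s.window_start +
                                            (s.n_functions * s.tr if s.kind == "fir"
                                             else s.window_length))
        if s.kind == "fir":
            idx = np.floor((tau[inside] - s.window_start) / s.tr).astype(int)
            out[np.nonzero(inside)[0], idx] = 1.0
        else:
            u = (tau[inside] - s.window_start) / s.window_length
            k = np.arange(1, s.n_regressors // 2 + 1)
            phase = 2.0 * np.pi * np.outer(u, k)
            col = 0
            if s.include_dc:
                # window boxcar: the response's mean level inside the
                # window; orthogonal to every harmonic over a full period
                out[inside, 0] = 1.0
                col = 1
            half = s.n_regressors // 2
            out[inside, col:col + half] = np.sin(phase)
            out[inside, col + half:] = np.cos(phase)
        return out

    def fir_bin_centers(self) -> np.ndarray:
        s = self.spec
        return s.window_start + (np.arange(s.n_functions) + 0.5) * s.tr

    def fir_bin_lags(self) -> np.ndarray:
        """For events on the tr grid: the unique grid lag inside each bin."""
        s = self.spec
        left = s.window_start + np.arange(s.n_functions) * s.tr
        return np.ceil(left / s.tr - 1e-9) * s.tr


def make_basis(spec: BasisSpec) -> BasisFunctions:
    return BasisFunctions(spec)


def _nuisance(frame_times: np.ndarray, drift: bool) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones_like(frame_times)]
    names = ["intercept"]
    if drift:
        t = frame_times - frame_times.mean()
        span = t.max() - t.min() if t.size > 1 else 1.0
        cols.append(t / (span or 1.0))
        names.append("drift")
    return np.column_stack(cols), names


def build_design_matrix(events: pd.DataFrame, basis: BasisFunctions,
                        frame_times: np.ndarray, drift: bool = True) -> DesignMatrix:
    """Signal column j at frame t is the sum of basis_j(t - onset) over
    stimulus events; intercept and linear drift are appended and flagged
    as nuisance."""
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.size > 1 and np.any(np.diff(frame_times) <= 0):
        raise DataError("frame_times must be strictly increasing")
    n_sig = basis.spec.n_functions
    Xs = np.zeros((frame_times.size, n_sig))
    stim = events[events["trial_type"] == "stim"] if len(events) else events
    for onset in stim.get("onset", []):
        Xs += basis(frame_times - onset)
    Xn, nuis_names = _nuisance(frame_times, drift)
    names = [f"{basis.spec.kind}_{j}" for j in range(n_sig)] + nuis_names
    return DesignMatrix(np.column_stack([Xs, Xn]), n_sig, names)


def _check_rank(design: DesignMatrix) -> None:
    X = design.X
    # the R diagonal of a QR factorization flags near-dependent columns
    _, rmat = np.linalg.qr(X, mode="reduced")
    diag = np.abs(np.diag(rmat))
    scale = diag.max() if diag.size else 0.0
    bad = [design.names[j] for j in range(X.shape[1])
           if diag[j] <= RANK_TOL * max(scale, 1.0)]
    if np.linalg.matrix_rank(X, tol=RANK_TOL * max(scale, 1.0)) < X.shape[1]:
        raise SingularDesignError(
            "design matrix is rank deficient; suspect columns: "
            + (", ".join(bad) if bad else "(collinear combination)"))


def fit_deconvolution(series: np.ndarray, design: DesignMatrix,
                      basis_spec: BasisSpec | None = None) -> DeconvolutionFit:
    """Ordinary least squares of a percent-signal-change series on a
    deconvolution design.

    ``r_squared`` is the variance explained by the signal columns beyond
    the nuisance-only model.
    """
    y = np.asarray(series, dtype=float)
    if y.shape[0] != design.X.shape[0]:
        raise DataError(
            f"series length {y.shape[0]} != design rows {design.X.shape[0]}")
    _check_rank(design)
    beta, *_ = np.linalg.lstsq(design.X, y, rcond=None)
    resid = y - design.X @ beta
    dof = max(y.size - design.X.shape[1], 1)
    ss_res = float(resid @ resid)
    beta_n, *_ = np.linalg.lstsq(design.nuisance, y, rcond=None)
    resid_n = y - design.nuisance @ beta_n
    ss_null = float(resid_n @ resid_n)
    r2 = 1.0 - ss_res / ss_null if ss_null > 0 else 0.0
    spec = basis_spec
    return DeconvolutionFit(
        coefficients=beta[:design.n_signal],
        nuisance_coefficients=beta[design.n_signal:],
        basis=spec,
        residual_variance=ss_res / dof,
        r_squared=r2,
    )


def reconstruct_hrf(fit: DeconvolutionFit, grid_step: float = 0.05) -> HRFCurve:
    """Evaluate a fitted basis expansion on a fine peristimulus grid.

    Fourier coefficients are evaluated analytically; FIR bin values are
    placed at bin centers and linearly interpolated.
    """
    if grid_step <= 0:
        raise DataError("grid_step must be positive")
    spec = fit.basis
    grid = np.arange(spec.window_start, spec.window_end + grid_step / 2, grid_step)
    basis = make_basis(spec)
    if spec.kind == "fourier":
        values = basis(grid) @ fit.coefficients
    else:
        centers = basis.fir_bin_centers()
        values = np.interp(grid, centers, fit.coefficients)
    return HRFCurve(grid, values)


def average_runs(runs: list[np.ndarray]) -> np.ndarray:
    """Element-wise mean across runs (equal shapes required)."""
    if not runs:
        raise DataError("no runs to average")
    arrs = [np.asarray(r, dtype=float) for r in runs]
    shape = arrs[0].shape
    if any(a.shape != shape for a in arrs):
        raise DataError("runs have mismatched shapes")
    return np.mean(arrs, axis=0)


class Deconvolver(BaseEstimator):
    """Basis-set HRF deconvolution as a scikit-learn style estimator.

    Parameters
    ----------
    kind : {"fir", "fourier"}
    tr : float
        Sampling interval of the series (s).
    window_start, window_end : float
        Peristimulus window (s from stimulus onset).
    n_regressors : int, optional
        Fourier order (even); ignored for FIR.
    drift : bool
        Include a linear drift nuisance regressor.

    Attributes
    ----------
    coef_ : (n_basis,) signal coefficients
    nuisance_coef_ : nuisance coefficients (intercept [, drift])
    r_squared_ : float, signal-explained variance beyond nuisance
    residual_var_ : float
    basis_spec_ : BasisSpec
    """

    def __init__(self, kind: str = "fourier", tr: float = 1.32,
                 window_start: float = -3.0, window_end: float = 27.0,
                 n_regressors: int | None = 10, drift: bool = True):
        self.kind = kind
        self.tr = tr
        self.window_start = window_start
        self.window_end = window_end
        self.n_regressors = n_regressors
        self.drift = drift

    def _spec(self) -> BasisSpec:
        return BasisSpec(kind=self.kind, tr=self.tr,
                         window_start=self.window_start,
                         window_end=self.window_end,
                         n_regressors=self.n_regressors if self.kind == "fourier" else None)

    def fit(self, events: pd.DataFrame, y: np.ndarray,
            frame_times: np.ndarray | None = None) -> "Deconvolver":
        y = np.asarray(y, dtype=float)
        if frame_times is None:
            frame_times = np.arange(y.shape[0]) * self.tr
        spec = self._spec()
        basis = make_basis(spec)
        design = build_design_matrix(events, basis, frame_times, drift=self.drift)
        fit = fit_deconvolution(y, design, basis_spec=spec)
        self.basis_spec_ = spec
        self.design_ = design
        self.frame_times_ = frame_times
        self.coef_ = fit.coefficients
        self.nuisance_coef_ = fit.nuisance_coefficients
        self.r_squared_ = fit.r_squared
        self.residual_var_ = fit.residual_variance
        self.fit_ = fit
        return self

    def predict(self, frame_times: np.ndarray | None = None,
                events: pd.DataFrame | None = None) -> np.ndarray:
        """Fitted signal prediction (nuisance excluded)."""
        if events is None and frame_times is None:
            return self.design_.signal @ self.coef_
        if events is None:
            raise DataError("events required when predicting on new frame_times")
        design = build_design_matrix(events, make_basis(self.basis_spec_),
                                     frame_times, drift=self.drift)
        return design.signal @ self.coef_

    def reconstruct(self, grid_step: float = 0.05) -> HRFCurve:
        return reconstruct_hrf(self.fit_, grid_step)


def select_n_regressors_cv(runs: list[tuple[np.ndarray, pd.DataFrame]],
                           candidates: list[int], tr: float,
                           window_start: float = -3.0, window_end: float = 27.0,
                           drift: bool = True) -> tuple[int, pd.DataFrame]:
    """Choose the Fourier order by leave-one-run-out cross-validation.

    For each candidate order the model is fit on all runs but one
    (stacked, with per-run nuisance regressors) and scored on the
    held-out run by out-of-set R^2 after residualizing the held-out
    series and signal design against that run's nuisance columns.
    Returns the argmax (ties resolved toward the smaller order, within
    1e-9) and the full candidate table.
    """
    if len(runs) < 2:
        raise DataError("cross-validation needs at least two runs")
    for c in candidates:
        if c < 2 or c % 2:
            raise ConfigurationError("candidate Fourier orders must be even and >= 2")

    prepared = []
    for series, events in runs:
        y = np.asarray(series, dtype=float)
        prepared.append((y, events, np.arange(y.size) * tr))

    def run_design(events, frame_times, n):
        spec = BasisSpec("fourier", tr, window_start, window_end, n)
        return build_design_matrix(events, make_basis(spec), frame_times, drift=drift)

    rows = []
    for n in candidates:
        scores = []
        for held in range(len(prepared)):
            train = [p for i, p in enumerate(prepared) if i != held]
            # stack signal columns; block-diagonal nuisance per run
            Xs, Xn_blocks, ys = [], [], []
            for y, events, ft in train:
                d = run_design(events, ft, n)
                Xs.append(d.signal)
                Xn_blocks.append(d.nuisance)
                ys.append(y)
            n_nuis = Xn_blocks[0].shape[1]
            Xn = np.zeros((sum(b.shape[0] for b in Xn_blocks),
                           n_nuis * len(Xn_blocks)))
            row0 = 0
            for i, b in enumerate(Xn_blocks):
                Xn[row0:row0 + b.shape[0], i * n_nuis:(i + 1) * n_nuis] = b
                row0 += b.shape[0]
            n_sig = Xs[0].shape[1]
            X = np.column_stack([np.vstack(Xs), Xn])
            yall = np.concatenate(ys)
            beta, *_ = np.linalg.lstsq(X, yall, rcond=None)
            beta_sig = beta[:n_sig]

            y_t, ev_t, ft_t = prepared[held]
            d_t = run_design(ev_t, ft_t, n)
            # project out the held-out run's own nuisance space
            Q, _ = np.linalg.qr(d_t.nuisance)
            y_res = y_t - Q @ (Q.T @ y_t)
            S_res = d_t.signal - Q @ (Q.T @ d_t.signal)
            resid = y_res - S_res @ beta_sig
            denom = float(y_res @ y_res)
            scores.append(1.0 - float(resid @ resid) / denom if denom > 0 else 0.0)
        rows.append({"n_regressors": n, "cv_r_squared": float(np.mean(scores))})

    table = pd.DataFrame(rows)
    best = table["cv_r_squared"].max()
    eligible = table[table["cv_r_squared"] >= best - 1e-9]
    selected = int(eligible["n_regressors"].min())
    return selected, table


class LocalizerGLM(BaseEstimator):
    """Block-design localizer GLM with a Gaussian response kernel.

    The single task regressor is the ON/OFF boxcar convolved with a
    unit-area Gaussian kernel (mean 6 s, SD 2 s by default), plus
    intercept and linear drift.  Rows of the data matrix are voxels;
    ``t_`` holds the regressor t statistic per row and ``mask_`` the
    rows with ``t >= t_threshold`` (default 2.3).
    """

    def __init__(self, tr: float = 1.32, kernel_mean: float = 6.0,
                 kernel_sd: float = 2.0, t_threshold: float = 2.3,
                 drift: bool = True):
        self.tr = tr
        self.kernel_mean = kernel_mean
        self.kernel_sd = kernel_sd
        self.t_threshold = t_threshold
        self.drift = drift

    def fit(self, events: pd.DataFrame, Y: np.ndarray) -> "LocalizerGLM":
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        n_time = Y.shape[1]
        times = np.arange(n_time) * self.tr
        box = np.zeros(n_time)
        stim = events[events["trial_type"] == "stim"] if len(events) else events
        for onset, duration in zip(stim.get("onset", []), stim.get("duration", [])):
            box[(times >= onset - 1e-9) & (times < onset + duration - 1e-9)] = 1.0
        support = np.arange(0.0, self.kernel_mean + 4 * self.kernel_sd, self.tr)
        kernel = norm.pdf(support, self.kernel_mean, self.kernel_sd) * self.tr
        reg = np.convolve(box, kernel)[:n_time]
        if np.allclose(reg, reg[0]):
            raise DataError("degenerate localizer design: constant regressor")
        Xn, _ = _nuisance(times, self.drift)
        X = np.column_stack([reg, Xn])
        p = X.shape[1]
        XtX_inv = np.linalg.inv(X.T @ X)
        beta = XtX_inv @ X.T @ Y.T  # (p, n_rows)
        resid = Y.T - X @ beta
        dof = n_time - p
        sigma2 = (resid ** 2).sum(axis=0) / dof
        se = np.sqrt(np.maximum(sigma2 * XtX_inv[0, 0], 1e-300))
        self.t_ = beta[0] / se
        self.df_ = dof
        self.mask_ = self.t_ >= self.t_threshold
        self.regressor_ = reg
        return self


def localizer_glm(series_matrix: np.ndarray, block_design: pd.DataFrame,
                  tr: float, t_threshold: float = 2.3,
                  **kernel_kwargs) -> tuple[np.ndarray, np.ndarray]:
    glm = LocalizerGLM(tr=tr, t_threshold=t_threshold, **kernel_kwargs)
    glm.fit(block_design, series_matrix)
    return glm.t_, glm.mask_
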