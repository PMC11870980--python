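"""Deconvolution GLM: basis construction, design assembly, OLS
estimation, reconstruction, cross-validation and the localizer."""

import numpy as np
import pytest

import linehrf as lh
from linehrf.deconv import (BasisSpec, DeconvolutionFit,
                            build_design_matrix, make_basis)
from linehrf.errors import (ConfigurationError, DataError,
                            SingularDesignError)

from conftest import events_from_onsets


class TestPercentSignalChange:
    def test_constant_series_maps_to_zero(self):
        out = lh.percent_signal_change(np.full(100, 100.0), tr=1.0)
        np.testing.assert_allclose(out, 0.0)

    @pytest.mark.parametrize("baseline, value, expected", [
        (100.0, 102.0, 2.0),
        (50.0, 49.0, -2.0),
    ])
    def test_sign_and_scale(self, baseline, value, expected):
        series = np.concatenate([np.full(20, baseline), [value]])
        out = lh.percent_signal_change(series, tr=1.0, baseline_window=20.0)
        assert out[-1] == pytest.approx(expected)

    def test_zero_baseline_rejected(self):
        with pytest.raises(DataError):
            lh.percent_signal_change(np.zeros(30), tr=1.0)


class TestMakeBasis:
    @pytest.mark.parametrize("tr, expected", [(1.32, 22), (0.105, 285)])
    def test_fir_bin_count_floors(self, tr, expected):
        spec = BasisSpec("fir", tr=tr)
        assert spec.n_functions == expected

    def test_fourier_pairs_are_orthogonal(self):
        # 5 sine + 5 cosine harmonics (+ window DC): the Gram matrix on a
        # dense grid is diagonal
        spec = BasisSpec("fourier", tr=1.0, n_regressors=10)
        basis = make_basis(spec)
        grid = np.linspace(-3.0, 27.0, 60000, endpoint=False)
        B = basis(grid)
        assert B.shape[1] == 11
        gram = B.T @ B * (30.0 / grid.size)
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-3

    def test_fourier_odd_count_rejected(self):
        with pytest.raises(ConfigurationError):
            BasisSpec("fourier", tr=1.0, n_regressors=9)

    def test_basis_vanishes_outside_window(self):
        for kind, n in (("fir", None), ("fourier", 6)):
            basis = make_basis(BasisSpec(kind, tr=1.0, n_regressors=n))
            out = basis(np.array([-10.0, 40.0]))
            assert np.all(out == 0.0)


class TestBuildDesignMatrix:
    def test_single_event_on_grid_is_identity_block(self):
        tr = 1.0
        spec = BasisSpec("fir", tr=tr, window_start=0.0, window_end=5.0)
        basis = make_basis(spec)
        events = events_from_onsets([0.0], duration=tr)
        frames = np.arange(5) * tr
        d = build_design_matrix(events, basis, frames, drift=False)
        np.testing.assert_allclose(d.signal, np.eye(5))

    def test_no_events_gives_nuisance_only_signal(self):
        spec = BasisSpec("fir", tr=1.0)
        d = build_design_matrix(events_from_onsets([]), make_basis(spec),
                                np.arange(40.0))
        assert np.all(d.signal == 0.0)
        assert d.nuisance.shape[1] == 2

    def test_superposition_over_events(self):
        spec = BasisSpec("fourier", tr=1.0, n_regressors=6)
        basis = make_basis(spec)
        frames = np.arange(80.0)
        d_ab = build_design_matrix(events_from_onsets([20.0, 26.0]), basis, frames)
        d_a = build_design_matrix(events_from_onsets([20.0]), basis, frames)
        d_b = build_design_matrix(events_from_onsets([26.0]), basis, frames)
        np.testing.assert_allclose(d_ab.signal, d_a.signal + d_b.signal)


class TestFitDeconvolution:
    def test_exact_coefficient_recovery_without_noise(self):
        spec = BasisSpec("fourier", tr=1.0, n_regressors=6)
        basis = make_basis(spec)
        frames = np.arange(120.0)
        d = build_design_matrix(events_from_onsets([20.0, 41.0, 66.0]),
                                basis, frames)
        rng = np.random.default_rng(0)
        beta = np.concatenate([rng.normal(size=d.n_signal), [1.0, 0.5]])
        y = d.X @ beta
        fit = lh.fit_deconvolution(y, d, basis_spec=spec)
        np.testing.assert_allclose(fit.coefficients, beta[:d.n_signal],
                                   atol=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_pure_noise_orthogonal_design_near_zero(self):
        rng = np.random.default_rng(1)
        n = 4000
        X = np.column_stack([np.eye(2)[rng.integers(0, 2, n)][:, :1],
                             np.ones(n)])
        from linehrf.deconv import DesignMatrix
        d = DesignMatrix(X, 1, ["c0", "intercept"])
        y = rng.normal(size=n)
        fit = lh.fit_deconvolution(y, d)
        assert abs(fit.coefficients[0]) < 0.15
        assert fit.r_squared < 0.01

    def test_duplicated_column_raises_named_error(self):
        X = np.column_stack([np.arange(10.0), np.arange(10.0), np.ones(10)])
        from linehrf.deconv import DesignMatrix
        d = DesignMatrix(X, 2, ["a", "b", "intercept"])
        with pytest.raises(SingularDesignError):
            lh.fit_deconvolution(np.zeros(10), d)

    def test_length_mismatch_rejected(self):
        spec = BasisSpec("fir", tr=1.0)
        d = build_design_matrix(events_from_onsets([5.0]), make_basis(spec),
                                np.arange(50.0))
        with pytest.raises(DataError):
            lh.fit_deconvolution(np.zeros(10), d)


class TestReconstruct:
    def test_zero_coefficients_give_zero_curve(self):
        spec = BasisSpec("fourier", tr=1.0, n_regressors=4)
        fit = DeconvolutionFit(np.zeros(spec.n_functions), np.zeros(2),
                               spec, 0.0, 0.0)
        curve = lh.reconstruct_hrf(fit, 0.1)
        assert np.all(curve.values == 0.0)

    def test_fourier_reproduces_in_band_sinusoid(self):
        # fit an in-band sinusoid sampled on frames; the analytic
        # reconstruction must match the target on the fine grid
        spec = BasisSpec("fourier", tr=0.5, window_start=0.0,
                         window_end=30.0, n_regressors=6)
        basis = make_basis(spec)
        events = events_from_onsets([0.0])
        frames = np.arange(0.0, 45.0, 0.5)
        d = build_design_matrix(events, basis, frames, drift=False)
        target = np.where(frames < 30.0,
                          np.sin(2 * np.pi * 2 * frames / 30.0), 0.0)
        fit = lh.fit_deconvolution(target, d, basis_spec=spec)
        curve = lh.reconstruct_hrf(fit, 0.01)
        expected = np.sin(2 * np.pi * 2 * curve.time / 30.0)
        assert np.abs(curve.values - expected).max() < 1e-6

    def test_fir_bins_peak_at_bin_center(self):
        spec = BasisSpec("fir", tr=1.0, window_start=0.0, window_end=3.0)
        fit = DeconvolutionFit(np.array([0.0, 2.0, 0.0]), np.zeros(2),
                               spec, 0.0, 1.0)
        curve = lh.reconstruct_hrf(fit, 0.5)
        assert curve.values.max() == pytest.approx(2.0)
        assert curve.time[np.argmax(curve.values)] == pytest.approx(1.5)


class TestCrossValidation:
    @staticmethod
    def _runs_from_truth(n_runs, n_harmonics, tr=1.0, seed=0):
        """Noise-free runs whose single-trial response is a band-limited
        combination of the first ``n_harmonics`` window harmonics."""
        spec = BasisSpec("fourier", tr=tr, n_regressors=2 * n_harmonics)
        basis = make_basis(spec)
        rng = np.random.default_rng(seed)
        beta = rng.normal(size=spec.n_functions)
        runs = []
        for r in range(n_runs):
            onsets = 20.0 + np.cumsum(rng.uniform(8, 14, size=6))
            events = events_from_onsets(onsets)
            frames = np.arange(0.0, onsets[-1] + 33.0, tr)
            d = build_design_matrix(events, basis, frames, drift=False)
            runs.append((d.signal @ beta, events))
        return runs

    def test_noise_free_two_harmonic_truth_selects_four(self):
        runs = self._runs_from_truth(3, 2)
        selected, table = lh.select_n_regressors_cv(runs, [4, 6, 8, 10], tr=1.0)
        assert selected == 4
        assert table.loc[table["n_regressors"] == 4,
                         "cv_r_squared"].iloc[0] > 0.999

    def test_single_candidate_returned(self):
        runs = self._runs_from_truth(2, 2)
        selected, _ = lh.select_n_regressors_cv(runs, [4], tr=1.0)
        assert selected == 4

    def test_selected_count_maximizes_cv_r2(self):
        runs = self._runs_from_truth(3, 3, seed=5)
        selected, table = lh.select_n_regressors_cv(runs, [2, 4, 6, 8], tr=1.0)
        best = table["cv_r_squared"].max()
        row = table[table["n_regressors"] == selected].iloc[0]
        assert row["cv_r_squared"] >= best - 1e-9

    def test_single_run_rejected(self):
        runs = self._runs_from_truth(1, 2)
        with pytest.raises(DataError):
            lh.select_n_regressors_cv(runs, [4, 6], tr=1.0)


class TestAverageRuns:
    def test_single_run_is_identity(self):
        x = np.arange(12.0).reshape(3, 4)
        np.testing.assert_array_equal(lh.average_runs([x]), x)

    def test_opposite_runs_cancel(self):
        x = np.random.default_rng(0).normal(size=(2, 30))
        np.testing.assert_allclose(lh.average_runs([x, -x]), 0.0)

    def test_averaging_shrinks_noise_variance(self):
        rng = np.random.default_rng(2)
        runs = [rng.normal(size=20000) for _ in range(3)]
        v1 = np.var(runs[0])
        v3 = np.var(lh.average_runs(runs))
        assert v3 == pytest.approx(v1 / 3, rel=0.1)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(DataError):
            lh.average_runs([np.zeros(3), np.zeros(4)])


class TestLocalizerGLM:
    @staticmethod
    def _block_events(n_blocks=6, on=12.0, off=12.0):
        onsets = np.arange(n_blocks) * (on + off) + off
        return events_from_onsets(onsets, duration=on)

    def test_noiseless_regressor_row_included(self):
        events = self._block_events()
        glm = lh.LocalizerGLM(tr=1.32).fit(events, np.zeros((1, 120)))
        series = 3.0 * glm.regressor_ + 5.0
        t, mask = lh.deconv.localizer_glm(series[None, :], events, tr=1.32)
        assert t[0] > 1e5
        assert mask[0]

    def test_infinite_threshold_empties_mask(self):
        events = self._block_events()
        rng = np.random.default_rng(0)
        Y = rng.normal(size=(20, 120))
        _, mask = lh.deconv.localizer_glm(Y, events, tr=1.32,
                                          t_threshold=np.inf)
        assert not mask.any()

    def test_null_inclusion_rate_matches_t_tail(self):
        """White-noise rows are included at about P(t >= 2.3) under the
        null t distribution."""
        from scipy import stats as sps
        events = self._block_events()
        rng = np.random.default_rng(42)
        n_rows, n_time = 2000, 120
        glm = lh.LocalizerGLM(tr=1.32).fit(events,
                                           rng.normal(size=(n_rows, n_time)))
        expected = sps.t.sf(2.3, glm.df_)
        rate = glm.mask_.mean()
        # binomial tolerance at 2000 draws
        assert rate == pytest.approx(expected, abs=3 * np.sqrt(expected / n_rows))


class TestModelInvariants:
    def test_deconvolution_commutes_with_scaling(self, noise_free_wb_run):
        events, psc, _ = noise_free_wb_run
        d1 = lh.Deconvolver(kind="fourier", tr=1.32, n_regressors=8)
        c1 = d1.fit(events, psc).reconstruct(0.1)
        d2 = lh.Deconvolver(kind="fourier", tr=1.32, n_regressors=8)
        c2 = d2.fit(events, 3.0 * psc).reconstruct(0.1)
        np.testing.assert_allclose(c2.values, 3.0 * c1.values, atol=1e-9)

    def test_training_r2_nondecreasing_in_harmonics(self, noise_free_wb_run):
        events, psc, _ = noise_free_wb_run
        r2 = [lh.Deconvolver(kind="fourier", tr=1.32, n_regressors=n)
              .fit(events, psc).r_squared_ for n in (2, 4, 6, 8, 10)]
        assert np.all(np.diff(r2) >= -1e-12)

    def test_fir_and_fourier_agree_on_band_limited_truth(self):
        """Both bases reconstruct the same noise-free band-limited
        response within 2% RMS of its peak."""
        tr = 0.25
        spec = BasisSpec("fourier", tr=tr, n_regressors=8)
        basis = make_basis(spec)
        rng = np.random.default_rng(3)
        onsets = 20.0 + np.cumsum(rng.uniform(8, 15, size=10))
        # place onsets on the half-grid so every FIR bin samples the
        # response exactly at its center
        onsets = (np.round(onsets / tr - 0.5) + 0.5) * tr
        events = events_from_onsets(onsets)
        frames = np.arange(0.0, onsets[-1] + 33.0, tr)
        d = build_design_matrix(events, basis, frames, drift=False)
        beta = rng.normal(size=spec.n_functions)
        y = d.signal @ beta

        cf = lh.Deconvolver(kind="fourier", tr=tr, n_regressors=8)
        cf.fit(events, y, frame_times=frames)
        ff = lh.Deconvolver(kind="fir", tr=tr)
        ff.fit(events, y, frame_times=frames)
        grid = 0.05
        a = cf.reconstruct(grid).values
        b = ff.reconstruct(grid).values
        keep = slice(int(1.0 / grid), a.size - int(1.0 / grid))  # edge bins interpolate
        rms = np.sqrt(np.mean((a[keep] - b[keep]) ** 2))
        assert rms < 0.02 * np.abs(a).max()
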