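"""Cleaning-contract tests: FD, censoring, nuisance regression, band-pass."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recovnet.preprocessing import (
    MinimumVolumesError,
    PreprocessConfig,
    Preprocessor,
    bandpass,
    build_nuisance_design,
    compute_fd,
    flag_and_censor,
    regress_nuisance,
)


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        assert np.allclose(compute_fd(np.zeros((50, 6))), 0.0)

    def test_single_translation_step(self):
        motion = np.zeros((20, 6))
        motion[10:, 0] = 0.3  # step of +0.3 mm in x at volume 10
        fd = compute_fd(motion)
        expected = np.zeros(20)
        expected[10] = 0.3
        assert np.allclose(fd, expected)

    def test_rotation_scaled_by_sphere_radius(self):
        motion = np.zeros((5, 6))
        motion[2:, 3] = 0.01  # 0.01 rad step
        fd = compute_fd(motion, radius_mm=50.0)
        assert fd[2] == pytest.approx(0.5)  # 0.01 x 50

    def test_first_volume_fd_is_zero(self):
        rng = np.random.default_rng(0)
        fd = compute_fd(rng.normal(size=(30, 6)))
        assert fd[0] == 0.0

    def test_nonfinite_motion_rejected(self):
        motion = np.zeros((10, 6))
        motion[3, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            compute_fd(motion)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(offset=st.floats(-10, 10, allow_nan=False))
    def test_invariant_to_constant_offset(self, offset):
        rng = np.random.default_rng(7)
        motion = rng.normal(scale=0.1, size=(40, 6))
        assert np.allclose(compute_fd(motion), compute_fd(motion + offset))


class TestCensoring:
    def test_no_spikes_keeps_everything(self):
        kept = flag_and_censor(np.zeros(240), PreprocessConfig())
        assert kept.size == 240

    def test_single_spike_removes_four_volumes(self):
        fd = np.zeros(240)
        fd[100] = 0.8
        kept = flag_and_censor(fd, PreprocessConfig())
        assert kept.size == 236
        removed = sorted(set(range(240)) - set(kept.tolist()))
        assert removed == [99, 100, 101, 102]

    def test_windows_clip_at_series_edges(self):
        fd = np.zeros(200)
        fd[0] = 1.0
        fd[199] = 1.0
        kept = flag_and_censor(fd, PreprocessConfig())
        # volume 0: no predecessor; volume 199: only itself (no followers)
        assert 0 not in kept and 1 not in kept and 2 not in kept
        assert 199 not in kept and 198 not in kept

    def test_too_many_spikes_raises_minimum_volumes_error(self):
        fd = np.zeros(240)
        fd[::4] = 1.0  # dense spikes censor everything
        with pytest.raises(MinimumVolumesError) as exc:
            flag_and_censor(fd, PreprocessConfig())
        assert exc.value.n_kept < 140

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(3)
        fd = np.where(rng.random(400) < 0.05, 1.0, 0.05)
        cfg = PreprocessConfig(min_volumes=10)
        kept = flag_and_censor(fd, cfg)
        again = flag_and_censor(fd[kept], cfg)
        assert again.size == kept.size


class TestNuisanceDesign:
    def _signals(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        return (rng.normal(size=(n, 6)), rng.normal(size=n), rng.normal(size=n),
                rng.normal(size=n))

    def test_full_design_has_36_columns(self):
        motion, wm, csf, gs = self._signals()
        assert build_nuisance_design(motion, wm, csf, gs).shape[1] == 36

    def test_without_global_signal_32_columns(self):
        # drop the global signal, its derivative and both squares: 36 - 4
        motion, wm, csf, _ = self._signals()
        design = build_nuisance_design(motion, wm, csf, use_global=False)
        assert design.shape[1] == 32

    def test_linear_ramp_derivative_is_constant(self):
        motion = np.zeros((50, 6))
        motion[:, 0] = np.arange(50) * 0.1
        design = build_nuisance_design(motion, np.zeros(50), np.zeros(50),
                                       np.zeros(50))
        deriv_col = design[:, 9]  # derivative of first motion column
        assert np.allclose(deriv_col[1:], 0.1)
        assert deriv_col[0] == 0.0

    def test_quadratic_columns_are_squares(self):
        motion, wm, csf, gs = self._signals()
        design = build_nuisance_design(motion, wm, csf, gs)
        assert np.allclose(design[:, 18:], design[:, :18] ** 2)

    def test_constant_signals_produce_low_rank_design(self):
        motion = np.zeros((40, 6))
        design = build_nuisance_design(motion, np.ones(40), np.ones(40),
                                       np.ones(40))
        demeaned = design - design.mean(axis=0)
        assert np.linalg.matrix_rank(demeaned) <= 2

    def test_length_mismatch_rejected(self):
        motion, wm, csf, gs = self._signals()
        with pytest.raises(ValueError, match="length"):
            build_nuisance_design(motion, wm[:-1], csf, gs)


class TestNuisanceRegression:
    def test_residual_of_a_regressor_is_zero(self):
        rng = np.random.default_rng(1)
        design = rng.normal(size=(80, 5))
        data = design[:, [2]] * 3.0
        resid = regress_nuisance(data, design)
        assert np.abs(resid).max() < 1e-10

    def test_intercept_only_demeans(self):
        rng = np.random.default_rng(2)
        data = rng.normal(loc=5.0, size=(60, 3))
        resid = regress_nuisance(data, np.empty((60, 0)))
        assert np.allclose(resid, data - data.mean(axis=0), atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(100, 4))
        design = rng.normal(size=(100, 7))
        resid = regress_nuisance(data, design)
        X = np.column_stack([np.ones(100), design])
        oracle = data - X @ (np.linalg.pinv(X) @ data)
        assert np.abs(resid - oracle).max() < 1e-10

    def test_residuals_orthogonal_to_all_36_regressors(self):
        rng = np.random.default_rng(4)
        motion = np.cumsum(rng.normal(scale=0.02, size=(120, 6)), axis=0)
        wm, csf, gs = rng.normal(size=(3, 120))
        design = build_nuisance_design(motion, wm, csf, gs)
        data = rng.normal(size=(120, 5))
        resid = regress_nuisance(data, design)
        demeaned = design - design.mean(axis=0)
        dots = np.abs(demeaned.T @ resid) / design.shape[0]
        assert dots.max() < 1e-8

    def test_rank_deficient_design_warns_and_stays_orthogonal(self):
        rng = np.random.default_rng(5)
        design = rng.normal(size=(50, 3))
        design = np.column_stack([design, design[:, 0]])  # duplicated column
        data = rng.normal(size=(50, 2))
        with pytest.warns(UserWarning, match="rank deficient"):
            resid = regress_nuisance(data, design)
        assert np.abs(design.T @ resid).max() / 50 < 1e-8


class TestBandpass:
    def _tone(self, freq_hz, tr=2.0, n=600):
        t = np.arange(n) * tr
        return np.sin(2 * np.pi * freq_hz * t)

    def _amplitude_ratio(self, freq_hz, tr=2.0):
        """FFT-oracle amplitude at the tone frequency, after vs before."""
        x = self._tone(freq_hz, tr)[:, None]
        y = bandpass(x, tr)[:, 0]
        f = np.fft.rfftfreq(x.shape[0], d=tr)
        k = np.argmin(np.abs(f - freq_hz))
        return np.abs(np.fft.rfft(y))[k] / np.abs(np.fft.rfft(x[:, 0]))[k]

    def test_passband_tone_preserved(self):
        assert self._amplitude_ratio(0.05) >= 0.95

    def test_stopband_tone_attenuated(self):
        assert self._amplitude_ratio(0.2) <= 0.10

    def test_constant_series_removed(self):
        x = np.full((200, 2), 7.0)
        y = bandpass(x, 2.0)
        assert np.abs(y).max() < 1e-6 * 7.0

    def test_incompatible_band_rejected(self):
        with pytest.raises(ValueError, match="incompatible|Nyquist"):
            bandpass(np.zeros((100, 1)), tr=10.0)  # Nyquist 0.05 < 0.1


class TestPreprocessorPipeline:
    def test_clean_discards_initial_and_scrubs(self, small_config, two_networks):
        from recovnet.synthetic import generate_patient

        series, _, _ = generate_patient(small_config, two_networks,
                                        timepoints=("w2",), seed=9)
        ts = series["w2"]
        cfg = Preprocessor(min_volumes=50)
        cleaned = cfg.clean(ts)
        assert cleaned.n_volumes <= ts.n_volumes - 10
        assert cleaned.kept_volumes is not None
        assert cleaned.node_ids == ts.node_ids

    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        p = Preprocessor(fd_threshold_mm=0.4)
        assert clone(p).get_params()["fd_threshold_mm"] == 0.4
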