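import numpy as np
import pytest
from scipy import signal

from restgraph.core import CensorMask, MotionTrace, RoiTimeSeries
from restgraph.preprocess import (
    PreprocessParams,
    bandpass_censored,
    censor_volumes,
    check_inclusion,
    framewise_displacement,
    preprocess_subject,
    regress_and_detrend,
)
from restgraph.synthetic import plant_covariance

from oracles import inclusion_any_window


def trace(translations, rotations):
    return MotionTrace(np.asarray(translations, float), np.asarray(rotations, float))


def still_trace(t=10):
    return trace(np.zeros((t, 3)), np.zeros((t, 3)))


class TestFramewiseDisplacement:
    def test_zero_motion_gives_zero_fd(self):
        assert framewise_displacement(still_trace()).max() == 0.0

    def test_unit_translation_step_gives_fd_one(self):
        tr = np.zeros((5, 3))
        tr[2:, 0] = 1.0  # 1 mm step at volume 2
        fd = framewise_displacement(trace(tr, np.zeros((5, 3))))
        assert fd[2] == pytest.approx(1.0)
        assert fd[[0, 1, 3, 4]].max() == 0.0

    def test_rotation_scaled_by_head_radius(self):
        # 0.02 rad * 50 mm = 1 mm displacement on the assumed sphere
        rot = np.zeros((5, 3))
        rot[3:, 1] = 0.02
        fd = framewise_displacement(trace(np.zeros((5, 3)), rot))
        assert fd[3] == pytest.approx(1.0)

    def test_invariant_to_constant_parameter_offset(self, rng):
        tr = rng.normal(size=(50, 3))
        rot = rng.normal(scale=0.01, size=(50, 3))
        fd = framewise_displacement(trace(tr, rot))
        fd_shifted = framewise_displacement(trace(tr + 3.7, rot - 0.2))
        np.testing.assert_allclose(fd, fd_shifted, atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            MotionTrace(np.zeros((1, 3)), np.zeros((1, 3)))


class TestCensoring:
    def test_clean_trace_censors_nothing(self):
        mask = censor_volumes(still_trace())
        assert mask.n_censored == 0

    def test_run_translation_excursion_flags_that_volume(self):
        tr = np.zeros((6, 3))
        tr[3, 0] = 1.5
        mask = censor_volumes(trace(tr, np.zeros((6, 3))))
        assert "run_translation" in mask.reasons[3]
        # the 1.5 mm jump in and back out also trips the FD rule twice
        assert "fd" in mask.reasons[3] and mask.reasons[4] == ("fd",)
        assert not mask.censored[[0, 1, 2, 5]].any()

    def test_spike_and_return_hit_both_rules(self):
        # 1.2 mm excursion at volume 2, back at volume 3: the spike violates
        # both the run-translation and FD rules, the return only FD.
        tr = np.zeros((5, 3))
        tr[2, 0] = 1.2
        mask = censor_volumes(trace(tr, np.zeros((5, 3))))
        assert set(mask.reasons[2]) == {"run_translation", "fd"}
        assert set(mask.reasons[3]) == {"fd"}
        assert not mask.censored[[0, 1, 4]].any()

    def test_rotation_threshold_is_in_degrees(self):
        rot = np.zeros((4, 3))
        rot[1, 2] = np.deg2rad(1.5)  # 1.5 degrees > 1 degree limit
        mask = censor_volumes(trace(np.zeros((4, 3)), rot))
        assert "run_rotation" in mask.reasons[1]

    def test_monotone_in_thresholds(self, rng):
        tr = rng.normal(scale=0.6, size=(80, 3))
        rot = rng.normal(scale=0.006, size=(80, 3))
        m = trace(tr, rot)
        loose = censor_volumes(m, PreprocessParams())
        tight = censor_volumes(
            m, PreprocessParams(run_translation_limit=0.5, run_rotation_limit=0.5, fd_limit=0.5)
        )
        # lowering limits never un-censors a volume
        assert np.all(tight.censored | ~loose.censored)


class TestInclusion:
    def test_clean_run_included(self):
        report = check_inclusion(CensorMask.clean(250), tr=1.8)
        assert report.included and report.best_fraction == 0.0

    def test_alternating_censoring_excluded(self):
        censored = np.arange(250) % 2 == 0
        mask = CensorMask(censored, [("fd",) if c else () for c in censored])
        report = check_inclusion(mask, tr=1.8)
        assert not report.included

    def test_clean_tail_window_qualifies(self):
        censored = np.zeros(250, dtype=bool)
        censored[:100] = np.arange(100) % 2 == 0  # heavy censoring up front
        mask = CensorMask(censored, [("fd",) if c else () for c in censored])
        report = check_inclusion(mask, tr=1.8)
        assert report.included
        start, stop = report.best_window
        # minimum admissible window is ceil(300/1.8) = 167 volumes, so the
        # best window ends at the clean tail and may only reach a few
        # censored head frames
        assert stop == 250 and stop - start >= 167
        assert report.best_fraction <= 0.1

    def test_run_shorter_than_interval_excluded_with_reason(self):
        report = check_inclusion(CensorMask.clean(100), tr=1.8)
        assert not report.included and "shorter" in report.reason

    def test_matches_any_window_oracle_on_random_masks(self, rng):
        params = PreprocessParams()
        for _ in range(60):
            t = int(rng.integers(170, 260))
            censored = rng.random(t) < rng.uniform(0.02, 0.25)
            mask = CensorMask(censored, [("fd",) if c else () for c in censored])
            got = check_inclusion(mask, tr=1.8, params=params).included
            window = int(np.ceil(params.min_interval / 1.8))
            expected = inclusion_any_window(censored, window, params.max_censored_fraction)
            assert got == expected


class TestRegression:
    def _subject(self, rng, t=200):
        nuisance = rng.normal(size=(t, 3))
        motion = trace(rng.normal(scale=0.05, size=(t, 3)), rng.normal(scale=5e-4, size=(t, 3)))
        return nuisance, motion

    def test_wm_signal_fits_perfectly(self, rng):
        nuisance, motion = self._subject(rng)
        ts = RoiTimeSeries(nuisance[:, [0]], tr=1.8)
        resid = regress_and_detrend(ts, motion, nuisance)
        assert np.abs(resid.data).max() < 1e-8

    def test_linear_trend_removed(self, rng):
        nuisance, motion = self._subject(rng)
        t = np.arange(200, dtype=float)
        ts = RoiTimeSeries((3.0 * t + 7.0)[:, None], tr=1.8)
        resid = regress_and_detrend(ts, motion, nuisance)
        assert np.abs(resid.data).max() < 1e-7

    def test_residuals_orthogonal_to_every_regressor(self, rng):
        nuisance, motion = self._subject(rng)
        data = rng.normal(size=(200, 5)) + 0.5 * nuisance[:, [2]]
        ts = RoiTimeSeries(data, tr=1.8)
        resid = regress_and_detrend(ts, motion, nuisance)
        regressors = np.hstack([nuisance, motion.parameters])
        regressors = (regressors - regressors.mean(0)) / regressors.std(0)
        standardized = resid.data / np.abs(resid.data).max()
        assert np.abs(regressors.T @ standardized).max() < 1e-8

    def test_fit_ignores_censored_volumes(self, rng):
        nuisance, motion = self._subject(rng)
        data = rng.normal(size=(200, 2))
        data[50] += 100.0  # a wild censored frame must not leak into the fit
        censored = np.zeros(200, dtype=bool)
        censored[50] = True
        mask = CensorMask(censored, [("fd",) if c else () for c in censored])
        with_spike = regress_and_detrend(RoiTimeSeries(data, 1.8), motion, nuisance, mask)
        clean = data.copy()
        clean[50] -= 100.0
        without = regress_and_detrend(RoiTimeSeries(clean, 1.8), motion, nuisance, mask)
        keep = ~censored
        np.testing.assert_allclose(with_spike.data[keep], without.data[keep], atol=1e-10)

    def test_collinear_design_names_columns(self, rng):
        nuisance, motion = self._subject(rng)
        nuisance[:, 1] = nuisance[:, 0]  # CSF duplicates WM
        ts = RoiTimeSeries(rng.normal(size=(200, 2)), tr=1.8)
        with pytest.raises(ValueError, match="wm|csf"):
            regress_and_detrend(ts, motion, nuisance)


class TestBandpass:
    def _tone(self, freq, tr=1.8, t=500):
        time = np.arange(t) * tr
        return np.sin(2 * np.pi * freq * time)[:, None]

    def test_in_band_tone_preserved(self):
        ts = RoiTimeSeries(self._tone(0.05), tr=1.8)
        out = bandpass_censored(ts)
        mid = slice(100, 400)  # avoid filter edge transients
        ratio = np.ptp(out.data[mid]) / np.ptp(ts.data[mid])
        assert ratio == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_tone_attenuated(self):
        ts = RoiTimeSeries(self._tone(0.2), tr=1.8)
        out = bandpass_censored(ts)
        mid = slice(100, 400)
        assert np.ptp(out.data[mid]) / np.ptp(ts.data[mid]) < 0.1

    def test_constant_series_removed(self):
        ts = RoiTimeSeries(np.full((400, 2), 11.0), tr=1.8)
        out = bandpass_censored(ts)
        assert np.abs(out.data).max() < 1e-6

    def test_band_above_nyquist_rejected(self):
        ts = RoiTimeSeries(self._tone(0.05), tr=1.8)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_censored(ts, band=(0.009, 0.3))

    def test_censored_frames_interpolated_then_reflagged(self):
        ts = RoiTimeSeries(self._tone(0.05), tr=1.8)
        censored = np.zeros(500, dtype=bool)
        censored[200:204] = True
        mask = CensorMask(censored, [("fd",) if c else () for c in censored])
        data = ts.data.copy()
        data[200:204] = 1e4  # garbage at censored frames must not ring through
        out = bandpass_censored(RoiTimeSeries(data, 1.8), mask)
        reference = bandpass_censored(ts)
        assert out.mask is mask
        # the garbage never rings through at its own scale ...
        assert np.abs(out.data).max() < 2.0
        # ... and frames away from the interpolated gap are untouched
        far = np.ones(500, dtype=bool)
        far[140:280] = False  # the 0.009 Hz edge has a ~60-sample response
        assert np.abs(out.data[far] - reference.data[far]).max() < 0.01


def test_full_preprocess_preserves_planted_connectivity(rng):
    """A clean subject's within-module correlation structure survives the
    censor/regress/filter chain (mean |r| changes by < 0.05)."""
    t = 1500  # band-pass filtering shrinks the effective sample size a lot
    cov = plant_covariance((5, 5), 0.6, 0.1)
    data = rng.multivariate_normal(np.zeros(10), cov, size=t)
    ts = RoiTimeSeries(data, tr=1.8)
    motion = trace(rng.normal(scale=0.02, size=(t, 3)), rng.normal(scale=2e-4, size=(t, 3)))
    nuisance = rng.normal(scale=0.05, size=(t, 3))
    filtered, mask, report = preprocess_subject(ts, motion, nuisance)
    assert report.included and mask.n_censored == 0

    def within_mean_abs_r(x):
        r = np.corrcoef(x, rowvar=False)
        block = r[:5, :5][np.triu_indices(5, 1)]
        return np.abs(block).mean()

    before = within_mean_abs_r(data)
    after = within_mean_abs_r(filtered.data)
    assert abs(before - after) < 0.05
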