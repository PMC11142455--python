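"""HRF, task design matrices, regression, band-pass, block extraction, FD."""

import numpy as np
import pytest

from reconfig_swm.conditioning import (SignalConfig, bandpass_detrend_rest,
                                       block_volume_indices, build_task_regressors,
                                       canonical_hrf, compute_fd, condition_task_run,
                                       extract_load_blocks, regress_out, trim_volumes)
from reconfig_swm.core import MotionTrace, RoiTimeSeries
from reconfig_swm.errors import DataError, ParameterError, SchemaError, StructureError


class TestCanonicalHrf:
    def test_peak_location_at_tr2(self):
        # dense-grid oracle: the response gamma's mode is at 6 s, so the
        # TR=2 s kernel peaks at sample index 3
        k = canonical_hrf(2.0)
        assert np.argmax(k) == 3
        dense = canonical_hrf(0.01)
        assert abs(np.argmax(dense) * 0.01 - 6.0) < 0.05

    def test_peak_normalized_and_undershoot(self):
        k = canonical_hrf(2.0)
        assert k.max() == pytest.approx(1.0)
        assert k.min() < 0

    def test_length_shorter_than_peak_rejected(self):
        with pytest.raises(ParameterError):
            canonical_hrf(2.0, length_s=4.0)


class TestTaskRegressors:
    def test_load5_encoding_duration(self, tiny_cohort):
        ev = tiny_cohort[0].events[0].events
        enc5 = ev[(ev["event_type"] == "encoding") & (ev["load"] == 5)]
        assert np.allclose(enc5["duration"], 2.5)  # 5 dots × 0.5 s

    def test_main_and_derivative_pairing(self, tiny_cohort):
        run = tiny_cohort[0]
        T = run.task_runs[0].n_volumes
        design = build_task_regressors(run.events[0], T, 2.0)
        assert design.values.shape[1] == len(design.labels)
        mains = [l for l in design.labels if not l.endswith("_derivative")]
        assert design.values.shape[1] == 2 * len(mains)

    def test_all_correct_run_drops_wrong_column(self, tiny_cohort):
        table = tiny_cohort[0].events[0]
        ev = table.events.copy()
        ev["correct"] = True
        from reconfig_swm.core import TaskEventTable
        T = tiny_cohort[0].task_runs[0].n_volumes
        design = build_task_regressors(TaskEventTable(ev), T, 2.0)
        assert "wrong_trial" in design.dropped
        assert "wrong_trial" not in design.labels

    def test_event_beyond_run_end_rejected(self, tiny_cohort):
        with pytest.raises(StructureError):
            build_task_regressors(tiny_cohort[0].events[0], 10, 2.0)

    def test_derivative_is_first_difference(self, tiny_cohort):
        run = tiny_cohort[0]
        design = build_task_regressors(run.events[0], run.task_runs[0].n_volumes, 2.0)
        i = design.labels.index("maintenance")
        j = design.labels.index("maintenance_derivative")
        main, deriv = design.values[:, i], design.values[:, j]
        np.testing.assert_allclose(deriv, np.diff(main, prepend=main[0]), atol=1e-12)


class TestRegressOut:
    def test_regressor_itself_gives_zero_residual(self, rng):
        x = rng.standard_normal(50)
        ts = RoiTimeSeries("s", "rest", np.column_stack([x, 2 * x + 1]))
        resid = regress_out(ts, x)
        np.testing.assert_allclose(resid.data, 0.0, atol=1e-10)

    def test_intercept_only_mean_centers(self, rng):
        data = rng.standard_normal((40, 3)) + 5.0
        ts = RoiTimeSeries("s", "rest", data)
        resid = regress_out(ts, np.ones((40, 1)))
        np.testing.assert_allclose(resid.data, data - data.mean(axis=0), atol=1e-10)

    def test_linearity_against_projection_oracle(self, rng):
        x = rng.standard_normal(60)
        sig = rng.standard_normal((60, 4))
        ts_a = RoiTimeSeries("s", "rest", sig)
        ts_b = RoiTimeSeries("s", "rest", sig + 3.0 * x[:, None])
        ra = regress_out(ts_a, x).data
        rb = regress_out(ts_b, x).data
        np.testing.assert_allclose(ra, rb, atol=1e-9)

    def test_residual_orthogonal_to_regressors(self, rng):
        X = rng.standard_normal((80, 5))
        ts = RoiTimeSeries("s", "rest", rng.standard_normal((80, 6)))
        resid = regress_out(ts, X).data
        prods = np.abs(X.T @ resid) / (np.linalg.norm(X, axis=0)[:, None]
                                       * np.linalg.norm(resid, axis=0))
        assert prods.max() < 1e-8

    def test_collinear_design_rejected(self, rng):
        x = rng.standard_normal(30)
        with pytest.raises(DataError, match="collinear"):
            regress_out(RoiTimeSeries("s", "rest", rng.standard_normal((30, 2))),
                        np.column_stack([x, 2 * x]))

    def test_near_idempotent(self, rng):
        X = rng.standard_normal((80, 4))
        ts = RoiTimeSeries("s", "rest", rng.standard_normal((80, 3)))
        once = regress_out(ts, X)
        twice = regress_out(once, X)
        assert np.max(np.abs(twice.data - once.data)) < 1e-6 * once.data.std()


class TestBandpassDetrend:
    def test_pure_quadratic_removed(self):
        t = np.arange(200)
        data = np.column_stack([3 + 0.1 * t - 0.002 * t**2] * 2)
        out = bandpass_detrend_rest(RoiTimeSeries("s", "rest", data))
        assert out.data.var() < 1e-6 * data.var()

    @pytest.mark.parametrize("freq,kept", [(0.05, True), (0.2, False)])
    def test_band_edges_fft_amplitude_oracle(self, freq, kept):
        tr, T = 2.0, 400
        t = np.arange(T) * tr
        sig = np.sin(2 * np.pi * freq * t)
        out = bandpass_detrend_rest(
            RoiTimeSeries("s", "rest", sig[:, None])).data[:, 0]
        amp_in = np.abs(np.fft.rfft(sig))
        amp_out = np.abs(np.fft.rfft(out))
        k = np.argmax(amp_in)
        ratio = amp_out[k] / amp_in[k]
        assert (ratio >= 0.9) if kept else (ratio <= 0.1)

    def test_invalid_band_rejected(self):
        cfg = SignalConfig(band_hz=(0.1, 0.4))  # high edge above Nyquist at TR=2
        with pytest.raises(ParameterError):
            bandpass_detrend_rest(
                RoiTimeSeries("s", "rest", np.random.default_rng(0)
                              .standard_normal((50, 2))), cfg)

    def test_near_idempotent(self, rng):
        ts = RoiTimeSeries("s", "rest", rng.standard_normal((200, 3)))
        once = bandpass_detrend_rest(ts)
        twice = bandpass_detrend_rest(once)
        assert np.max(np.abs(twice.data - once.data)) < 1e-6 * once.data.std()


class TestBlockExtraction:
    def test_volume_count_matches_interval_arithmetic(self, tiny_cohort):
        rec = tiny_cohort[0]
        runs = [trim_volumes(r) for r in rec.task_runs]
        for load in (1, 3, 5):
            out = extract_load_blocks(runs, rec.events, load)
            expected = 0
            for run, ev in zip(runs, rec.events):
                start, end = ev.block_interval(load)
                mid = (np.arange(run.n_volumes) + 0.5) * 2.0
                expected += int(((mid >= start) & (mid <= end)).sum())
            assert out.n_volumes == expected

    def test_baseline_volumes_never_included(self, tiny_cohort):
        rec = tiny_cohort[0]
        run = trim_volumes(rec.task_runs[0])
        ev = rec.events[0]
        baselines = ev.events[ev.events["event_type"] == "baseline"]
        picked = {load: set(block_volume_indices(ev, run.n_volumes, 2.0, load))
                  for load in (1, 3, 5)}
        all_picked = set().union(*picked.values())
        for _, row in baselines.iterrows():
            mids = (np.arange(run.n_volumes) + 0.5) * 2.0
            inside = np.flatnonzero((mids > row["onset"])
                                    & (mids < row["onset"] + row["duration"]))
            assert not (set(inside) & all_picked)

    def test_two_runs_contribute_two_segments(self, tiny_cohort):
        rec = tiny_cohort[0]
        runs = [trim_volumes(r) for r in rec.task_runs]
        both = extract_load_blocks(runs, rec.events, 3)
        solo = extract_load_blocks(runs[:1], rec.events[:1], 3)
        assert both.n_volumes > solo.n_volumes

    def test_missing_load_raises(self, tiny_cohort):
        rec = tiny_cohort[0]
        with pytest.raises(StructureError):
            trimmed = [trim_volumes(r) for r in rec.task_runs]
            extract_load_blocks(trimmed, rec.events, 7)


class TestFramewiseDisplacement:
    def test_constant_parameters_zero_fd(self):
        out = compute_fd(np.ones((10, 6)))
        np.testing.assert_array_equal(out.fd, 0.0)
        assert out.mean_fd == 0.0

    def test_unit_translation_step(self):
        params = np.zeros((10, 6))
        params[4:, 0] = 1.0
        out = compute_fd(params)
        assert out.fd[3] == pytest.approx(1.0)
        assert np.count_nonzero(out.fd) == 1

    def test_rotation_contribution_scaled_by_radius(self):
        params = np.zeros((5, 6))
        params[2:, 3] = 0.01
        out = compute_fd(params)
        assert out.fd[1] == pytest.approx(0.5)  # 50 mm × 0.01 rad

    def test_wrong_parameter_count_rejected(self):
        with pytest.raises(SchemaError):
            compute_fd(np.zeros((10, 5)))

    def test_max_abs_displacement_euclidean_from_reference(self):
        params = np.zeros((4, 6))
        params[2, :3] = (3.0, 4.0, 0.0)
        assert compute_fd(params).max_abs_displacement == pytest.approx(5.0)


class TestTaskConditioning:
    def test_joint_residual_orthogonal_to_design(self, tiny_cohort):
        rec = tiny_cohort[0]
        resid, _, design = condition_task_run(
            rec.task_runs[0], rec.events[0], rec.motion["task_run1"])
        X = design.values
        corr = np.abs(X.T @ resid.data) / (
            np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(resid.data, axis=0))
        assert corr.max() < 1e-8
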