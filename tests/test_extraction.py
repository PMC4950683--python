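"""Baseline-block cutting, concatenation and task regression."""

import math

import numpy as np
import pytest

import restex as rx
from restex.design import Event
from restex.extraction import shifted_baseline_windows

from conftest import make_confounds


def _volumes(start_s, end_s, tr, n_volumes):
    """Independent seconds-to-volume arithmetic used as the oracle."""
    a = max(0, math.ceil(start_s / tr - 1e-9))
    b = min(n_volumes, math.floor(end_s / tr + 1e-9))
    return (a, b) if b > a else None


class TestSegmentsFixed:
    def test_rft_retains_less_than_thirty_seconds(self, rft):
        seg = rx.segments_fixed(rft)
        assert 0 < seg.total_seconds < 30.0

    def test_rft_retention_under_alternative_reading(self, rft):
        seg = rx.segments_fixed(rft, pre_extension_mode="baseline_head")
        assert seg.total_seconds < 30.0

    def test_isolated_baseline_fully_retained(self):
        d = rx.TaskDesign(events=(Event("baseline", 0.0, 30.0),), tr=1.0, n_volumes=30)
        seg = rx.segments_fixed(d)
        assert seg.intervals == ((0, 30),)

    def test_short_inter_task_baseline_dropped(self):
        # 12 s baseline between tasks cannot survive a 15 s post-gap
        d = rx.TaskDesign(
            events=(
                Event("a", 0.0, 10.0),
                Event("baseline", 10.0, 12.0),
                Event("a", 22.0, 10.0),
            ),
            tr=1.0,
            n_volumes=32,
        )
        seg = rx.segments_fixed(d, pre_extension=0.0)
        assert seg.intervals == ()

    def test_edt_intervals_match_hand_application(self, edt):
        """Apply the cutting rule by hand to the printed block grid."""
        windows = [(0.0, 25.0)]  # leading baseline: no cut, extends 5 s into task 1
        for k in range(7):  # interior baselines at 40, 80, ..., 280 s
            onset = 40.0 + 40.0 * k
            windows.append((onset + 15.0, onset + 25.0))
        windows.append((335.0, 340.0))  # trailing baseline: post-gap cut only
        expected = tuple(
            iv
            for iv in (_volumes(a, b, edt.tr, edt.n_volumes) for a, b in windows)
            if iv is not None
        )
        assert rx.segments_fixed(edt).intervals == expected

    def test_design_without_baseline_rejected(self):
        d = rx.TaskDesign(events=(Event("a", 0.0, 10.0),), tr=1.0, n_volumes=10)
        with pytest.raises(ValueError, match="baseline"):
            rx.segments_fixed(d)


class TestSegmentsVar:
    def test_zero_shift_reproduces_baseline_blocks(self, edt):
        seg = rx.segments_var(edt, 0.0)
        expected = tuple(
            _volumes(a, b, edt.tr, edt.n_volumes)
            for a, b in edt.baseline_periods()
        )
        assert seg.intervals == expected

    def test_shifted_window_arithmetic(self):
        # 20 s baseline at onset 20 s shifted by 4 TRs (5.6 s): [25.6, 45.6) s
        tr = 1.4
        d = rx.TaskDesign(
            events=(Event("task", 0.0, 20.0), Event("baseline", 20.0, 20.0)),
            tr=tr,
            n_volumes=36,
        )
        windows = shifted_baseline_windows(d, 4 * tr)
        assert windows[0] == (pytest.approx(25.6), pytest.approx(45.6))
        seg = rx.segments_var(d, 4 * tr)
        assert seg.intervals[0] == _volumes(25.6, 45.6, tr, 36)

    def test_final_window_truncated_at_run_end(self, edt):
        shift_s = 5 * edt.tr
        windows = shifted_baseline_windows(edt, shift_s)
        last = windows[-1]
        assert last[1] == pytest.approx(edt.duration)
        assert last[1] - last[0] < 20.0


class TestConcatenateRun:
    def test_whole_run_segments_are_identity(self, tiny_run, tiny_confounds):
        seg = rx.SegmentList(
            intervals=((0, tiny_run.n_volumes),), tr=tiny_run.tr
        )
        out = rx.concatenate_run(tiny_run, tiny_confounds, seg, min_duration_s=0)
        assert np.array_equal(out.run.data, tiny_run.data)
        assert np.array_equal(out.confounds.motion, tiny_confounds.motion)

    def test_empty_segment_list_rejected(self, tiny_run, tiny_confounds):
        seg = rx.SegmentList(intervals=(), tr=tiny_run.tr)
        with pytest.raises(rx.InsufficientDataError):
            rx.concatenate_run(tiny_run, tiny_confounds, seg, min_duration_s=0)

    def test_two_intervals_gather_values_in_order(self, tiny_run, tiny_confounds):
        seg = rx.SegmentList(intervals=((3, 8), (20, 26)), tr=tiny_run.tr)
        out = rx.concatenate_run(tiny_run, tiny_confounds, seg, min_duration_s=0)
        idx = np.r_[3:8, 20:26]
        assert np.array_equal(out.run.data, tiny_run.data[..., idx])
        assert np.array_equal(
            out.confounds.global_signal, tiny_confounds.global_signal[idx]
        )
        assert out.retained_seconds == pytest.approx(len(idx) * tiny_run.tr)

    def test_minimum_duration_enforced_with_method_name(self, tiny_run, tiny_confounds):
        seg = rx.SegmentList(intervals=((0, 4),), tr=tiny_run.tr)
        with pytest.raises(rx.InsufficientDataError, match="BLOCK"):
            rx.concatenate_run(
                tiny_run, tiny_confounds, seg, min_duration_s=30, method="BLOCK"
            )


class TestOlsResiduals:
    def test_channel_equal_to_regressor_vanishes(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((50, 2))
        resid = rx.ols_residuals(x[:, :1], x)
        assert np.allclose(resid, 0.0, atol=1e-10)

    def test_intercept_only_mean_centres(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal((40, 3)) + 5.0
        resid = rx.ols_residuals(y, np.empty((40, 0)))
        assert np.allclose(resid, y - y.mean(axis=0), atol=1e-10)

    def test_residuals_orthogonal_to_regressors(self):
        """Normal-equations oracle: X'e = 0 for every channel."""
        rng = np.random.default_rng(3)
        y = rng.standard_normal((80, 10))
        x = rng.standard_normal((80, 4))
        resid = rx.ols_residuals(y, x)
        assert np.max(np.abs(x.T @ resid)) < 1e-8
        assert np.max(np.abs(resid.sum(axis=0))) < 1e-8  # intercept too

    def test_collinear_columns_reported(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal((30, 2))
        x = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            rx.ols_residuals(rng.standard_normal((30, 2)), x)


class TestApplyMethod:
    @pytest.fixture()
    def edt_subject(self, truth8, edt, edt_task_runs):
        run, conf = edt_task_runs["sub-03"]
        roi = truth8.network_masks["occipital"]
        from restex.pipeline import _estimate_subject_shift

        shift = _estimate_subject_shift(run, edt, roi)
        return run, conf, shift

    def test_orig_is_identity(self, edt_subject, edt):
        run, conf, _ = edt_subject
        out = rx.apply_method("ORIG", run, conf, design=edt)
        assert out.retained_seconds == pytest.approx(run.duration)
        assert out.run is run

    def test_reg_perfect_fit_leaves_zero_residuals(self, edt):
        reg = rx.convolve_regressor(
            rx.boxcar(edt, "emotion"), rx.canonical_hrf(tr=edt.tr)
        ).values
        data = np.tile(reg, (2, 2, 1, 1))
        run = rx.BoldRun(data=data, tr=edt.tr, mask=np.ones((2, 2, 1), bool))
        conf = make_confounds(edt.n_volumes)
        out = rx.apply_method("REG", run, conf, design=edt)
        assert np.allclose(out.run.data, 0.0, atol=1e-8)

    def test_reg_residuals_uncorrelated_with_task(self, edt_subject, edt):
        run, conf, _ = edt_subject
        out = rx.apply_method("REG", run, conf, design=edt)
        series = out.run.timeseries()
        kernel = rx.canonical_hrf(tr=edt.tr)
        for label in edt.task_labels:
            reg = rx.convolve_regressor(rx.boxcar(edt, label), kernel).values
            reg_c = reg - reg.mean()
            centred = series - series.mean(axis=0)
            r = reg_c @ centred / (
                np.linalg.norm(reg_c) * np.linalg.norm(centred, axis=0)
            )
            assert np.max(np.abs(r)) < 0.01

    def test_blockreg_composes_regression_then_concatenation(
        self, edt_subject, edt
    ):
        run, conf, shift = edt_subject
        combined = rx.apply_method("BLOCKREG", run, conf, design=edt, shift=shift)
        manual_reg = rx.apply_method("REG", run, conf, design=edt)
        manual = rx.concatenate_run(
            manual_reg.run, conf, rx.segments_var(edt, shift), method="BLOCKREG"
        )
        assert np.array_equal(combined.run.data, manual.run.data)
        assert np.array_equal(combined.confounds.motion, manual.confounds.motion)

    def test_duration_ordering_on_edt(self, edt_subject, edt):
        run, conf, shift = edt_subject
        durations = {
            m: rx.apply_method(m, run, conf, design=edt, shift=shift).retained_seconds
            for m in rx.METHODS
        }
        assert durations["ORIG"] == durations["REG"]
        assert durations["REG"] >= durations["BLOCKVAR"] >= durations["BLOCK"]

    def test_block_insufficient_on_rft(self, truth8, rft):
        run, conf = rx.generate_subject(rft, truth8, "sub-01", "task", run_label="RFT")
        with pytest.raises(rx.InsufficientDataError, match="insufficient|below"):
            rx.apply_method("BLOCK", run, conf, design=rft)

    def test_unknown_method_rejected(self, tiny_run, tiny_confounds):
        with pytest.raises(ValueError, match="unknown method"):
            rx.apply_method("FOO", tiny_run, tiny_confounds)

    def test_blockvar_requires_shift(self, tiny_run, tiny_confounds, edt):
        with pytest.raises(ValueError, match="shift"):
            rx.apply_method("BLOCKVAR", tiny_run, tiny_confounds, design=edt)
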