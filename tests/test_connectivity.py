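"""Nuisance regression, band-pass filtering and seed correlation maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import restex as rx
from restex.design import rest_design
from restex.extraction import ExtractionResult

from conftest import make_confounds


def _run_from_series(series, tr=1.4):
    """Pack a (time, voxel) matrix into a 1-D-masked run."""
    n_t, n_v = series.shape
    data = np.zeros((n_v, 1, 1, n_t))
    data[:, 0, 0, :] = series.T
    return rx.BoldRun(data=data, tr=tr, mask=np.ones((n_v, 1, 1), bool))


class TestNuisanceRegress:
    def test_voxel_equal_to_global_removed_with_gsr(self):
        conf = make_confounds(60, seed=8)
        series = np.column_stack([conf.global_signal, conf.white_matter])
        run = _run_from_series(series)
        out = rx.nuisance_regress(run, conf, use_gsr=True)
        assert np.allclose(out.timeseries(), 0.0, atol=1e-10)

    def test_global_voxel_survives_without_gsr(self):
        # global built orthogonal to the other confounds so OLS cannot
        # remove it indirectly
        rng = np.random.default_rng(9)
        base = rng.standard_normal((60, 8))
        q, _ = np.linalg.qr(np.column_stack([np.ones(60), base, rng.standard_normal(60)]))
        conf = rx.ConfoundSet(
            motion=q[:, 1:7],
            white_matter=q[:, 7],
            csf=q[:, 8],
            global_signal=q[:, 9],
        )
        run = _run_from_series(np.column_stack([conf.global_signal] * 2))
        out = rx.nuisance_regress(run, conf, use_gsr=False)
        kept = out.timeseries()[:, 0]
        r = np.corrcoef(kept, conf.global_signal)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-8)

    def test_zero_confound_columns_rejected(self, tiny_run):
        n = tiny_run.n_volumes
        conf = rx.ConfoundSet(
            motion=np.zeros((n, 6)),
            white_matter=np.zeros(n),
            csf=np.zeros(n),
            global_signal=np.zeros(n),
        )
        with pytest.raises(ValueError, match="collinear"):
            rx.nuisance_regress(tiny_run, conf, use_gsr=True)

    def test_length_mismatch_rejected(self, tiny_run):
        with pytest.raises(ValueError, match="length"):
            rx.nuisance_regress(tiny_run, make_confounds(tiny_run.n_volumes + 1), True)


class TestBandpass:
    @pytest.mark.parametrize(
        "freq,bound,above",
        [(0.04, 0.9, True), (0.2, 0.1, False)],
    )
    def test_power_ratio_by_fft_oracle(self, freq, bound, above):
        tr = 1.4
        t = np.arange(256) * tr
        series = np.sin(2 * np.pi * freq * t)[:, None]
        out = rx.bandpass(_run_from_series(series, tr)).timeseries()[:, 0]
        ratio = np.sum(out**2) / np.sum(series[:, 0] ** 2)
        if above:
            assert ratio > bound
        else:
            assert ratio < bound

    def test_constant_series_zeroed(self):
        series = np.full((64, 1), 3.0)
        out = rx.bandpass(_run_from_series(series)).timeseries()
        assert np.allclose(out, 0.0, atol=1e-8)

    def test_too_short_run_rejected_with_minimum_named(self):
        series = np.random.default_rng(0).standard_normal((8, 1))
        with pytest.raises(ValueError, match="12"):
            rx.bandpass(_run_from_series(series))

    def test_invalid_band_rejected(self, tiny_run):
        with pytest.raises(ValueError, match="Nyquist"):
            rx.bandpass(tiny_run, 0.01, 0.5)


class TestSeedTimecourse:
    def test_uniform_volume_returns_shared_series(self):
        series = np.tile(np.sin(np.arange(30.0)), (27, 1))
        data = series.reshape(3, 3, 3, 30)
        run = rx.BoldRun(data=data, tr=1.4, mask=np.ones((3, 3, 3), bool))
        assert np.allclose(rx.seed_timecourse(run, (1, 1, 1)), np.sin(np.arange(30.0)))

    def test_cube_mean_matches_direct_average(self, tiny_run):
        ts = rx.seed_timecourse(tiny_run, (1, 1, 1))
        oracle = tiny_run.data[0:3, 0:3, 0:3].reshape(27, -1).mean(axis=0)
        assert np.allclose(ts, oracle)

    def test_corner_center_rejected(self, tiny_run):
        with pytest.raises(ValueError, match="bounds"):
            rx.seed_timecourse(tiny_run, (0, 0, 0))


class TestCorrelationZmap:
    def test_identical_voxel_hits_clip_value(self):
        rng = np.random.default_rng(3)
        seed_ts = rng.standard_normal(50)
        series = np.column_stack([seed_ts, rng.standard_normal(50)])
        zmap = rx.correlation_zmap(_run_from_series(series), seed_ts)
        assert zmap.masked()[0] == pytest.approx(np.arctanh(1 - 1e-7))

    def test_orthogonal_voxel_near_zero(self):
        t = np.arange(64.0)
        seed_ts = np.sin(2 * np.pi * t / 16)
        series = np.column_stack([np.cos(2 * np.pi * t / 16)])
        zmap = rx.correlation_zmap(_run_from_series(series), seed_ts)
        assert abs(zmap.masked()[0]) < 1e-10

    def test_antisymmetric_under_negation(self):
        rng = np.random.default_rng(4)
        seed_ts = rng.standard_normal(50)
        series = np.column_stack([seed_ts, -seed_ts, rng.standard_normal(50)])
        z = rx.correlation_zmap(_run_from_series(series), seed_ts).masked()
        assert z[1] == pytest.approx(-z[0])

    def test_constant_seed_rejected(self, tiny_run):
        with pytest.raises(ValueError, match="constant"):
            rx.correlation_zmap(tiny_run, np.ones(tiny_run.n_volumes))

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.integers(0, 2**31 - 1))
    def test_invariant_under_positive_affine_voxel_rescaling(self, a, b, seed):
        rng = np.random.default_rng(seed)
        seed_ts = rng.standard_normal(40)
        series = rng.standard_normal((40, 5))
        base = rx.correlation_zmap(_run_from_series(series), seed_ts).masked()
        scaled = rx.correlation_zmap(
            _run_from_series(a * series + b), seed_ts
        ).masked()
        assert np.allclose(base, scaled, atol=1e-8)


@pytest.fixture(scope="module")
def rest_extraction(truth8):
    run, conf = rx.generate_subject(
        rest_design(360), truth8.zeroed(), "sub-01", "rest"
    )
    return ExtractionResult(
        run=run, confounds=conf, method="ORIG", retained_seconds=run.duration
    )


class TestRunConnectivity:
    def test_one_map_per_seed_and_deterministic(self, truth8, rest_extraction):
        seeds = {
            name: truth8.seed_voxel(name)
            for name in ("default_mode", "cuneus", "thalamus")
        }
        maps = rx.run_connectivity(rest_extraction, seeds, use_gsr=True)
        again = rx.run_connectivity(rest_extraction, seeds, use_gsr=True)
        assert set(maps) == set(seeds)
        for name in seeds:
            assert np.array_equal(maps[name].z_values, again[name].z_values)

    def test_seed_network_stands_out(self, truth8, rest_extraction):
        name = "default_mode"
        maps = rx.run_connectivity(
            rest_extraction, {name: truth8.seed_voxel(name)}, use_gsr=True
        )
        z = maps[name].z_values
        inside = z[truth8.network_masks[name]].mean()
        outside = z[~truth8.network_masks[name] & maps[name].mask].mean()
        assert inside > outside + 0.5

    def test_stage_order_is_observable(self, truth8, rest_extraction):
        """Regress-then-filter differs from filter-then-regress; the
        pipeline is pinned to the former."""
        extraction = rest_extraction
        pipeline = rx.run_connectivity(
            extraction, {"default_mode": truth8.seed_voxel("default_mode")}, True
        )["default_mode"]
        regressed = rx.nuisance_regress(extraction.run, extraction.confounds, True)
        filtered = rx.bandpass(regressed)
        manual = rx.correlation_zmap(
            filtered, rx.seed_timecourse(filtered, truth8.seed_voxel("default_mode"))
        )
        assert np.allclose(pipeline.z_values, manual.z_values)

        swapped_run = rx.nuisance_regress(
            rx.bandpass(extraction.run), extraction.confounds, True
        )
        swapped = rx.correlation_zmap(
            swapped_run,
            rx.seed_timecourse(swapped_run, truth8.seed_voxel("default_mode")),
        )
        assert not np.allclose(pipeline.z_values, swapped.z_values)

    def test_too_short_extraction_rejected(self, tiny_confounds):
        rng = np.random.default_rng(1)
        run = _run_from_series(rng.standard_normal((8, 3)))
        ex = ExtractionResult(
            run=run,
            confounds=make_confounds(8),
            method="BLOCK",
            retained_seconds=run.duration,
        )
        with pytest.raises(ValueError, match="short"):
            rx.run_connectivity(ex, {"n": (1, 0, 0)}, True)
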