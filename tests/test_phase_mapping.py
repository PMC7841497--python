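"""Detector, wavefront, tracking and scale-transform tests, anchored to
the brute-force winding oracle in conftest."""

import numpy as np
import pytest
from conftest import brute_force_ps, loop_charge, random_defect_frame

from fibrenew import phase_mapping as pm
from fibrenew import renewal_stats as rs
from fibrenew import synthetic_data as sd
from fibrenew.types import (
    MMInfParams,
    ParameterError,
    PSDetection,
    SpiralDefect,
    SpiralScript,
    TrackConfig,
)


def _atan_frame(shape, x0, y0, sign=+1):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return sign * np.arctan2(yy - y0, xx - x0)


class TestKernelDetector:
    def test_unit_winding_field(self):
        dets = pm.detect_ps_kernel(_atan_frame((16, 16), 7.3, 8.6))
        assert len(dets) == 1
        d = dets[0]
        assert (abs(d.x - 7.3) < 1 and abs(d.y - 8.6) < 1)
        assert d.chirality == +1

    def test_constant_phase_no_detections(self):
        assert pm.detect_ps_kernel(np.full((8, 8), 0.7)) == []

    def test_opposite_pair_sums_to_zero(self):
        frame = _atan_frame((24, 24), 6.4, 6.2) - _atan_frame((24, 24), 17.6, 17.1)
        frame = np.angle(np.exp(1j * frame))
        dets = pm.detect_ps_kernel(frame)
        assert len(dets) == 2
        assert sum(d.chirality for d in dets) == 0
        oracle = brute_force_ps(frame)
        assert sorted((d.x, d.y, d.chirality) for d in dets) == sorted(oracle)

    def test_matches_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            frame, _truth = random_defect_frame(rng)
            dets = pm.detect_ps_kernel(frame)
            oracle = brute_force_ps(frame)
            assert sorted((d.x, d.y, d.chirality) for d in dets) == sorted(oracle)

    def test_masked_plaquettes_skipped(self):
        frame = _atan_frame((16, 16), 7.3, 8.6)
        mask = np.ones((16, 16), dtype=bool)
        mask[7:10, 6:9] = False  # cover the defect
        assert pm.detect_ps_kernel(frame, mask=mask) == []

    def test_fully_masked_frame_is_empty_not_error(self):
        frame = _atan_frame((8, 8), 3.5, 3.5)
        assert pm.detect_ps_kernel(frame, mask=np.zeros((8, 8), bool)) == []


class TestDoubleRingDetector:
    def test_agrees_with_kernel_on_planted_fixtures(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            frame, truth = random_defect_frame(rng)
            k = pm.detect_ps_kernel(frame)
            r = pm.detect_ps_double_ring(frame)
            assert len(k) == len(r) == len(truth)
            for dk in k:
                near = [dr for dr in r
                        if np.hypot(dr.x - dk.x, dr.y - dk.y) <= 1.5]
                assert len(near) == 1 and near[0].chirality == dk.chirality

    def test_constant_phase_no_detections(self):
        assert pm.detect_ps_double_ring(np.zeros((9, 9))) == []

    def test_near_boundary_defect_not_reported(self):
        # outer ring incomplete within 2 px of the edge: documented blind spot
        frame = _atan_frame((16, 16), 1.2, 8.0)
        dets = pm.detect_ps_double_ring(frame)
        assert all(d.x >= 2 for d in dets)


class TestWavefronts:
    def test_plane_wave_single_straight_isoline(self):
        # wavelength exceeds the domain, so exactly one zero-phase line
        xx = np.arange(24, dtype=float)
        frame = np.tile(0.26 * (xx - 12.0), (24, 1))
        frame = np.angle(np.exp(1j * frame))
        fronts = pm.extract_wavefronts(frame)
        assert len(fronts) == 1
        xs = fronts[0].polyline[:, 0]
        np.testing.assert_allclose(xs, 12.0, atol=0.01)

    def test_uniform_nonzero_phase_has_no_front(self):
        assert pm.extract_wavefronts(np.full((12, 12), np.pi / 2)) == []

    def test_spiral_free_end_terminates_at_singularity(self):
        s = SpiralScript([SpiralDefect(0, 1, np.array([11.3, 12.6]), +1)],
                         n_frames=1)
        movie, _ = sd.make_spiral_phase_movie(s, (24, 24))
        frame = movie.values[0]
        [ps] = pm.detect_ps_kernel(frame)
        fronts = pm.extract_wavefronts(frame)
        ends = [e for f in fronts for e in f.endpoints]
        assert ends, "spiral wavefront must have an interior free end"
        d = min(np.hypot(ex - ps.x, ey - ps.y) for ex, ey in ends)
        assert d <= 2.0

    def test_identically_zero_frame_rejected(self):
        with pytest.raises(ParameterError):
            pm.extract_wavefronts(np.zeros((8, 8)))


def _static_detection_stream(n_frames, positions, chiralities=None):
    chiralities = chiralities or [1] * len(positions)
    return [
        [PSDetection(f, x, y, q) for (x, y), q in zip(positions, chiralities)]
        for f in range(n_frames)
    ]


class TestTracking:
    def test_lifetime_uses_half_open_convention(self):
        dets = _static_detection_stream(10, [(5.0, 5.0)])
        ev = pm.track_entities(dets, TrackConfig(r=2, r_unit="px", tau_ms=0),
                               dt_ms=10.0)
        assert len(ev) == 1
        rec = ev.records.iloc[0]
        assert rec.onset_ms == 0.0 and rec.offset_ms == 100.0

    def test_single_frame_entity_below_tau_discarded(self):
        dets = [[PSDetection(0, 3.0, 3.0, 1)]] + [[] for _ in range(20)]
        ev = pm.track_entities(dets, TrackConfig(r=2, r_unit="px", tau_ms=10),
                               dt_ms=1.0)
        assert len(ev) == 0

    def test_distant_detections_are_distinct_entities(self):
        dets = _static_detection_stream(50, [(2.0, 2.0), (12.0, 2.0)])
        ev = pm.track_entities(dets, TrackConfig(r=4, r_unit="mm", tau_ms=0),
                               dt_ms=1.0, pixel_mm=1.0)
        assert len(ev) == 2

    def test_chirality_mismatch_blocks_association(self):
        dets = [[PSDetection(0, 5.0, 5.0, +1)], [PSDetection(1, 5.0, 5.0, -1)]]
        ev = pm.track_entities(dets, TrackConfig(r=3, r_unit="px", tau_ms=0),
                               dt_ms=1.0)
        assert len(ev) == 2  # sign cannot flip: two one-frame entities

    def test_censoring_flags_at_epoch_edges(self):
        dets = _static_detection_stream(5, [(4.0, 4.0)])
        ev = pm.track_entities(dets, TrackConfig(r=2, r_unit="px", tau_ms=0),
                               dt_ms=1.0)
        rec = ev.records.iloc[0]
        assert rec.censored_left and rec.censored_right

    def test_greedy_and_optimal_agree_on_easy_streams(self):
        rng = np.random.default_rng(5)
        pos = [(float(rng.uniform(3, 20)), float(rng.uniform(3, 20)))
               for _ in range(3)]
        dets = _static_detection_stream(30, pos)
        for assignment in ("optimal", "greedy"):
            ev = pm.track_entities(
                dets, TrackConfig(r=2, r_unit="px", tau_ms=0,
                                  assignment=assignment), dt_ms=1.0)
            assert len(ev) == 3

    def test_planted_script_round_trip(self, coupled_fixture):
        _params, movie, truth = coupled_fixture
        dets = pm.detect_movie(movie)
        rec = pm.track_entities(dets, TrackConfig(r=3, r_unit="px", tau_ms=0),
                                dt_ms=movie.dt_ms)
        assert len(rec) == len(truth)
        t = truth.records.sort_values(["onset_ms", "x"]).reset_index(drop=True)
        r = rec.records.sort_values(["onset_ms", "x"]).reset_index(drop=True)
        assert np.abs(t.onset_ms - r.onset_ms).max() <= movie.dt_ms
        assert np.abs(t.offset_ms - r.offset_ms).max() <= movie.dt_ms
        assert (t.chirality.values == r.chirality.values).all()

    def test_wavefront_tracking_by_overlap(self):
        # a vertical zero-phase line drifting slowly right: one entity
        frames = []
        for t in range(30):
            xx = np.arange(16, dtype=float)
            phase = np.angle(np.exp(1j * 0.3 * (xx - 8.0 - 0.1 * t)))
            frames.append(np.tile(phase, (16, 1)))
        dets = [pm.extract_wavefronts(f, frame_index=i)
                for i, f in enumerate(frames)]
        ev = pm.track_entities(dets, TrackConfig(r=3, r_unit="px", tau_ms=0),
                               dt_ms=1.0, kind="wavelet")
        assert len(ev) == 1
        assert ev.records.iloc[0].chirality == 0


class TestChargeBookkeeping:
    def test_pair_mode_total_chirality_constant(self):
        script = sd.make_pair_script(3, 40, (32, 32), seed=21)
        movie, _ = sd.make_spiral_phase_movie(script, (32, 32))
        for t in range(movie.n_frames):
            dets = pm.detect_ps_kernel(movie.values[t])
            assert sum(d.chirality for d in dets) == 0
            assert sum(d.chirality for d in dets) == loop_charge(movie.values[t])


class TestScaleTransforms:
    def test_decimate_identity_at_full_shape(self, coupled_fixture):
        _p, movie, _t = coupled_fixture
        out = pm.decimate_and_interpolate(movie, movie.shape)
        np.testing.assert_array_equal(out.values, movie.values)

    def test_decimated_central_defect_still_detected(self):
        s = SpiralScript([SpiralDefect(0, 3, np.array([31.2, 32.4]), +1)],
                         n_frames=3)
        movie, _ = sd.make_spiral_phase_movie(s, (64, 64))
        dec = pm.decimate_and_interpolate(movie, (16, 16), (64, 64))
        dets = pm.detect_ps_kernel(dec.values[0])
        assert len(dets) >= 1
        d = min(dets, key=lambda d: np.hypot(d.x - 31.2, d.y - 32.4))
        assert np.hypot(d.x - 31.2, d.y - 32.4) < 4
        assert d.chirality == +1

    def test_constant_field_survives_any_density(self):
        movie, _ = sd.make_spiral_phase_movie(
            SpiralScript([], n_frames=3, omega=0.0), (16, 16))
        out = pm.decimate_and_interpolate(movie, (4, 4))
        np.testing.assert_allclose(np.ptp(out.values, axis=(1, 2)), 0, atol=1e-9)

    def test_tiny_keep_shape_rejected(self, coupled_fixture):
        _p, movie, _t = coupled_fixture
        with pytest.raises(ParameterError):
            pm.decimate_and_interpolate(movie, (1, 4))

    def test_crop_identity_and_window_validation(self, coupled_fixture):
        _p, movie, _t = coupled_fixture
        out = pm.crop_field(movie, (0, movie.shape[0], 0, movie.shape[1]))
        np.testing.assert_array_equal(out.values, movie.values)
        with pytest.raises(ParameterError):
            pm.crop_field(movie, (5, 5, 0, 4))

    def test_window_excluding_defect_sees_nothing(self):
        s = SpiralScript([SpiralDefect(0, 3, np.array([25.0, 25.0]), +1)],
                         n_frames=3)
        movie, _ = sd.make_spiral_phase_movie(s, (32, 32))
        sub = pm.crop_field(movie, (0, 12, 0, 12))
        assert pm.detect_ps_kernel(sub.values[0]) == []

    def test_detected_count_monotone_in_window_size(self, coupled_fixture):
        _p, movie, _t = coupled_fixture
        counts = []
        for size in (12, 20, 26, 32):
            sub = pm.crop_field(movie, (0, size, 0, size))
            n = sum(len(pm.detect_ps_kernel(sub.values[t]))
                    for t in range(0, sub.n_frames, 25))
            counts.append(n)
        assert counts == sorted(counts)


class TestTrackingSensitivity:
    def test_lambda_estimates_keep_exponential_gof_across_tau_and_r(self):
        """Varying the minimum lifetime tau (5-40 ms) and the association
        radius changes the fitted rates but must not break the
        exponential renewal structure on event-coupled movies."""
        ok = total = 0
        for seed in (3, 11, 29):
            params = MMInfParams(0.03, 0.01, 4000.0, seed=seed)
            events = sd.simulate_mminf_events(params)
            script = sd.script_from_events(events, (32, 32), dt_ms=2.0,
                                           seed=seed)
            movie, _ = sd.make_spiral_phase_movie(script, (32, 32), dt_ms=2.0)
            dets = pm.detect_movie(movie)
            for tau in (5.0, 40.0):
                for r in (2.83, 5.67):
                    ev = pm.track_entities(
                        dets, TrackConfig(r=r, r_unit="px", tau_ms=tau),
                        dt_ms=2.0)
                    inter, life = rs.extract_intervals(ev, shift_ms=tau)
                    for sample in (inter, life):
                        if sample.n >= 20:
                            total += 1
                            ok += rs.fit_exponential(sample).chi2_p > 0.05
        assert total >= 10
        assert ok >= 0.9 * total
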