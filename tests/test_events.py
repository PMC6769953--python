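"""I-VT classification, offscreen detection, and calibration offsets."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialgaze.errors import DataError, EstimationError
from socialgaze.events import (
    CalibrationOffset,
    apply_offset,
    classify_ivt,
    detect_offscreen_looks,
    estimate_offset,
    sample_velocity,
    segment_stream,
)
from socialgaze.gaze_io import GazeSample
from socialgaze.simulate import SimProfile, simulate_gaze
from socialgaze.scenes import build_scene_script

from conftest import DT, make_stream, static_track


class TestSampleVelocity:
    def test_identical_coordinates_give_zero(self, geom):
        s1 = GazeSample(0, 100.0, 100.0, 0, 0)
        s2 = GazeSample(17, 100.0, 100.0, 0, 0)
        assert sample_velocity(s1, s2, geom) == 0.0

    def test_matches_trigonometric_oracle(self, geom):
        # oracle: 10 px horizontal step, pixel pitch from the geometry,
        # angle = atan(displacement / distance), over 16.667 ms
        s1 = GazeSample(0, 640.0, 512.0, 0, 0)
        s2 = GazeSample(17, 650.0, 512.0, 0, 0)
        pitch = geom.screen_mm[0] / geom.screen_px[0]
        expected = math.degrees(math.atan(10 * pitch / 550.0)) / ((17) / 1000.0)
        assert sample_velocity(s1, s2, geom) == pytest.approx(expected, rel=1e-12)

    def test_doubling_dt_halves_velocity(self, geom):
        s1 = GazeSample(0, 0.0, 0.0, 0, 0)
        v1 = sample_velocity(s1, GazeSample(10, 30.0, 40.0, 0, 0), geom)
        v2 = sample_velocity(s1, GazeSample(20, 30.0, 40.0, 0, 0), geom)
        assert v1 == pytest.approx(2 * v2)

    def test_symmetric_in_argument_exchange(self, geom):
        s1 = GazeSample(0, 10.0, 20.0, 0, 0)
        s2 = GazeSample(16, 55.0, 80.0, 0, 0)
        assert sample_velocity(s1, s2, geom) == sample_velocity(s2, s1, geom)

    def test_zero_dt_is_error(self, geom):
        s = GazeSample(0, 0.0, 0.0, 0, 0)
        with pytest.raises(DataError):
            sample_velocity(s, s, geom)


class TestClassifyIvt:
    def test_one_second_jitter_is_single_fixation(self, stationary_stream, geom):
        events = classify_ivt(stationary_stream, geom)
        fixations = [e for e in events if e.kind == "fixation"]
        assert len(fixations) == 1
        fx = fixations[0]
        assert fx.duration_ms == pytest.approx(1000, abs=2 * DT)
        assert fx.centroid_px[0] == pytest.approx(
            stationary_stream.data["x_px"].mean(), abs=0.01
        )

    def test_two_clusters_one_jump_give_two_fixations_one_saccade(self, geom):
        pts = [(200.0, 300.0)] * 30 + [(900.0, 300.0)] * 30
        events = classify_ivt(make_stream(pts), geom)
        kinds = [e.kind for e in events]
        assert kinds.count("fixation") == 2
        assert kinds.count("saccade") == 1

    def test_all_invalid_stream_warns_not_raises(self, geom, caplog):
        stream = make_stream([(np.nan, np.nan)] * 20, validity=[4] * 20)
        with caplog.at_level("WARNING"):
            events = classify_ivt(stream, geom)
        assert all(e.kind == "gap" for e in events)
        assert "no valid samples" in caplog.text

    def test_short_fixation_demoted_to_gap(self, geom):
        # 50 ms pause (3 samples) between two long fixations, below the
        # 100 ms minimum -> demoted
        pts = [(200.0, 300.0)] * 30 + [(600.0, 300.0)] * 3 + [(1000.0, 300.0)] * 30
        events = classify_ivt(make_stream(pts), geom)
        fixations = [e for e in events if e.kind == "fixation"]
        assert len(fixations) == 2
        centers = sorted(f.centroid_px[0] for f in fixations)
        assert centers[0] == pytest.approx(200, abs=1)
        assert centers[1] == pytest.approx(1000, abs=1)

    def test_short_invalid_run_inside_fixation_is_filled(self, geom):
        validity = [0] * 30 + [4] * 3 + [0] * 30
        pts = [(300.0, 300.0)] * 30 + [(np.nan, np.nan)] * 3 + [(300.0, 300.0)] * 30
        events = classify_ivt(make_stream(pts, validity=validity), geom)
        fixations = [e for e in events if e.kind == "fixation"]
        assert len(fixations) == 1
        assert fixations[0].duration_ms == pytest.approx(63 * DT, abs=2 * DT)

    def test_events_tile_stream_span(self, geom):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0, 1200, (200, 2))
        validity = rng.integers(0, 5, 200)
        stream = make_stream([tuple(p) for p in pts], validity=validity)
        events = classify_ivt(stream, geom)
        span = stream.span_ms
        assert events[0].t_start_ms == span[0]
        assert events[-1].t_end_ms == span[1]
        for a, b in zip(events, events[1:]):
            assert a.t_end_ms == b.t_start_ms

    def test_raising_threshold_never_adds_saccades(self, geom):
        rng = np.random.default_rng(11)
        pts = np.cumsum(rng.normal(0, 20, (300, 2)), axis=0) + 500
        stream = make_stream([tuple(p) for p in np.clip(pts, 0, 1200)])
        counts = []
        for thr in (10.0, 30.0, 60.0, 120.0):
            events = classify_ivt(stream, geom, velocity_threshold_deg_s=thr)
            counts.append(sum(e.n_samples for e in events if e.kind == "saccade"))
        assert counts == sorted(counts, reverse=True)

    def test_noise_free_synthetic_boundaries_match_ground_truth(self, geom):
        script = build_scene_script("exclusion", "explicit", 0, 1)
        profile = SimProfile(
            condition="explicit", noise_sd_px=0.0, dropout_rate=0.0, offscreen_hazard=0.0
        )
        stream, truth = simulate_gaze(script, profile, seed=2)
        events = classify_ivt(stream, geom)
        fixations = [e for e in events if e.kind == "fixation"]
        starts = np.array([f.t_start_ms for f in fixations])
        # collapsed ground-truth visit onsets (consecutive same-AOI draws
        # merge into one dwell, and a 1-3 sample saccade transit separates
        # dwells) must each have a recovered fixation onset within two
        # sample intervals
        onsets = []
        prev = None
        for aoi, t0, _ in truth.itinerary:
            if aoi != prev:
                onsets.append(t0)
            prev = aoi
        for t0 in onsets[1:]:
            assert np.min(np.abs(starts - t0)) <= 2 * DT + 1


class TestOffscreen:
    def _stream_with_invalid_run(self, n_invalid, n_valid=30):
        n = n_valid + n_invalid + n_valid
        validity = [0] * n_valid + [4] * n_invalid + [0] * n_valid
        pts = [(500.0, 300.0)] * n_valid + [(np.nan, np.nan)] * n_invalid + [
            (500.0, 300.0)
        ] * n_valid
        return make_stream(pts, validity=validity)

    def test_700ms_invalid_run_is_one_offscreen_event(self):
        stream = self._stream_with_invalid_run(42)  # 42 * 16.7 = 700 ms
        events = detect_offscreen_looks(stream)
        assert len(events) == 1
        assert events[0].duration_ms > 500

    def test_400ms_invalid_run_is_no_offscreen_event(self):
        stream = self._stream_with_invalid_run(24)  # 400 ms
        assert detect_offscreen_looks(stream) == []

    def test_two_separated_runs_give_two_events(self):
        validity = [0] * 30 + [4] * 36 + [0] * 6 + [4] * 36 + [0] * 30
        pts = [
            (500.0, 300.0) if v == 0 else (np.nan, np.nan) for v in validity
        ]
        stream = make_stream(pts, validity=validity)
        assert len(detect_offscreen_looks(stream)) == 2

    def test_count_non_increasing_in_min_invalid_ms(self):
        rng = np.random.default_rng(5)
        validity = (rng.random(1200) < 0.25).astype(int) * 4
        pts = [
            (500.0, 300.0) if v == 0 else (np.nan, np.nan) for v in validity
        ]
        stream = make_stream(pts, validity=validity)
        counts = [
            len(detect_offscreen_looks(stream, min_invalid_ms=m))
            for m in (100, 250, 500, 1000)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_segment_stream_keeps_offscreen_unfilled(self, geom):
        stream = self._stream_with_invalid_run(42)
        events = segment_stream(stream, geom)
        assert sum(e.kind == "offscreen" for e in events) == 1
        # tiling still holds with the offscreen relabelling
        for a, b in zip(events, events[1:]):
            assert a.t_end_ms == b.t_start_ms


class TestCalibrationOffset:
    def test_zero_offset_is_identity(self, stationary_stream):
        out = apply_offset(stationary_stream, CalibrationOffset(0, 0))
        assert np.allclose(out.xy, stationary_stream.xy)

    def test_offset_then_negation_restores_stream(self, stationary_stream):
        off = CalibrationOffset(5.0, -3.0)
        out = apply_offset(apply_offset(stationary_stream, off), off.negated())
        assert np.allclose(out.xy, stationary_stream.xy)

    def test_centroids_shift_by_exactly_the_offset(self, stationary_stream, geom):
        off = CalibrationOffset(12.0, -7.0)
        base = classify_ivt(stationary_stream, geom)
        shifted = classify_ivt(apply_offset(stationary_stream, off), geom)
        c0 = [e.centroid_px for e in base if e.kind == "fixation"][0]
        c1 = [e.centroid_px for e in shifted if e.kind == "fixation"][0]
        assert c1[0] - c0[0] == pytest.approx(12.0, abs=1e-9)
        assert c1[1] - c0[1] == pytest.approx(-7.0, abs=1e-9)

    @pytest.mark.parametrize("true_offset", [(12.0, -8.0), (0.0, 0.0)])
    def test_injected_offset_recovered(self, geom, true_offset):
        script = build_scene_script("exclusion", "explicit", 0, 1)
        profile = SimProfile(
            condition="explicit",
            noise_sd_px=3.0,
            dropout_rate=0.0,
            offscreen_hazard=0.0,
            calibration_offset_px=true_offset,
        )
        stream, _ = simulate_gaze(script, profile, seed=4)
        est = estimate_offset(stream, script.tracks, geom)
        assert est.dx_px == pytest.approx(true_offset[0], abs=3)
        assert est.dy_px == pytest.approx(true_offset[1], abs=3)

    def test_estimate_is_translation_equivariant(self, geom):
        script = build_scene_script("exclusion", "explicit", 0, 1)
        profile = SimProfile(
            condition="explicit", noise_sd_px=3.0, dropout_rate=0.0, offscreen_hazard=0.0
        )
        stream, _ = simulate_gaze(script, profile, seed=6)
        base = estimate_offset(stream, script.tracks, geom)
        shifted = estimate_offset(
            apply_offset(stream, CalibrationOffset(15.0, 9.0)), script.tracks, geom
        )
        assert shifted.dx_px - base.dx_px == pytest.approx(15.0, abs=1.5)
        assert shifted.dy_px - base.dy_px == pytest.approx(9.0, abs=1.5)

    def test_no_fixations_is_estimation_error(self, geom):
        stream = make_stream([(np.nan, np.nan)] * 20, validity=[4] * 20)
        with pytest.raises(EstimationError):
            estimate_offset(stream, [static_track("Excluded", (400.0, 300.0))], geom)
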