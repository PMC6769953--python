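"""Dynamic AOIs, scanpath extraction, pattern matching, aversion rates."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from socialgaze.aoi import (
    GROUP_AOIS,
    OFFSCREEN,
    AoiShape,
    AoiTrack,
    PatternTemplate,
    ScanpathSequence,
    ScanpathVisit,
    aoi_at,
    aversion_contingency,
    aversion_ratio,
    extract_scanpath,
    hit_test,
    match_pattern,
    synchrony_summary,
    tracks_from_json,
    tracks_to_json,
)
from socialgaze.errors import DataError
from socialgaze.events import GazeEvent, segment_stream
from socialgaze.scenes import build_scene_script
from socialgaze.simulate import SimProfile, simulate_gaze

from conftest import static_track


def seq_from_labels(labels, visit_ms=500):
    visits = []
    t = 0
    for lab in labels:
        visits.append(ScanpathVisit(lab, t, t + visit_ms, 1, visit_ms))
        t += visit_ms + 40
    return ScanpathSequence(visits)


class TestAoiAt:
    def test_keyframe_time_returns_that_shape(self):
        track = static_track("Excluded", (200.0, 300.0))
        assert aoi_at(track, 0).center_px == (200.0, 300.0)

    def test_linear_midpoint_averages_centers(self):
        a = AoiShape("ellipse", (100.0, 100.0), (50.0, 50.0))
        b = AoiShape("ellipse", (300.0, 200.0), (50.0, 50.0))
        track = AoiTrack("Excluded", ((0, a), (1000, b)), interpolation="linear")
        mid = aoi_at(track, 500)
        assert mid.center_px == (200.0, 150.0)

    def test_before_first_keyframe_is_none(self):
        a = AoiShape("ellipse", (100.0, 100.0), (50.0, 50.0))
        track = AoiTrack("Excluded", ((1000, a), (2000, a)))
        assert aoi_at(track, 500) is None

    def test_step_interpolation_holds_previous_shape(self):
        a = AoiShape("ellipse", (100.0, 100.0), (50.0, 50.0))
        b = AoiShape("ellipse", (300.0, 200.0), (50.0, 50.0))
        track = AoiTrack("Excluded", ((0, a), (1000, b)), interpolation="step")
        assert aoi_at(track, 999).center_px == (100.0, 100.0)


class TestHitTest:
    def test_point_at_center_hits_that_aoi(self):
        tracks = [
            static_track("Excluded", (200.0, 300.0)),
            static_track("Gatekeeper", (800.0, 300.0)),
        ]
        assert hit_test((200.0, 300.0), tracks, 1000) == "Excluded"

    def test_overlap_resolved_by_nearest_center(self):
        tracks = [
            static_track("GroupMemberA", (500.0, 300.0)),
            static_track("GroupMemberB", (620.0, 300.0)),
        ]
        assert hit_test((550.0, 300.0), tracks, 0) == "GroupMemberA"
        assert hit_test((580.0, 300.0), tracks, 0) == "GroupMemberB"

    def test_point_far_from_all_shapes_is_none(self):
        tracks = [static_track("Excluded", (200.0, 300.0))]
        assert hit_test((1200.0, 700.0), tracks, 0) is None

    @given(
        px=st.floats(0, 1280),
        py=st.floats(0, 720),
        pad_small=st.floats(0, 30),
        pad_extra=st.floats(0, 40),
    )
    @settings(max_examples=60, deadline=None)
    def test_enlarging_padding_never_turns_hit_into_miss(
        self, px, py, pad_small, pad_extra
    ):
        def track(pad):
            shape = AoiShape("ellipse", (640.0, 360.0), (110.0, 140.0), padding_px=pad)
            return AoiTrack("Excluded", ((0, shape), (1000, shape)))

        small = hit_test((px, py), [track(pad_small)], 500)
        if small is not None:
            assert hit_test((px, py), [track(pad_small + pad_extra)], 500) is not None


class TestExtractScanpath:
    def _fix(self, t0, t1, centroid):
        return GazeEvent("fixation", t0, t1, centroid_px=centroid, n_samples=5)

    def test_consecutive_same_aoi_fixations_collapse(self):
        tracks = [
            static_track("Excluded", (200.0, 300.0)),
            static_track("Gatekeeper", (800.0, 300.0)),
        ]
        events = [
            self._fix(0, 400, (200.0, 300.0)),
            self._fix(450, 900, (205.0, 305.0)),
            self._fix(950, 1400, (800.0, 300.0)),
        ]
        seq = extract_scanpath(events, tracks)
        assert seq.labels == ["Excluded", "Gatekeeper"]
        assert seq.visits[0].n_fixations == 2

    def test_unlabeled_fixation_logged_not_emitted(self):
        tracks = [static_track("Excluded", (200.0, 300.0))]
        events = [self._fix(0, 400, (1200.0, 700.0))]
        seq = extract_scanpath(events, tracks)
        assert seq.visits == []
        assert seq.n_unlabeled_fixations == 1

    def test_offscreen_events_become_offscreen_visits(self):
        tracks = [static_track("Excluded", (200.0, 300.0))]
        events = [
            self._fix(0, 400, (200.0, 300.0)),
            GazeEvent("offscreen", 400, 1100, n_samples=42),
            self._fix(1100, 1500, (200.0, 300.0)),
        ]
        seq = extract_scanpath(events, tracks)
        assert seq.labels == ["Excluded", OFFSCREEN, "Excluded"]

    def test_synthetic_visit_sequence_matches_generator_itinerary(self, geom):
        script = build_scene_script("exclusion", "implicit", 0, 1)
        profile = SimProfile(
            condition="implicit", noise_sd_px=0.0, dropout_rate=0.0,
            offscreen_hazard=0.0, aversion_multiplier=1.0,
        )
        stream, truth = simulate_gaze(script, profile, seed=9)
        events = segment_stream(stream, geom)
        seq = extract_scanpath(events, script.tracks)
        assert seq.labels == truth.visit_labels

    def test_collapse_is_idempotent(self):
        seq = seq_from_labels(["Excluded", "Gatekeeper", "Excluded"])
        again = seq.onscreen().onscreen()
        assert again.labels == seq.labels


def brute_force_ordered_matches(labels, times, steps, max_span):
    """All leftmost non-overlapping ordered matches by exhaustive enumeration."""
    found = []
    lo = 0
    while True:
        candidates = [
            combo
            for combo in itertools.combinations(range(lo, len(labels)), len(steps))
            if all(labels[i] in step for i, step in zip(combo, steps))
            and (max_span is None or times[combo[-1]] - times[combo[0]] <= max_span)
        ]
        if not candidates:
            return found
        best = min(candidates)  # leftmost-first: smallest index tuple
        found.append((best[0], best[-1]))
        lo = best[-1] + 1


class TestMatchPattern:
    def test_ordered_individual_group_individual(self):
        seq = seq_from_labels(["Excluded", "GroupMemberA", "Excluded"])
        tpl = PatternTemplate.make(["Excluded", GROUP_AOIS, "Excluded"])
        assert match_pattern(seq, tpl) == [(0, 2)]

    def test_unordered_template_matches_in_any_order(self):
        seq = seq_from_labels(["Resource", "Excluded", "GroupMemberB"])
        tpl = PatternTemplate.make(
            [{"Excluded"}, {"Resource"}, GROUP_AOIS], ordered=False,
            window=(0, 5000), max_span_ms=None,
        )
        assert len(match_pattern(seq, tpl)) == 1

    def test_span_limit_rejects_slow_patterns(self):
        visits = [
            ScanpathVisit("Excluded", 0, 400),
            ScanpathVisit("GroupMemberA", 500, 900),
            ScanpathVisit("Excluded", 8000, 8400),
        ]
        seq = ScanpathSequence(visits)
        tpl = PatternTemplate.make(
            ["Excluded", GROUP_AOIS, "Excluded"], max_span_ms=4000
        )
        assert match_pattern(seq, tpl) == []

    @given(
        labels=st.lists(
            st.sampled_from(["Excluded", "Gatekeeper", "GroupMemberA", "Resource"]),
            min_size=0,
            max_size=8,
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_matcher_agrees_with_exhaustive_enumeration(self, labels):
        # collapse duplicates to honour the visit invariant
        collapsed = [lab for i, lab in enumerate(labels) if i == 0 or lab != labels[i - 1]]
        seq = seq_from_labels(collapsed)
        tpl = PatternTemplate.make(
            ["Excluded", GROUP_AOIS, "Excluded"], max_span_ms=4000
        )
        times = [v.t_start_ms for v in seq.visits]
        expected = brute_force_ordered_matches(
            collapsed, times, tpl.steps, tpl.max_span_ms
        )
        assert match_pattern(seq, tpl) == expected

    def test_appending_visits_preserves_existing_matches(self):
        base = ["Excluded", "GroupMemberA", "Excluded"]
        tpl = PatternTemplate.make(["Excluded", GROUP_AOIS, "Excluded"])
        before = match_pattern(seq_from_labels(base), tpl)
        after = match_pattern(seq_from_labels(base + ["Resource", "Gatekeeper"]), tpl)
        assert before[0] in after


class TestSynchronySummary:
    def _session(self, infant_id):
        class S:
            pass

        s = S()
        s.infant_id = infant_id
        return s

    def test_three_of_four_trials_give_075(self):
        tpl = PatternTemplate.make(["Excluded", GROUP_AOIS, "Excluded"])
        matching = seq_from_labels(["Excluded", "GroupMemberA", "Excluded"])
        non_matching = seq_from_labels(["Resource", "Gatekeeper"])
        cohort = [
            (self._session("a"), [matching, matching]),
            (self._session("b"), [matching, non_matching]),
        ]
        frame = synchrony_summary(cohort, tpl)
        assert frame.attrs["fraction"] == 0.75
        assert frame.attrs["n_matched"] == 3

    def test_zero_trials_is_error(self):
        tpl = PatternTemplate.make(["Excluded", GROUP_AOIS, "Excluded"])
        with pytest.raises(DataError):
            synchrony_summary([], tpl)


class TestAversion:
    def test_gatekeeper_then_offscreen_counts(self):
        seq = seq_from_labels(["Gatekeeper", OFFSCREEN])
        assert aversion_contingency([seq]) == 1.0

    def test_interposed_visit_does_not_count(self):
        seq = seq_from_labels(["Gatekeeper", "Excluded", OFFSCREEN])
        assert aversion_contingency([seq]) == 0.0

    def test_zero_divisor_ratio_is_nan_not_exception(self):
        a = [seq_from_labels(["Gatekeeper", OFFSCREEN])]
        b = [seq_from_labels(["Gatekeeper", "Excluded"])]
        assert np.isnan(aversion_ratio(a, b))


def test_tracks_round_trip_through_json(tmp_path):
    script = build_scene_script("exclusion", "explicit", 0, 1)
    path = tmp_path / "tracks.json"
    tracks_to_json(script.tracks, path)
    back = tracks_from_json(path)
    assert back == list(script.tracks)
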