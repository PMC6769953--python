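"""Semi-Markov simulation of infant gaze over the scripted scenes.

The generator emulates what a 60 Hz infant recording looks like: an itinerary
of AOI *visits* drawn from a condition-dependent dwell distribution, visit
durations drawn log-normally (median ~400 ms), 1-2 sample high-velocity
saccade transits between visits, occasional purposeful offscreen episodes
(validity dropout > 500 ms, with an elevated hazard right after a gatekeeper
visit in the explicit condition), Gaussian oculomotor noise around the moving
AOI centre, sporadic single-sample tracking dropout, and an optional constant
calibration offset.  Every stream is accompanied by a ground-truth log of the
intended itinerary so each pipeline stage can be validated against what the
generator meant to produce.

Cohort simulation adds the outcome models: the preferential-reaching choice
(predicted character chosen with probability 0.75 explicit / 0.77 implicit),
the anticipatory first look (probability 0.727 of looking to the group in the
implicit condition, 0.545 explicit), and a configurable fraction of sessions
made deliberately invalid to exercise the inclusion filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from socialgaze.aoi import GROUP_AOIS, OFFSCREEN, aoi_at
from socialgaze.errors import ConfigError
from socialgaze.events import GEOMETRY_17IN_1280x1024, GeometryConfig
from socialgaze.gaze_io import GazeStream, SessionRecord, TrialRecord
from socialgaze.scenes import SceneScript, build_scene_script

DT_MS = 1000.0 / 60.0

#: exclusion-trial dwell shares seeded from the reported per-condition means
#: (excluded 0.439 / gatekeeper 0.268 implicit; 0.338 / 0.351 explicit)
DWELL_EXCLUSION = {
    "implicit": {
        "Excluded": 0.439, "Gatekeeper": 0.268, "GroupMemberA": 0.09,
        "GroupMemberB": 0.09, "Resource": 0.113,
    },
    "explicit": {
        "Excluded": 0.338, "Gatekeeper": 0.351, "GroupMemberA": 0.10,
        "GroupMemberB": 0.10, "Resource": 0.111,
    },
}
DWELL_ACCEPTANCE = {
    "Excluded": 0.30, "Gatekeeper": 0.25, "GroupMemberA": 0.15,
    "GroupMemberB": 0.15, "Resource": 0.15,
}
DWELL_END_SCENE = {"Excluded": 0.5, "Gatekeeper": 0.5}
#: focal test-trial scanning, mostly on the neutral character
DWELL_TEST = {
    "Neutral": 0.45, "Excluded": 0.20, "Gatekeeper": 0.15,
    "GroupMemberA": 0.10, "GroupMemberB": 0.10,
}


@dataclass(frozen=True)
class SimProfile:
    """Stochastic gaze-behaviour parameters for one condition."""

    condition: str = "explicit"
    visit_median_ms: float = 400.0
    visit_sigma: float = 0.45
    visit_min_ms: float = 200.0
    visit_max_ms: float = 3000.0
    saccade_ms: tuple[float, float] = (17.0, 50.0)
    offscreen_hazard: float = 0.015
    aversion_multiplier: float = 1.8  # applies after a Gatekeeper visit
    offscreen_ms: tuple[float, float] = (600.0, 1500.0)
    noise_sd_px: float = 6.0
    noise_rho: float = 0.6  # AR(1) autocorrelation of the oculomotor noise
    dropout_rate: float = 0.01
    calibration_offset_px: tuple[float, float] = (0.0, 0.0)
    choice_p: float = 0.75  # P(choose the predicted character)
    anticipation_p: float = 0.545  # P(first look to the group)
    synchrony_q: float = 0.747  # P(embed the entry I->Group->I pattern)
    dwell_override: dict | None = None

    def __post_init__(self) -> None:
        for p in (self.offscreen_hazard, self.choice_p, self.anticipation_p, self.synchrony_q):
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")

    def dwell(self, script: SceneScript) -> dict[str, float]:
        if self.dwell_override is not None:
            d = dict(self.dwell_override)
        elif script.scene_type == "acceptance":
            d = dict(DWELL_ACCEPTANCE)
        elif script.scene_type == "end_scene":
            d = dict(DWELL_END_SCENE)
        elif script.scene_type == "test":
            d = dict(DWELL_TEST)
        else:
            d = dict(DWELL_EXCLUSION[self.condition])
        if script.experiment == 2 and script.scene_type not in ("test", "end_scene"):
            d.setdefault("Neutral", 0.10)
        d = {a: w for a, w in d.items() if a in script.aoi_ids}
        total = sum(d.values())
        return {a: w / total for a, w in d.items()}


def default_profiles() -> dict[str, SimProfile]:
    """Condition profiles seeded from the reported outcome frequencies."""
    return {
        "explicit": SimProfile(
            condition="explicit", choice_p=0.75, anticipation_p=0.545,
            aversion_multiplier=1.8,
        ),
        "implicit": SimProfile(
            condition="implicit", choice_p=0.77, anticipation_p=0.727,
            aversion_multiplier=1.0,
        ),
    }


@dataclass(frozen=True)
class CohortSpec:
    """Shape of a simulated cohort."""

    n_per_condition: int = 16
    experiment: int = 1
    min_trial_pairs: int = 2
    max_trial_pairs: int = 3
    invalid_fraction: float = 0.0
    seed: int = 0
    #: skip stream rendering (outcome draws and trial records only) — used for
    #: large-n checks of the choice/anticipation models
    render_gaze: bool = True

    def __post_init__(self) -> None:
        if self.n_per_condition < 1:
            raise ConfigError("need at least one infant per condition")
        if not 2 <= self.min_trial_pairs <= self.max_trial_pairs <= 3:
            raise ConfigError("trial pairs must lie in the 2-3 range")
        if not 0 <= self.invalid_fraction <= 1:
            raise ConfigError("invalid fraction must lie in [0, 1]")


@dataclass
class GroundTruth:
    """What the generator intended: the AOI itinerary and offscreen episodes."""

    itinerary: list[tuple[str, int, int]]  # (aoi or Offscreen, t0, t1)
    pattern_embedded: bool = False
    pattern_present: bool = False

    @property
    def visit_labels(self) -> list[str]:
        """Collapsed label sequence (consecutive duplicates merged)."""
        labels = [a for a, _, _ in self.itinerary]
        out: list[str] = []
        for lab in labels:
            if not out or out[-1] != lab:
                out.append(lab)
        return out


@dataclass
class SimTrial:
    record: TrialRecord
    script: SceneScript
    stream: GazeStream
    truth: GroundTruth


@dataclass
class SimSession:
    session: SessionRecord
    trials: list[SimTrial] = field(default_factory=list)


#: canonical seeded demonstration cohorts; regenerate with
#: ``simulate_cohort(FIXTURE_SPECS[name])`` — identical every time
FIXTURE_SPECS = {
    "exp1-small": CohortSpec(n_per_condition=3, experiment=1, seed=101),
    "exp2-small": CohortSpec(n_per_condition=3, experiment=2, seed=202),
    "exp1-with-dropouts": CohortSpec(
        n_per_condition=4, experiment=1, invalid_fraction=0.25, seed=303
    ),
}


# ---------------------------------------------------------------------------
# itinerary and rendering


def _sample_aoi(rng, dwell: dict[str, float], exclude: str | None) -> str:
    items = [(a, w) for a, w in dwell.items() if a != exclude]
    total = sum(w for _, w in items)
    r = rng.random() * total
    acc = 0.0
    for a, w in items:
        acc += w
        if r <= acc:
            return a
    return items[-1][0]


def _build_itinerary(
    script: SceneScript,
    profile: SimProfile,
    rng: np.random.Generator,
    forced: Sequence[tuple[int, Sequence[str]]] = (),
) -> GroundTruth:
    dwell = profile.dwell(script)
    mu = math.log(profile.visit_median_ms)
    forced = sorted(forced, key=lambda f: f[0])
    queue: list[str] = []
    next_forced = 0
    t = 0.0
    prev: str | None = None
    segments: list[tuple[str, int, int]] = []
    embedded = False
    while t < script.duration_ms - profile.visit_min_ms:
        if not queue and next_forced < len(forced) and t >= forced[next_forced][0]:
            queue = list(forced[next_forced][1])
            next_forced += 1
            embedded = True
        if queue:
            aoi = queue.pop(0)
            if aoi == prev and queue:
                aoi = queue.pop(0)
        else:
            # iid draws (repeats allowed, later collapsed) keep the expected
            # fixation-time share of each AOI equal to its dwell weight
            aoi = _sample_aoi(rng, dwell, None)
        dur = float(np.clip(rng.lognormal(mu, profile.visit_sigma),
                            profile.visit_min_ms, profile.visit_max_ms))
        dur = min(dur, script.duration_ms - t)
        if dur < profile.visit_min_ms:
            break
        segments.append((aoi, int(round(t)), int(round(t + dur))))
        t += dur
        prev = aoi
        hazard = profile.offscreen_hazard * (
            profile.aversion_multiplier if aoi == "Gatekeeper" else 1.0
        )
        if rng.random() < hazard and t + profile.offscreen_ms[1] < script.duration_ms:
            off = rng.uniform(*profile.offscreen_ms)
            segments.append((OFFSCREEN, int(round(t)), int(round(t + off))))
            t += off
        t += rng.uniform(*profile.saccade_ms)
    return GroundTruth(segments, pattern_embedded=embedded)


def _render_stream(
    script: SceneScript,
    truth: GroundTruth,
    profile: SimProfile,
    rng: np.random.Generator,
    recording_id: str,
    geometry: GeometryConfig,
) -> GazeStream:
    n_samples = int(script.duration_ms / DT_MS)
    times = np.round(np.arange(n_samples) * DT_MS).astype(np.int64)
    x = np.full(n_samples, np.nan)
    y = np.full(n_samples, np.nan)
    validity = np.full(n_samples, 4, dtype=np.int64)

    track_of = {tr.aoi_id: tr for tr in script.tracks}

    def center(aoi: str, t: float) -> tuple[float, float]:
        shape = aoi_at(track_of[aoi], t)
        if shape is None:  # hold at nearest keyframe (tracks span the scene)
            shape = track_of[aoi].keyframes[0][1]
        return shape.center_px

    prev_end_pos: tuple[float, float] | None = None
    prev_end_t: float | None = None
    for aoi, t0, t1 in truth.itinerary:
        sel = (times >= t0) & (times < t1)
        idx = np.flatnonzero(sel)
        if aoi == OFFSCREEN:
            prev_end_pos, prev_end_t = None, None
            continue
        centers = np.array([center(aoi, float(times[i])) for i in idx])
        if idx.size:
            # AR(1) noise: tracker jitter is temporally correlated, so the
            # sample-to-sample step stays well below the saccade threshold
            sd, rho = profile.noise_sd_px, profile.noise_rho
            noise = np.zeros((idx.size, 2))
            if sd > 0:
                noise[0] = rng.normal(0.0, sd, 2)
                innov = rng.normal(0.0, sd * math.sqrt(1 - rho**2), (idx.size, 2))
                for j in range(1, idx.size):
                    noise[j] = rho * noise[j - 1] + innov[j]
            x[idx] = centers[:, 0] + noise[:, 0]
            y[idx] = centers[:, 1] + noise[:, 1]
            validity[idx] = 0
        # saccade transit: samples between the previous visit and this one
        if idx.size and prev_end_pos is not None:
            gap = np.flatnonzero((times >= prev_end_t) & (times < t0))
            if gap.size:
                start, end = prev_end_pos, center(aoi, float(t0))
                for g_i, i in enumerate(gap, start=1):
                    w = g_i / (gap.size + 1)
                    x[i] = (1 - w) * start[0] + w * end[0]
                    y[i] = (1 - w) * start[1] + w * end[1]
                    validity[i] = 0
        if idx.size:
            prev_end_pos = center(aoi, float(t1))
            prev_end_t = t1

    # sporadic single-sample tracking dropout (never forms an offscreen run)
    if profile.dropout_rate > 0:
        drop = rng.random(n_samples) < profile.dropout_rate
        drop &= np.roll(drop, 1) == False  # noqa: E712 — keep runs at length 1
        x[drop] = np.nan
        y[drop] = np.nan
        validity[drop] = 4

    dx, dy = profile.calibration_offset_px
    frame = pd.DataFrame(
        {
            "time_ms": times,
            "x_px": x + dx,
            "y_px": y + dy,
            "validity_left": validity,
            "validity_right": validity,
        }
    )
    return GazeStream(frame, recording_id=recording_id, geometry=geometry)


def simulate_gaze(
    script: SceneScript,
    profile: SimProfile,
    seed: int | np.random.Generator = 0,
    recording_id: str = "sim",
    forced: Sequence[tuple[int, Sequence[str]]] = (),
    geometry: GeometryConfig = GEOMETRY_17IN_1280x1024,
) -> tuple[GazeStream, GroundTruth]:
    """Simulate one trial's gaze stream plus its ground-truth log.

    ``forced`` injects deterministic visit runs: each entry ``(t_ms, aois)``
    makes the itinerary follow the given AOI order once the clock passes
    ``t_ms`` (used for pattern embedding and scripted anticipation looks).
    Identical seed, identical output.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    truth = _build_itinerary(script, profile, rng, forced)
    stream = _render_stream(script, truth, profile, rng, recording_id, geometry)
    labels = truth.visit_labels
    pattern = any(
        a == "Excluded" and b in GROUP_AOIS and c == "Excluded"
        for a, b, c in zip(labels, labels[1:], labels[2:])
    )
    truth.pattern_present = pattern
    return stream, truth


# ---------------------------------------------------------------------------
# cohort simulation


def _familiarization_schedule(n_pairs: int, experiment: int) -> list[str]:
    scenes = []
    for _ in range(n_pairs):
        scenes.extend(["acceptance", "exclusion"])
    scenes.append("end_scene" if experiment == 1 else "test")
    return scenes


def simulate_cohort(
    spec: CohortSpec,
    profiles: dict[str, SimProfile] | None = None,
    geometry: GeometryConfig = GEOMETRY_17IN_1280x1024,
) -> list[SimSession]:
    """Simulate a full cohort of sessions with sampled outcomes.

    The first ``round(invalid_fraction * n)`` infants of each condition are
    given too few familiarization trials (and a fussiness flag), so exactly
    that many sessions fail the inclusion filter by construction.
    """
    profiles = profiles or default_profiles()
    root = np.random.SeedSequence(spec.seed)
    sessions: list[SimSession] = []
    infant_no = 0
    for condition in ("explicit", "implicit"):
        profile = profiles[condition]
        n_invalid = round(spec.invalid_fraction * spec.n_per_condition)
        child_seeds = root.spawn(spec.n_per_condition)
        for i in range(spec.n_per_condition):
            infant_no += 1
            rng = np.random.default_rng(child_seeds[i])
            infant_id = f"sim{infant_no:03d}"
            invalid = i < n_invalid
            counterbalance = int(rng.integers(2))
            n_pairs = 1 if invalid else int(
                rng.integers(spec.min_trial_pairs, spec.max_trial_pairs + 1)
            )
            scene_order = _familiarization_schedule(n_pairs, spec.experiment)
            if invalid:
                scene_order = scene_order[:-1]  # fussy: session stops early

            # outcome draws (generator ground truth)
            predicted = "excluded" if condition == "explicit" else "gatekeeper"
            other = "gatekeeper" if condition == "explicit" else "excluded"
            choice = predicted if rng.random() < profile.choice_p else other
            first_dir = "group" if rng.random() < profile.anticipation_p else "excluded"
            voe_dir = "group" if rng.random() < 0.5 else "excluded"

            trials: list[SimTrial] = []
            records: list[TrialRecord] = []
            t_cursor = 0
            for k, scene in enumerate(scene_order, start=1):
                script = build_scene_script(
                    scene, condition, counterbalance, spec.experiment, geometry
                )
                forced: list[tuple[int, Sequence[str]]] = []
                if scene == "exclusion" and rng.random() < profile.synchrony_q:
                    member = ("Gatekeeper", "GroupMemberA", "GroupMemberB")[
                        int(rng.integers(3))
                    ]
                    forced.append(
                        (script.markers["entry"], ["Excluded", member, "Excluded"])
                    )
                if scene == "test":
                    target = (
                        "GroupMemberA" if first_dir == "group" else "Excluded"
                    )
                    forced.append(
                        (script.critical_window[0], ["Neutral", target, "Neutral"])
                    )
                if spec.render_gaze:
                    stream, truth = simulate_gaze(
                        script, profile, rng,
                        recording_id=f"{infant_id}_t{k:02d}_{script.scene_type}",
                        forced=forced, geometry=geometry,
                    )
                else:
                    stream, truth = None, None
                record = TrialRecord(
                    infant_id=infant_id,
                    experiment=spec.experiment,
                    condition=condition,
                    trial_index=k,
                    scene_type=scene if scene != "exclusion" else "exclusion",
                    t_start_ms=t_cursor,
                    t_end_ms=t_cursor + script.duration_ms,
                    critical_event_seen=True,
                )
                t_cursor += script.duration_ms + 2_000  # attention grabber
                records.append(record)
                trials.append(SimTrial(record, script, stream, truth))

            session = SessionRecord(
                infant_id=infant_id,
                age_days=int(rng.integers(213, 300)),  # 7m0d - 9m28d
                experiment=spec.experiment,
                condition=condition,
                trials=records,
                choice_outcome=choice if spec.experiment == 1 and not invalid else "none",
                anticipation_first_direction=(
                    first_dir if spec.experiment == 2 and not invalid else "none"
                ),
                voe_direction=voe_dir if spec.experiment == 2 and not invalid else "none",
                flags=frozenset({"fussiness"}) if invalid else frozenset(),
            )
            sessions.append(SimSession(session, trials))
    return sessions
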