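"""Oculomotor event classification.

Raw 60 Hz samples are segmented into four mutually exclusive event kinds that
tile the stream span:

``fixation``
    a maximal run of valid samples whose angular velocity stays below the
    I-VT threshold, lasting at least ``min_fixation_ms``;
``saccade``
    supra-threshold valid samples between fixations;
``offscreen``
    a maximal run of invalid samples longer than 500 ms — treated as the
    infant's purposeful look away from the screen (head turn), not tracker
    noise;
``gap``
    everything else (short dropouts, demoted micro-fixations).

Angular velocity is computed from pixel pitch and viewing distance; with the
default geometry (17-inch screen at 550 mm) one degree is roughly 40-50 px,
which is also the AOI padding scale used downstream.

Short invalid runs (<= ``max_gap_fill_ms``) flanked by fixation samples are
interpolated into the fixation; offscreen runs are detected first and are
never interpolated away.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from socialgaze.errors import ConfigError, DataError, EstimationError
from socialgaze.gaze_io import DEFAULT_VALIDITY_THRESHOLD, GazeSample, GazeStream

logger = logging.getLogger(__name__)

DEFAULT_VELOCITY_THRESHOLD_DEG_S = 30.0
DEFAULT_MIN_FIXATION_MS = 100
DEFAULT_MAX_GAP_FILL_MS = 75
DEFAULT_MIN_OFFSCREEN_MS = 500


@dataclass(frozen=True)
class GeometryConfig:
    """Physical setup: screen size, resolution, viewing distance, stimulus placement.

    The stimulus (1280 x 720 by default) is centred on the physical screen;
    letterbox margins are on-screen but off-stimulus.
    """

    screen_px: tuple[int, int]
    screen_mm: tuple[float, float]
    viewing_distance_mm: float = 550.0
    stimulus_size_px: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        if min(*self.screen_px, *self.screen_mm, self.viewing_distance_mm) <= 0:
            raise ConfigError("geometry values must be positive")
        if not 400 <= self.viewing_distance_mm <= 800:
            logger.warning(
                "viewing distance %.0f mm outside the typical 400-800 mm band",
                self.viewing_distance_mm,
            )

    @property
    def mm_per_px(self) -> tuple[float, float]:
        return (
            self.screen_mm[0] / self.screen_px[0],
            self.screen_mm[1] / self.screen_px[1],
        )

    @property
    def stimulus_origin_px(self) -> tuple[float, float]:
        return (
            (self.screen_px[0] - self.stimulus_size_px[0]) / 2.0,
            (self.screen_px[1] - self.stimulus_size_px[1]) / 2.0,
        )

    def px_per_degree(self) -> float:
        """Approximate pixels per degree of visual angle at screen centre."""
        pitch = sum(self.mm_per_px) / 2.0
        mm_per_deg = self.viewing_distance_mm * math.tan(math.radians(1.0))
        return mm_per_deg / pitch

    def on_stimulus(self, x_px: float, y_px: float) -> bool:
        ox, oy = self.stimulus_origin_px
        w, h = self.stimulus_size_px
        return ox <= x_px < ox + w and oy <= y_px < oy + h


#: 17-inch 1280x1024 tracker-with-monitor setup (4:3 panel, ~338 x 270 mm)
GEOMETRY_17IN_1280x1024 = GeometryConfig(screen_px=(1280, 1024), screen_mm=(337.9, 270.3))
#: 23-inch 1920x1080 setup (16:9 panel, ~509 x 286 mm)
GEOMETRY_23IN_1920x1080 = GeometryConfig(screen_px=(1920, 1080), screen_mm=(509.2, 286.4))

GEOMETRY_PRESETS = {
    "17in-1280x1024": GEOMETRY_17IN_1280x1024,
    "23in-1920x1080": GEOMETRY_23IN_1920x1080,
}


@dataclass(frozen=True)
class GazeEvent:
    """A classified interval, half-open on the stream clock."""

    kind: str  # "fixation" | "saccade" | "gap" | "offscreen"
    t_start_ms: int
    t_end_ms: int
    centroid_px: tuple[float, float] | None = None
    dispersion_px: float | None = None
    peak_velocity_deg_s: float | None = None
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.t_end_ms <= self.t_start_ms:
            raise DataError(f"event with non-positive duration: {self}")

    @property
    def duration_ms(self) -> int:
        return self.t_end_ms - self.t_start_ms

    @property
    def t_mid_ms(self) -> float:
        return (self.t_start_ms + self.t_end_ms) / 2.0


@dataclass(frozen=True)
class CalibrationOffset:
    """Constant translation of all gaze coordinates within a session."""

    dx_px: float
    dy_px: float

    def __post_init__(self) -> None:
        if abs(self.dx_px) > 200 or abs(self.dy_px) > 200:
            raise ConfigError("calibration offset beyond the 200 px sanity bound")

    def negated(self) -> "CalibrationOffset":
        return CalibrationOffset(-self.dx_px, -self.dy_px)


# ---------------------------------------------------------------------------
# geometry


def sample_velocity(s1: GazeSample, s2: GazeSample, geom: GeometryConfig) -> float:
    """Angular velocity (deg/s) between two samples.

    The visual angle is ``atan(chord / viewing_distance)`` where the chord is
    the on-screen displacement converted to millimetres via the per-axis pixel
    pitch.  Symmetric under argument exchange.
    """
    dt_ms = abs(s2.time_ms - s1.time_ms)
    if dt_ms == 0:
        raise DataError("zero time difference between samples")
    mx, my = geom.mm_per_px
    dx_mm = (s2.x_px - s1.x_px) * mx
    dy_mm = (s2.y_px - s1.y_px) * my
    chord = math.hypot(dx_mm, dy_mm)
    angle_deg = math.degrees(math.atan(chord / geom.viewing_distance_mm))
    return angle_deg / (dt_ms / 1000.0)


def _velocity_profile(stream: GazeStream, geom: GeometryConfig, valid: np.ndarray) -> np.ndarray:
    """Per-sample angular velocity, assigned to the later sample of each pair.

    Velocity is computed between *successive valid* samples, bridging invalid
    gaps with the true elapsed time — otherwise a one-sample dropout at the
    moment of a saccade would hide the cross-AOI jump entirely.  NaN on
    invalid samples and on the first valid sample of the stream.
    """
    t = stream.time_ms.astype(float)
    xy = stream.xy
    mx, my = geom.mm_per_px
    v = np.full(len(t), np.nan)
    idx = np.flatnonzero(valid)
    if idx.size < 2:
        return v
    a, b = idx[:-1], idx[1:]
    dt = t[b] - t[a]
    dmm = (xy[b] - xy[a]) * np.array([mx, my])
    chord = np.hypot(dmm[:, 0], dmm[:, 1])
    angle = np.degrees(np.arctan(chord / geom.viewing_distance_mm))
    v[b] = angle / (dt / 1000.0)
    return v


# ---------------------------------------------------------------------------
# run helpers


def _runs(labels: np.ndarray) -> list[tuple[int, int, object]]:
    """Maximal runs of equal labels as (start, stop_exclusive, label)."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((start, i, labels[start]))
            start = i
    return out


def _sample_bounds(stream: GazeStream) -> np.ndarray:
    """edges[i] = start time of sample i's half-open cover; edges[n] = stream end."""
    t = stream.time_ms
    return np.append(t, stream.span_ms[1])


# ---------------------------------------------------------------------------
# classification


def detect_offscreen_looks(
    stream: GazeStream,
    min_invalid_ms: int = DEFAULT_MIN_OFFSCREEN_MS,
    validity_threshold: int = DEFAULT_VALIDITY_THRESHOLD,
) -> list[GazeEvent]:
    """Purposeful offscreen looks: maximal invalid runs spanning > *min_invalid_ms*.

    An infant turning its head away loses both eyes for the tracker, so a long
    run of invalid samples is read as a deliberate look away from the screen
    rather than noise; shorter runs stay ordinary gaps.
    """
    if min_invalid_ms <= 0:
        raise ConfigError("min_invalid_ms must be positive")
    valid = stream.valid_mask(validity_threshold)
    edges = _sample_bounds(stream)
    events = []
    for start, stop, lab in _runs(~valid):
        if not lab:
            continue
        t0, t1 = int(edges[start]), int(edges[stop])
        if t1 - t0 > min_invalid_ms:
            events.append(
                GazeEvent("offscreen", t0, t1, n_samples=stop - start)
            )
    return events


def classify_ivt(
    stream: GazeStream,
    geom: GeometryConfig,
    velocity_threshold_deg_s: float = DEFAULT_VELOCITY_THRESHOLD_DEG_S,
    min_fixation_ms: int = DEFAULT_MIN_FIXATION_MS,
    max_gap_fill_ms: int = DEFAULT_MAX_GAP_FILL_MS,
    validity_threshold: int = DEFAULT_VALIDITY_THRESHOLD,
    protected: Sequence[GazeEvent] = (),
) -> list[GazeEvent]:
    """I-VT classification into fixation/saccade/gap events tiling the stream.

    Valid samples are fixation material when their sample-to-sample angular
    velocity is below the threshold, saccade material otherwise.  Invalid runs
    no longer than ``max_gap_fill_ms`` that sit between fixation samples are
    interpolated into the surrounding fixation, except inside *protected*
    intervals (the offscreen looks).  Fixation runs shorter than
    ``min_fixation_ms`` are demoted to gaps.
    """
    if velocity_threshold_deg_s <= 0:
        raise ConfigError("velocity threshold must be positive")
    valid = stream.valid_mask(validity_threshold)
    n = len(stream)
    edges = _sample_bounds(stream)
    if not valid.any():
        logger.warning("%s: no valid samples; no events classified", stream.recording_id)
        return [GazeEvent("gap", *stream.span_ms, n_samples=n)]

    vel = _velocity_profile(stream, geom, valid)
    labels = np.full(n, "g", dtype=object)
    labels[valid & (vel < velocity_threshold_deg_s)] = "f"
    labels[valid & (vel >= velocity_threshold_deg_s)] = "s"
    # first valid sample of a run carries no velocity: inherit the next
    # sample's class when it is part of the same valid run, else fixation
    for i in np.flatnonzero(valid & np.isnan(vel)):
        if i + 1 < n and valid[i + 1] and not np.isnan(vel[i + 1]):
            labels[i] = labels[i + 1]
        else:
            labels[i] = "f"

    protected_mask = np.zeros(n, dtype=bool)
    for ev in protected:
        protected_mask |= (stream.time_ms >= ev.t_start_ms) & (
            stream.time_ms < ev.t_end_ms
        )

    # gap filling: short invalid runs strictly between fixation samples
    for start, stop, lab in _runs(labels):
        if lab != "g":
            continue
        if protected_mask[start:stop].any():
            continue
        span = edges[stop] - edges[start]
        if span > max_gap_fill_ms:
            continue
        left_fix = start > 0 and labels[start - 1] == "f"
        right_fix = stop < n and labels[stop] == "f"
        if left_fix and right_fix:
            labels[start:stop] = "F"  # filled: member of fixation, no coordinates

    # merge filled samples into fixation runs, then demote short fixations
    coalesce = np.where(labels == "F", "f", labels)
    for start, stop, lab in _runs(coalesce):
        if lab == "f" and edges[stop] - edges[start] < min_fixation_ms:
            coalesce[start:stop] = "g"
            labels[start:stop] = "g"

    events: list[GazeEvent] = []
    xy = stream.xy
    for start, stop, lab in _runs(coalesce):
        t0, t1 = int(edges[start]), int(edges[stop])
        member = np.arange(start, stop)
        if lab == "f":
            real = member[(labels[member] == "f") & valid[member]]
            pts = xy[real]
            centroid = tuple(pts.mean(axis=0))
            disp = float(np.max(np.hypot(*(pts - pts.mean(axis=0)).T))) if len(pts) else 0.0
            events.append(
                GazeEvent(
                    "fixation", t0, t1, centroid_px=centroid, dispersion_px=disp,
                    n_samples=len(real),
                )
            )
        elif lab == "s":
            peak = float(np.nanmax(vel[member])) if np.isfinite(vel[member]).any() else None
            events.append(
                GazeEvent("saccade", t0, t1, peak_velocity_deg_s=peak, n_samples=stop - start)
            )
        else:
            events.append(GazeEvent("gap", t0, t1, n_samples=stop - start))
    return events


def segment_stream(
    stream: GazeStream,
    geom: GeometryConfig,
    velocity_threshold_deg_s: float = DEFAULT_VELOCITY_THRESHOLD_DEG_S,
    min_fixation_ms: int = DEFAULT_MIN_FIXATION_MS,
    max_gap_fill_ms: int = DEFAULT_MAX_GAP_FILL_MS,
    min_offscreen_ms: int = DEFAULT_MIN_OFFSCREEN_MS,
    validity_threshold: int = DEFAULT_VALIDITY_THRESHOLD,
) -> list[GazeEvent]:
    """Full event segmentation: offscreen looks first, then I-VT around them.

    Returns a single ordered, non-overlapping event list tiling the stream
    span, with gap samples inside detected offscreen runs relabelled
    ``offscreen``.
    """
    offscreen = detect_offscreen_looks(stream, min_offscreen_ms, validity_threshold)
    base = classify_ivt(
        stream,
        geom,
        velocity_threshold_deg_s,
        min_fixation_ms,
        max_gap_fill_ms,
        validity_threshold,
        protected=offscreen,
    )
    # gap events are split at offscreen-run boundaries (a demoted
    # micro-fixation next to an aversion merges into the same gap event,
    # so plain relabelling would lose the offscreen span)
    off_spans = [(ev.t_start_ms, ev.t_end_ms) for ev in offscreen]
    out: list[GazeEvent] = []
    for ev in base:
        if ev.kind != "gap":
            out.append(ev)
            continue
        cursor = ev.t_start_ms
        for o0, o1 in off_spans:
            lo, hi = max(cursor, o0), min(ev.t_end_ms, o1)
            if lo >= hi:
                continue
            if lo > cursor:
                out.append(replace(ev, t_start_ms=cursor, t_end_ms=lo))
            out.append(replace(ev, kind="offscreen", t_start_ms=lo, t_end_ms=hi))
            cursor = hi
        if cursor < ev.t_end_ms:
            out.append(replace(ev, t_start_ms=cursor, t_end_ms=ev.t_end_ms))
    return out


# ---------------------------------------------------------------------------
# calibration offset


def apply_offset(stream: GazeStream, offset: CalibrationOffset) -> GazeStream:
    """Translate every coordinate by (dx, dy); validity codes untouched."""
    data = stream.data.copy()
    data["x_px"] = data["x_px"] + offset.dx_px
    data["y_px"] = data["y_px"] + offset.dy_px
    return replace(stream, data=data)


def estimate_offset(
    stream: GazeStream,
    tracks: Sequence,
    geom: GeometryConfig,
    search_px: int = 60,
    coarse_step_px: int = 4,
    events: Sequence[GazeEvent] | None = None,
) -> CalibrationOffset:
    """Estimate the constant calibration offset present in a stream.

    Fixation centroids are compared with the time-matched centres of the
    moving AOIs; the returned offset is the translation ``d`` minimising the
    mean distance from ``centroid - d`` to the nearest AOI centre, found by a
    coarse-to-fine grid search (deterministic).  Correct a stream with
    ``apply_offset(stream, estimate.negated())``.
    """
    from socialgaze.aoi import aoi_at  # local import: aoi depends on events

    if events is None:
        events = classify_ivt(stream, geom)
    fixations = [ev for ev in events if ev.kind == "fixation"]
    if not fixations:
        raise EstimationError("no fixations available for offset estimation")

    centroids, centers = [], []
    for ev in fixations:
        cs = []
        for track in tracks:
            shape = aoi_at(track, ev.t_mid_ms)
            if shape is not None:
                cs.append(shape.center_px)
        if cs:
            centroids.append(ev.centroid_px)
            centers.append(cs)
    if not centroids:
        raise EstimationError("no AOI track overlaps the stream in time")

    cents = np.asarray(centroids)  # (k, 2)
    maxc = max(len(c) for c in centers)
    padded = np.full((len(centers), maxc, 2), np.inf)
    for i, cs in enumerate(centers):
        padded[i, : len(cs)] = cs

    def cost(d: np.ndarray) -> float:
        shifted = cents - d  # (k, 2)
        dist = np.linalg.norm(padded - shifted[:, None, :], axis=2)
        return float(np.min(dist, axis=1).mean())

    def grid_search(center: np.ndarray, radius: int, step: int) -> np.ndarray:
        best, best_cost = center, cost(center)
        offsets = np.arange(-radius, radius + 1, step)
        for dx in offsets:
            for dy in offsets:
                d = center + np.array([dx, dy], dtype=float)
                c = cost(d)
                if c < best_cost - 1e-12:
                    best, best_cost = d, c
        return best

    coarse = grid_search(np.zeros(2), search_px, coarse_step_px)
    fine = grid_search(coarse, coarse_step_px, 1)
    return CalibrationOffset(float(fine[0]), float(fine[1]))
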