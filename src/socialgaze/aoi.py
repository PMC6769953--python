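"""Dynamic areas of interest, scanpath extraction, and pattern matching.

Each animated character (and the shared group resource) is a moving AOI
described by time-keyed shapes.  Fixation events are attributed to the AOI
whose padded shape contains the fixation centroid at the fixation's temporal
midpoint; consecutive same-AOI fixations collapse into a single *visit*, and
purposeful offscreen looks become visits to the virtual ``Offscreen`` AOI.
The resulting visit sequence (the scanpath) is the input to transition-matrix
and attentional-synchrony analyses.

Canonical AOI identifiers used throughout:
``Excluded``, ``Gatekeeper``, ``GroupMemberA``, ``GroupMemberB``,
``Resource``, ``Neutral`` and the virtual ``Offscreen``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from socialgaze.errors import ConfigError, DataError
from socialgaze.events import GazeEvent

logger = logging.getLogger(__name__)

OFFSCREEN = "Offscreen"
GROUP_AOIS = frozenset({"Gatekeeper", "GroupMemberA", "GroupMemberB"})

#: default padding per side, ~half the one-degree (40-50 px) AOI margin
DEFAULT_PADDING_PX = 20.0


@dataclass(frozen=True)
class AoiShape:
    """A rectangle or ellipse centred at ``center_px`` with full size ``size_px``."""

    kind: str  # "rectangle" | "ellipse"
    center_px: tuple[float, float]
    size_px: tuple[float, float]
    padding_px: float = DEFAULT_PADDING_PX

    def __post_init__(self) -> None:
        if self.kind not in ("rectangle", "ellipse"):
            raise ConfigError(f"unknown shape kind {self.kind!r}")
        if min(self.size_px) <= 0 or self.padding_px < 0:
            raise ConfigError("shape size must be positive, padding non-negative")

    def contains(self, x_px: float, y_px: float) -> bool:
        cx, cy = self.center_px
        hw = self.size_px[0] / 2.0 + self.padding_px
        hh = self.size_px[1] / 2.0 + self.padding_px
        if self.kind == "rectangle":
            return abs(x_px - cx) <= hw and abs(y_px - cy) <= hh
        return ((x_px - cx) / hw) ** 2 + ((y_px - cy) / hh) ** 2 <= 1.0


@dataclass(frozen=True)
class AoiTrack:
    """Time-keyed shapes for one AOI; keyframes interpolate per ``interpolation``."""

    aoi_id: str
    keyframes: tuple[tuple[int, AoiShape], ...]
    interpolation: str = "linear"  # "step" | "linear"

    def __post_init__(self) -> None:
        if not self.keyframes:
            raise ConfigError(f"track {self.aoi_id}: no keyframes")
        times = [t for t, _ in self.keyframes]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ConfigError(f"track {self.aoi_id}: keyframe times not increasing")
        if self.interpolation not in ("step", "linear"):
            raise ConfigError(f"unknown interpolation {self.interpolation!r}")

    @property
    def span_ms(self) -> tuple[int, int]:
        return self.keyframes[0][0], self.keyframes[-1][0]


def aoi_at(track: AoiTrack, t_ms: float) -> AoiShape | None:
    """Shape of *track* at time *t_ms*, or None outside the keyframe span."""
    times = [t for t, _ in track.keyframes]
    if t_ms < times[0] or t_ms > times[-1]:
        return None
    idx = int(np.searchsorted(times, t_ms, side="right")) - 1
    t0, s0 = track.keyframes[idx]
    if idx == len(track.keyframes) - 1 or track.interpolation == "step":
        return s0
    t1, s1 = track.keyframes[idx + 1]
    w = (t_ms - t0) / (t1 - t0)
    lerp = lambda a, b: tuple((1 - w) * np.asarray(a) + w * np.asarray(b))
    return AoiShape(
        kind=s0.kind,
        center_px=lerp(s0.center_px, s1.center_px),
        size_px=lerp(s0.size_px, s1.size_px),
        padding_px=(1 - w) * s0.padding_px + w * s1.padding_px,
    )


def hit_test(
    point_px: tuple[float, float],
    tracks: Sequence[AoiTrack],
    t_ms: float,
    tie_rule: str = "nearest_center",
) -> str | None:
    """AOI containing *point_px* at *t_ms* (padding included); ties -> nearest centre."""
    if tie_rule != "nearest_center":
        raise ConfigError(f"unknown tie rule {tie_rule!r}")
    hits = []
    for track in tracks:
        shape = aoi_at(track, t_ms)
        if shape is not None and shape.contains(*point_px):
            d = math.dist(point_px, shape.center_px)
            hits.append((d, track.aoi_id))
    if not hits:
        return None
    return min(hits)[1]


# ---------------------------------------------------------------------------
# scanpaths


@dataclass(frozen=True)
class ScanpathVisit:
    """One collapsed dwell on a single AOI (or the virtual Offscreen AOI)."""

    aoi_id: str
    t_start_ms: int
    t_end_ms: int
    n_fixations: int = 1
    total_fixation_ms: int = 0

    def __post_init__(self) -> None:
        if self.t_end_ms <= self.t_start_ms:
            raise DataError(f"visit with non-positive duration: {self}")


@dataclass
class ScanpathSequence:
    """Ordered AOI visits for one trial; consecutive visits differ in AOI."""

    visits: list[ScanpathVisit] = field(default_factory=list)
    n_unlabeled_fixations: int = 0
    trial_id: str = ""

    def __post_init__(self) -> None:
        for a, b in zip(self.visits, self.visits[1:]):
            if a.aoi_id == b.aoi_id:
                raise DataError(
                    f"consecutive visits share AOI {a.aoi_id!r} in {self.trial_id}"
                )

    @property
    def labels(self) -> list[str]:
        return [v.aoi_id for v in self.visits]

    def onscreen(self) -> "ScanpathSequence":
        """Copy without Offscreen visits, re-collapsing adjacent duplicates."""
        kept = [v for v in self.visits if v.aoi_id != OFFSCREEN]
        collapsed: list[ScanpathVisit] = []
        for v in kept:
            if collapsed and collapsed[-1].aoi_id == v.aoi_id:
                prev = collapsed[-1]
                collapsed[-1] = ScanpathVisit(
                    prev.aoi_id,
                    prev.t_start_ms,
                    v.t_end_ms,
                    prev.n_fixations + v.n_fixations,
                    prev.total_fixation_ms + v.total_fixation_ms,
                )
            else:
                collapsed.append(v)
        return ScanpathSequence(
            collapsed, self.n_unlabeled_fixations, self.trial_id
        )

    def restrict(self, t_start_ms: int, t_end_ms: int) -> "ScanpathSequence":
        """Visits overlapping the half-open window (bounds left untouched)."""
        kept = [
            v
            for v in self.visits
            if v.t_end_ms > t_start_ms and v.t_start_ms < t_end_ms
        ]
        return ScanpathSequence(kept, self.n_unlabeled_fixations, self.trial_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (v.aoi_id, v.t_start_ms, v.t_end_ms, v.n_fixations, v.total_fixation_ms)
                for v in self.visits
            ],
            columns=["aoi", "start_ms", "end_ms", "n_fixations", "fixation_ms"],
        )


def extract_scanpath(
    events: Sequence[GazeEvent],
    tracks: Sequence[AoiTrack],
    trial_id: str = "",
) -> ScanpathSequence:
    """Label fixations with AOIs and collapse them into a visit sequence.

    Fixations are attributed by hit-testing the centroid at the fixation's
    temporal midpoint; offscreen events become ``Offscreen`` visits; fixations
    landing on no AOI are counted but emit no visit.
    """
    labelled: list[tuple[str, GazeEvent]] = []
    n_unlabeled = 0
    for ev in events:
        if ev.kind == "fixation":
            aoi = hit_test(ev.centroid_px, tracks, ev.t_mid_ms)
            if aoi is None:
                n_unlabeled += 1
                logger.debug("unlabeled fixation at %s ms", ev.t_start_ms)
            else:
                labelled.append((aoi, ev))
        elif ev.kind == "offscreen":
            labelled.append((OFFSCREEN, ev))

    visits: list[ScanpathVisit] = []
    for aoi, ev in labelled:
        fix_ms = ev.duration_ms if ev.kind == "fixation" else 0
        n_fix = 1 if ev.kind == "fixation" else 0
        if visits and visits[-1].aoi_id == aoi:
            prev = visits[-1]
            visits[-1] = ScanpathVisit(
                aoi,
                prev.t_start_ms,
                ev.t_end_ms,
                prev.n_fixations + n_fix,
                prev.total_fixation_ms + fix_ms,
            )
        else:
            visits.append(
                ScanpathVisit(aoi, ev.t_start_ms, ev.t_end_ms, n_fix, fix_ms)
            )
    return ScanpathSequence(visits, n_unlabeled, trial_id)


# ---------------------------------------------------------------------------
# pattern matching


@dataclass(frozen=True)
class PatternTemplate:
    """A scanpath pattern: ordered steps (subsequence) or an unordered step set.

    Each step is a set of acceptable AOI ids (e.g. the whole group counts as
    one step).  Ordered templates match as a subsequence of visits whose first
    and last matched visit starts lie within ``max_span_ms``; unordered
    templates match when every step set is visited inside the window.
    """

    steps: tuple[frozenset, ...]
    ordered: bool = True
    max_span_ms: int | None = 4000
    window: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if len(self.steps) < 2:
            raise ConfigError("a pattern needs at least two steps")

    @staticmethod
    def make(steps: Iterable[Iterable[str] | str], ordered: bool = True, **kw) -> "PatternTemplate":
        norm = tuple(
            frozenset([s]) if isinstance(s, str) else frozenset(s) for s in steps
        )
        return PatternTemplate(norm, ordered=ordered, **kw)


#: individual character -> any group character -> back to the individual
ENTRY_SYNCHRONY_PATTERN = PatternTemplate.make(
    ["Excluded", GROUP_AOIS, "Excluded"], ordered=True
)


def match_pattern(
    seq: ScanpathSequence, tpl: PatternTemplate
) -> list[tuple[int, int]]:
    """Non-overlapping, leftmost-first matches of *tpl* in *seq*.

    Returns (first_visit_index, last_visit_index) spans, inclusive.
    """
    visits = seq.visits
    if tpl.window is not None:
        lo, hi = tpl.window
        idx = [
            i
            for i, v in enumerate(visits)
            if v.t_end_ms > lo and v.t_start_ms < hi
        ]
    else:
        idx = list(range(len(visits)))

    matches: list[tuple[int, int]] = []
    if tpl.ordered:
        pos = 0
        while pos < len(idx):
            first = None
            step_i = 0
            last = None
            for j in idx[pos:]:
                v = visits[j]
                if v.aoi_id in tpl.steps[step_i]:
                    if first is None:
                        first = j
                    elif (
                        tpl.max_span_ms is not None
                        and v.t_start_ms - visits[first].t_start_ms > tpl.max_span_ms
                    ):
                        break  # span blown: restart search after `first`
                    last = j
                    step_i += 1
                    if step_i == len(tpl.steps):
                        break
            if step_i == len(tpl.steps):
                matches.append((first, last))
                pos = idx.index(last) + 1
            else:
                if first is None:
                    break
                pos = idx.index(first) + 1
    else:
        hit_steps = [
            any(visits[j].aoi_id in step for j in idx) for step in tpl.steps
        ]
        if all(hit_steps):
            touched = [
                j for j in idx if any(visits[j].aoi_id in s for s in tpl.steps)
            ]
            matches.append((min(touched), max(touched)))
    return matches


def synchrony_summary(
    cohort: Sequence[tuple[object, Sequence[ScanpathSequence]]],
    tpl: PatternTemplate,
) -> pd.DataFrame:
    """Per-trial template matches across a cohort, plus the matching fraction.

    ``cohort`` pairs each session record with its trial scanpaths.  Returns a
    table with one row per trial and a ``matched`` flag; the fraction of
    matching trials is stored in ``frame.attrs["fraction"]``.
    """
    rows = []
    for session, seqs in cohort:
        infant = getattr(session, "infant_id", str(session))
        for seq in seqs:
            n = len(match_pattern(seq, tpl))
            rows.append((infant, seq.trial_id, n, n > 0))
    if not rows:
        raise DataError("synchrony summary needs at least one trial")
    frame = pd.DataFrame(rows, columns=["infant_id", "trial_id", "n_matches", "matched"])
    frame.attrs["fraction"] = float(frame["matched"].mean())
    frame.attrs["n_trials"] = len(frame)
    frame.attrs["n_matched"] = int(frame["matched"].sum())
    return frame


def aversion_contingency(
    sequences: Sequence[ScanpathSequence], prior_aoi: str = "Gatekeeper"
) -> float:
    """Rate of offscreen looks immediately preceded by a visit to *prior_aoi*.

    The count of Offscreen visits whose immediate predecessor is *prior_aoi*,
    divided by the number of trials.
    """
    if not sequences:
        raise DataError("no sequences supplied")
    count = 0
    for seq in sequences:
        labels = seq.labels
        count += sum(
            1
            for prev, cur in zip(labels, labels[1:])
            if cur == OFFSCREEN and prev == prior_aoi
        )
    return count / len(sequences)


def aversion_ratio(
    sequences_a: Sequence[ScanpathSequence],
    sequences_b: Sequence[ScanpathSequence],
    prior_aoi: str = "Gatekeeper",
) -> float:
    """Between-condition ratio of aversion rates (NaN when the divisor is 0)."""
    rate_a = aversion_contingency(sequences_a, prior_aoi)
    rate_b = aversion_contingency(sequences_b, prior_aoi)
    if rate_b == 0:
        logger.warning("aversion ratio undefined: zero rate in comparison group")
        return float("nan")
    return rate_a / rate_b


# ---------------------------------------------------------------------------
# JSON track (de)serialisation


def tracks_to_json(tracks: Sequence[AoiTrack], path: str | Path) -> None:
    doc = [
        {
            "aoi_id": tr.aoi_id,
            "interpolation": tr.interpolation,
            "keyframes": [
                {
                    "time_ms": t,
                    "kind": s.kind,
                    "center_px": list(s.center_px),
                    "size_px": list(s.size_px),
                    "padding_px": s.padding_px,
                }
                for t, s in tr.keyframes
            ],
        }
        for tr in tracks
    ]
    Path(path).write_text(json.dumps(doc, indent=2))


def tracks_from_json(path: str | Path) -> list[AoiTrack]:
    doc = json.loads(Path(path).read_text())
    return [
        AoiTrack(
            aoi_id=entry["aoi_id"],
            interpolation=entry.get("interpolation", "linear"),
            keyframes=tuple(
                (
                    int(kf["time_ms"]),
                    AoiShape(
                        kind=kf["kind"],
                        center_px=tuple(kf["center_px"]),
                        size_px=tuple(kf["size_px"]),
                        padding_px=float(kf.get("padding_px", DEFAULT_PADDING_PX)),
                    ),
                )
                for kf in entry["keyframes"]
            ),
        )
        for entry in doc
    ]
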