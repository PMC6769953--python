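"""Windowed looking-time metrics.

Three families of per-trial measures:

* **fixation-duration proportions** — time fixating each AOI divided by the
  total time fixating any AOI within an analysis window.  The ratio removes
  between-infant differences in overall attention and tracking quality.
* **first look** — the earliest AOI hit of any kind (a single valid sample
  counts, so saccadic glances are included) inside a window.
* **violation-of-expectation (VOE) looking time** — total looking after a
  scripted reference point (the neutral character arriving at its destination
  at 24,000 ms), with purposeful offscreen time subtracted and observation
  stopping at the onset of the infant's third offscreen look after the
  reference point (the infant is allowed to look away twice).  Looking times
  are compared on a log scale (natural log by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from socialgaze.aoi import AoiTrack, ScanpathSequence, hit_test
from socialgaze.errors import ConfigError, DataError
from socialgaze.events import GazeEvent
from socialgaze.gaze_io import DEFAULT_VALIDITY_THRESHOLD, GazeStream

logger = logging.getLogger(__name__)

VOE_ONSET_MS = 24_000
VOE_MAX_OFFSCREEN_LOOKS = 2


@dataclass(frozen=True)
class AnalysisWindow:
    """Half-open time window relative to trial onset."""

    label: str  # whole_trial | post_exclusion | end_scene | test_critical | voe
    t_start_ms: int
    t_end_ms: int

    def __post_init__(self) -> None:
        if self.t_start_ms >= self.t_end_ms:
            raise ConfigError(f"window {self.label}: start must precede end")

    def clip(self, t0: int, t1: int) -> int:
        """Overlap in ms between [t0, t1) and this window."""
        return max(0, min(t1, self.t_end_ms) - max(t0, self.t_start_ms))


@dataclass(frozen=True)
class FirstLook:
    aoi_id: str
    t_ms: int
    hit_kind: str  # "saccadic" | "fixation"


@dataclass(frozen=True)
class VoeResult:
    looking_ms: float
    log_looking: float | None
    n_offscreen_used: int
    span_end_ms: int


def proportion_fixation(
    events: Sequence[GazeEvent],
    seq: ScanpathSequence,
    window: AnalysisWindow,
    aois: Sequence[str],
) -> dict[str, float] | None:
    """Per-AOI share of fixation time within *window* (None when nothing on-AOI).

    Visit fixation time is clipped to the window, so a fixation straddling the
    boundary contributes only its in-window part.  Shares are over the tracked
    AOIs only and sum to 1.
    """
    del events  # the visit sequence already carries per-AOI fixation time
    totals = {a: 0.0 for a in aois}
    for v in seq.visits:
        if v.aoi_id not in totals or v.n_fixations == 0:
            continue
        overlap = window.clip(v.t_start_ms, v.t_end_ms)
        if overlap <= 0:
            continue
        # fixation time inside the window, assuming fixations spread evenly
        # across the visit (exact when the visit is a single fixation)
        totals[v.aoi_id] += v.total_fixation_ms * overlap / (v.t_end_ms - v.t_start_ms)
    grand = sum(totals.values())
    if grand <= 0:
        logger.info("no on-AOI fixation time in window %s", window.label)
        return None
    return {a: t / grand for a, t in totals.items()}


def proportion_table(
    rows: Sequence[tuple[str, str, dict[str, float] | None]],
    aois: Sequence[str],
) -> pd.DataFrame:
    """Group means/SDs/95% CIs shaped like the published proportion tables.

    ``rows`` holds (infant_id, group_label, proportions) with None marking an
    infant excluded for lack of on-AOI time.
    """
    records = []
    for infant_id, group, props in rows:
        if props is None:
            continue
        records.append({"infant_id": infant_id, "group": group, **props})
    if not records:
        raise DataError("no infants contributed on-AOI fixation time")
    per_infant = pd.DataFrame(records)
    out = []
    for aoi in aois:
        for group, chunk in per_infant.groupby("group"):
            vals = chunk[aoi].to_numpy(dtype=float)
            n = len(vals)
            mean = float(vals.mean())
            sd = float(vals.std(ddof=1)) if n > 1 else 0.0
            sem = sd / math.sqrt(n) if n > 1 else 0.0
            out.append(
                {
                    "character": aoi,
                    "group": group,
                    "n": n,
                    "mean": round(mean, 3),
                    "sd": round(sd, 3),
                    "ci_low": round(mean - 1.96 * sem, 3),
                    "ci_high": round(mean + 1.96 * sem, 3),
                }
            )
    return pd.DataFrame(out)


def first_look(
    stream: GazeStream,
    events: Sequence[GazeEvent],
    window: AnalysisWindow,
    tracks: Sequence[AoiTrack],
    validity_threshold: int = DEFAULT_VALIDITY_THRESHOLD,
) -> FirstLook | None:
    """Earliest AOI hit of any kind inside *window* (sample-level).

    Any valid sample landing on an AOI counts, so a saccadic sweep across a
    character registers; the hit is labelled ``fixation`` when it falls inside
    a classified fixation event, ``saccadic`` otherwise.
    """
    t = stream.time_ms
    sel = (t >= window.t_start_ms) & (t < window.t_end_ms) & stream.valid_mask(
        validity_threshold
    )
    xy = stream.xy
    fixation_spans = [
        (ev.t_start_ms, ev.t_end_ms) for ev in events if ev.kind == "fixation"
    ]
    for i in np.flatnonzero(sel):
        aoi = hit_test(tuple(xy[i]), tracks, float(t[i]))
        if aoi is None:
            continue
        in_fix = any(a <= t[i] < b for a, b in fixation_spans)
        return FirstLook(aoi, int(t[i]), "fixation" if in_fix else "saccadic")
    return None


def voe_looking_time(
    stream: GazeStream,
    events: Sequence[GazeEvent],
    offscreen_events: Sequence[GazeEvent],
    t0_ms: int = VOE_ONSET_MS,
    stop_after_offscreen: int = VOE_MAX_OFFSCREEN_LOOKS,
    log_base: str = "natural",
) -> VoeResult:
    """Looking time after *t0_ms* with offscreen subtraction and a stopping rule.

    Observation runs from ``t0_ms`` to the trial end or to the onset of the
    ``stop_after_offscreen + 1``-th offscreen look after ``t0_ms``, whichever
    comes first.  Offscreen time inside that span is subtracted; the result is
    reported raw and log-transformed (log undefined at zero looking, flagged
    as ``None``).
    """
    del events
    span_start, span_end = stream.span_ms
    if span_end <= t0_ms:
        raise DataError(f"trial ends at {span_end} ms, before the {t0_ms} ms onset")
    after = sorted(
        (ev for ev in offscreen_events if ev.t_end_ms > t0_ms),
        key=lambda ev: ev.t_start_ms,
    )
    end = span_end
    if len(after) > stop_after_offscreen:
        end = max(t0_ms, after[stop_after_offscreen].t_start_ms)
    used = [ev for ev in after if ev.t_start_ms < end]
    offscreen_ms = sum(
        max(0, min(ev.t_end_ms, end) - max(ev.t_start_ms, t0_ms)) for ev in used
    )
    looking = float((end - t0_ms) - offscreen_ms)
    if looking > 0:
        log_val = math.log(looking) if log_base == "natural" else math.log10(looking)
    else:
        logger.warning("%s: zero looking time after %d ms", stream.recording_id, t0_ms)
        log_val = None
    return VoeResult(looking, log_val, len(used), int(end))
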