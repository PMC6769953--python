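"""Reading, writing and segmenting raw gaze recordings.

A recording is a stream of 60 Hz samples: timestamp in milliseconds, screen
coordinates in pixels (origin top-left, y down), and one ordinal validity code
per eye (0 = tracked perfectly, 4 = eye not found; codes 0-1 count as valid by
default).  Two delimited-text dialects are supported:

``vendor-tsv``
    Tab-separated with header ``RecordingTimestamp  GazePointX  GazePointY
    ValidityLeft  ValidityRight`` — the shape of a vendor raw-data export.
``simple-csv``
    Comma-separated with header ``time_ms,x_px,y_px,vl,vr``.

Streams are stored column-wise in a :class:`pandas.DataFrame`; the
:class:`GazeSample` record view exists for ergonomic row access and tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

from socialgaze.errors import ConfigError, DataError, FormatError

logger = logging.getLogger(__name__)

#: validity codes <= this value count as "eye tracked" unless overridden
DEFAULT_VALIDITY_THRESHOLD = 1

_COLUMNS = ["time_ms", "x_px", "y_px", "validity_left", "validity_right"]

_DIALECTS = {
    "vendor-tsv": {
        "sep": "\t",
        "names": {
            "RecordingTimestamp": "time_ms",
            "GazePointX": "x_px",
            "GazePointY": "y_px",
            "ValidityLeft": "validity_left",
            "ValidityRight": "validity_right",
        },
    },
    "simple-csv": {
        "sep": ",",
        "names": {
            "time_ms": "time_ms",
            "x_px": "x_px",
            "y_px": "y_px",
            "vl": "validity_left",
            "vr": "validity_right",
        },
    },
}


class GazeSample(NamedTuple):
    """One 60 Hz gaze sample (screen pixels, origin top-left, y down)."""

    time_ms: int
    x_px: float
    y_px: float
    validity_left: int
    validity_right: int

    def is_valid(self, threshold: int = DEFAULT_VALIDITY_THRESHOLD) -> bool:
        """True when at least one eye is tracked at or below *threshold*."""
        return min(self.validity_left, self.validity_right) <= threshold


@dataclass
class GazeStream:
    """An ordered gaze recording plus its screen geometry.

    ``data`` holds one row per sample with columns ``time_ms`` (int), ``x_px``,
    ``y_px`` (float; NaN allowed for untracked samples) and the two integer
    validity codes.  Timestamps are strictly increasing.
    """

    data: pd.DataFrame
    recording_id: str = "unnamed"
    geometry: object | None = None  # GeometryConfig; typed loosely to avoid a cycle

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"stream missing columns: {missing}")
        if len(self.data) == 0:
            raise DataError("empty gaze stream")
        t = self.data["time_ms"].to_numpy()
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            raise DataError(
                f"non-monotonic timestamp at row {bad[0] + 2}: "
                f"{t[bad[0] + 1]} after {t[bad[0]]}"
            )
        self.data = self.data.reset_index(drop=True)

    # -- array views ------------------------------------------------------
    @property
    def time_ms(self) -> np.ndarray:
        return self.data["time_ms"].to_numpy(dtype=np.int64)

    @property
    def xy(self) -> np.ndarray:
        return self.data[["x_px", "y_px"]].to_numpy(dtype=float)

    def valid_mask(self, threshold: int = DEFAULT_VALIDITY_THRESHOLD) -> np.ndarray:
        """Boolean mask of samples with at least one eye at/below *threshold*.

        Coordinates must additionally be finite for a sample to be usable.
        """
        vl = self.data["validity_left"].to_numpy()
        vr = self.data["validity_right"].to_numpy()
        finite = np.isfinite(self.xy).all(axis=1)
        return (np.minimum(vl, vr) <= threshold) & finite

    @property
    def nominal_dt_ms(self) -> float:
        """Median inter-sample interval (≈ 1000/60 ms for a 60 Hz stream)."""
        t = self.time_ms
        if len(t) < 2:
            return 1000.0 / 60.0
        return float(np.median(np.diff(t)))

    @property
    def span_ms(self) -> tuple[int, int]:
        """Half-open [start, end) span: last sample extends one nominal dt."""
        t = self.time_ms
        return int(t[0]), int(t[-1] + round(self.nominal_dt_ms))

    def __len__(self) -> int:
        return len(self.data)

    def __iter__(self) -> Iterator[GazeSample]:
        for row in self.data.itertuples(index=False):
            yield GazeSample(
                int(row.time_ms),
                float(row.x_px),
                float(row.y_px),
                int(row.validity_left),
                int(row.validity_right),
            )

    def slice_time(self, t_start_ms: int, t_end_ms: int) -> "GazeStream":
        """Samples with t_start <= time < t_end (times left absolute)."""
        t = self.time_ms
        sel = (t >= t_start_ms) & (t < t_end_ms)
        if not sel.any():
            raise DataError(
                f"no samples in [{t_start_ms}, {t_end_ms}) of {self.recording_id}"
            )
        return replace(self, data=self.data.loc[sel].reset_index(drop=True))

    @classmethod
    def from_samples(
        cls,
        samples: Sequence[GazeSample],
        recording_id: str = "unnamed",
        geometry: object | None = None,
    ) -> "GazeStream":
        frame = pd.DataFrame(samples, columns=_COLUMNS)
        return cls(frame, recording_id=recording_id, geometry=geometry)


@dataclass
class TrialRecord:
    """One scheduled stimulus presentation within a recording.

    Bounds are half-open on the stream clock.  ``critical_event_seen`` records
    whether the infant attended the scene's critical moment (the exclusion
    event, or the test trial's anticipation window).
    """

    infant_id: str
    experiment: int
    condition: str  # "explicit" | "implicit"
    trial_index: int
    scene_type: str  # "acceptance" | "exclusion" | "end_scene" | "test"
    t_start_ms: int
    t_end_ms: int
    critical_event_seen: bool = True

    def __post_init__(self) -> None:
        if self.t_start_ms >= self.t_end_ms:
            raise ConfigError(
                f"trial bounds reversed: [{self.t_start_ms}, {self.t_end_ms})"
            )

    @property
    def duration_ms(self) -> int:
        return self.t_end_ms - self.t_start_ms


@dataclass
class SessionRecord:
    """One infant's session: trial bookkeeping and recorded outcomes.

    ``choice_outcome`` (preferential reaching) is populated only for
    experiment 1; ``anticipation_first_direction`` and ``voe_direction`` only
    for experiment 2.  ``flags`` carries coder-supplied exclusion metadata
    (``fussiness``, ``technical``, ``both_reach``, ``lunge_grab``,
    ``no_reach``, ``color_preference``).
    """

    infant_id: str
    age_days: int
    experiment: int
    condition: str
    trials: list[TrialRecord] = field(default_factory=list)
    choice_outcome: str = "none"  # "excluded" | "gatekeeper" | "none"
    anticipation_first_direction: str = "none"  # "excluded" | "group" | "none"
    voe_direction: str = "none"  # "excluded" | "group" | "none"
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.experiment == 1 and (
            self.anticipation_first_direction != "none" or self.voe_direction != "none"
        ):
            raise ConfigError("anticipation/VOE outcomes are experiment-2 only")
        if self.experiment == 2 and self.choice_outcome != "none":
            raise ConfigError("reaching choice outcome is experiment-1 only")

    def trials_of(self, scene_type: str) -> list[TrialRecord]:
        return [t for t in self.trials if t.scene_type == scene_type]


# ---------------------------------------------------------------------------
# file I/O


def read_gaze_export(
    path: str | Path, dialect: str = "vendor-tsv", recording_id: str | None = None
) -> GazeStream:
    """Parse a delimited gaze export into a :class:`GazeStream`.

    Malformed rows (non-numeric fields) are counted and logged, never silently
    dropped.  A missing required column raises :class:`FormatError`; a
    timestamp that does not strictly increase raises :class:`DataError` naming
    the first offending row.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ConfigError(f"unknown dialect {dialect!r}")
    spec = _DIALECTS[dialect]
    frame = pd.read_csv(path, sep=spec["sep"], dtype=str)
    missing = [c for c in spec["names"] if c not in frame.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")
    frame = frame.rename(columns=spec["names"])[_COLUMNS]

    numeric = frame.apply(pd.to_numeric, errors="coerce")
    # a row is malformed when a validity/time field failed to parse;
    # coordinates may legitimately be empty for untracked samples
    malformed = (
        numeric["time_ms"].isna()
        | numeric["validity_left"].isna()
        | numeric["validity_right"].isna()
    )
    n_bad = int(malformed.sum())
    if n_bad:
        logger.warning("%s: dropped %d malformed rows", path.name, n_bad)
        numeric = numeric.loc[~malformed]
    numeric = numeric.astype(
        {"time_ms": np.int64, "validity_left": np.int64, "validity_right": np.int64}
    )
    return GazeStream(
        numeric.reset_index(drop=True), recording_id=recording_id or path.stem
    )


def write_gaze_export(stream: GazeStream, path: str | Path, dialect: str = "vendor-tsv") -> None:
    """Write a stream back out in one of the supported dialects (lossless)."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ConfigError(f"unknown dialect {dialect!r}")
    spec = _DIALECTS[dialect]
    inverse = {v: k for k, v in spec["names"].items()}
    out = stream.data[_COLUMNS].rename(columns=inverse)
    out.to_csv(path, sep=spec["sep"], index=False)


def segment_trials(
    stream: GazeStream,
    schedule: Sequence[tuple[str, int, int]],
    infant_id: str = "unknown",
    experiment: int = 1,
    condition: str = "explicit",
) -> list[TrialRecord]:
    """Cut a continuous recording into trials per a (scene, onset, duration) schedule.

    Intervals are half-open ``[onset, onset + duration)`` on the stream clock
    and must be pairwise disjoint and inside the stream span; samples between
    entries are inter-trial (attention-grabber) time and belong to no trial.
    """
    entries = sorted(schedule, key=lambda e: e[1])
    span_start, span_end = stream.span_ms
    prev_end = None
    trials: list[TrialRecord] = []
    for idx, (scene_type, onset_ms, duration_ms) in enumerate(entries, start=1):
        if duration_ms <= 0:
            raise ConfigError(f"schedule entry {idx}: non-positive duration")
        end = onset_ms + duration_ms
        if prev_end is not None and onset_ms < prev_end:
            raise ConfigError(f"schedule entry {idx} overlaps the previous entry")
        if onset_ms < span_start or end > span_end:
            raise ConfigError(
                f"schedule entry {idx} [{onset_ms}, {end}) outside stream span "
                f"[{span_start}, {span_end})"
            )
        prev_end = end
        trials.append(
            TrialRecord(
                infant_id=infant_id,
                experiment=experiment,
                condition=condition,
                trial_index=idx,
                scene_type=scene_type,
                t_start_ms=onset_ms,
                t_end_ms=end,
            )
        )
    return trials


def write_report(
    tables: dict[str, pd.DataFrame], path: str | Path, format: str = "csv"
) -> None:
    """Write named result tables to *path* (a directory for csv, a file for json).

    Column order is preserved as given, so reruns are byte-identical.
    """
    if not tables:
        raise ConfigError("no tables to write")
    path = Path(path)
    if format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        for name, table in tables.items():
            table.to_csv(path / f"{name}.csv", index=False)
    elif format == "json":
        payload = {
            name: json.loads(table.to_json(orient="table", index=False))
            for name, table in tables.items()
        }
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
    else:
        raise ConfigError(f"unknown report format {format!r}")


def read_report(path: str | Path, format: str = "json") -> dict[str, pd.DataFrame]:
    """Inverse of :func:`write_report` for the json format."""
    if format != "json":
        raise ConfigError("only the json format round-trips through read_report")
    payload = json.loads(Path(path).read_text())
    return {
        name: pd.DataFrame(doc["data"], columns=[f["name"] for f in doc["schema"]["fields"]])
        for name, doc in payload.items()
    }
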