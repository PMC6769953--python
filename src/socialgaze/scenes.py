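"""Deterministic scene scripts for the animated social-exclusion stimuli.

Each 48 s familiarization scene shows a three-character group (the outermost
member is the *gatekeeper*), a shared resource below the group, and an
individual character who enters, approaches, and attempts a call-response
exchange.  In the *acceptance* scene the group responds and everyone bounces
in synchrony; in the *explicit exclusion* scene the gatekeeper physically
pushes the individual away; in the *implicit* variant the gatekeeper simply
ignores it, and the individual retreats by itself.  A final 8 s static end
scene shows only the excluded character and the gatekeeper.  Experiment 2
adds a neutral background character to every scene and replaces the end scene
with a test trial in which the neutral character descends the stage and moves
toward either the excluded character or the group, arriving (with a bell) at
24,000 ms.

Scripts are rendered as dynamic AOI tracks with piecewise-linear keyframes in
screen coordinates, plus named event markers; the event order and the timing
anchors (48 s trim, 8 s end scene, 24 s arrival, 300-1000 ms event offsets)
are fixed, while the exact trajectories are this package's own invention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from socialgaze.aoi import AoiShape, AoiTrack
from socialgaze.errors import ConfigError
from socialgaze.events import GEOMETRY_17IN_1280x1024, GeometryConfig

FAMILIARIZATION_MS = 48_000
END_SCENE_MS = 8_000
TEST_SCENE_MS = 40_000
ARRIVAL_MS = 24_000
STIMULUS_PX = (1280, 720)

#: character body size in stimulus pixels
CHARACTER_SIZE = (110.0, 140.0)
RESOURCE_SIZE = (140.0, 90.0)

#: counterbalanced colour assignments for the two exclusion-scene principals
COLOR_SCHEMES = (
    {"Excluded": "turquoise", "Gatekeeper": "purple"},
    {"Excluded": "purple", "Gatekeeper": "turquoise"},
)

SCENE_TYPES = ("acceptance", "explicit_exclusion", "implicit_exclusion", "end_scene", "test")


@dataclass(frozen=True)
class SceneScript:
    """A fully specified stimulus scene: AOI tracks plus event markers."""

    scene_type: str
    condition: str
    experiment: int
    duration_ms: int
    tracks: tuple[AoiTrack, ...]
    markers: dict[str, int] = field(default_factory=dict)
    colors: dict[str, str] = field(default_factory=dict)
    resolution: tuple[int, int] = STIMULUS_PX

    @property
    def aoi_ids(self) -> tuple[str, ...]:
        return tuple(t.aoi_id for t in self.tracks)

    @property
    def critical_window(self) -> tuple[int, int] | None:
        """Anticipation window of the test scene (descent start to arrival)."""
        if self.scene_type != "test":
            return None
        return self.markers["neutral_descent"], self.markers["arrival"]

    @property
    def exclusion_event_end_ms(self) -> int | None:
        """End of the push/ignore event; start of the post-exclusion window."""
        for key in ("push", "ignore"):
            if key in self.markers:
                return self.markers[key] + 2_000
        return None

    def track(self, aoi_id: str) -> AoiTrack:
        for t in self.tracks:
            if t.aoi_id == aoi_id:
                return t
        raise KeyError(aoi_id)


def _static(aoi_id, center, size, duration, origin) -> AoiTrack:
    cx, cy = origin[0] + center[0], origin[1] + center[1]
    shape = AoiShape("ellipse", (cx, cy), size)
    return AoiTrack(aoi_id, ((0, shape), (duration, shape)))


def _moving(aoi_id, waypoints, size, duration, origin) -> AoiTrack:
    # waypoints: ordered (time_ms, (x, y)) in stimulus coordinates; the track
    # is held at the first/last position to span the whole scene
    pts = list(waypoints)
    if pts[0][0] > 0:
        pts.insert(0, (0, pts[0][1]))
    if pts[-1][0] < duration:
        pts.append((duration, pts[-1][1]))
    frames = tuple(
        (t, AoiShape("ellipse", (origin[0] + x, origin[1] + y), size))
        for t, (x, y) in pts
    )
    return AoiTrack(aoi_id, frames, interpolation="linear")


def build_scene_script(
    scene_type: str,
    condition: str = "explicit",
    counterbalance: int = 0,
    experiment: int = 1,
    geometry: GeometryConfig = GEOMETRY_17IN_1280x1024,
) -> SceneScript:
    """Construct the deterministic script for one scene.

    ``counterbalance`` (0/1) flips the colour assignment of the two exclusion
    principals.  Requesting the test scene for experiment 1 is an error (it
    exists only in the anticipatory-looking design), as is an end scene for
    experiment 2.
    """
    if scene_type not in SCENE_TYPES and scene_type != "exclusion":
        raise ConfigError(f"unknown scene type {scene_type!r}")
    if condition not in ("explicit", "implicit"):
        raise ConfigError(f"unknown condition {condition!r}")
    if scene_type == "exclusion":  # convenience alias
        scene_type = f"{condition}_exclusion"
    if scene_type == "test" and experiment != 2:
        raise ConfigError("the test scene exists only in experiment 2")
    if scene_type == "end_scene" and experiment != 1:
        raise ConfigError("the static end scene is an experiment-1 outcome display")

    origin = geometry.stimulus_origin_px
    colors = dict(COLOR_SCHEMES[counterbalance % 2])

    if scene_type == "end_scene":
        dur = END_SCENE_MS
        tracks = (
            _static("Excluded", (420, 360), CHARACTER_SIZE, dur, origin),
            _static("Gatekeeper", (860, 360), CHARACTER_SIZE, dur, origin),
        )
        return SceneScript(scene_type, condition, experiment, dur, tracks, {"bell": 0}, colors)

    if scene_type == "test":
        dur = TEST_SCENE_MS
        markers = {
            "neutral_activation": 2_000,
            "neutral_descent": 6_000,
            "arrival": ARRIVAL_MS,
            "bell": ARRIVAL_MS,
        }
        # destination counterbalanced by the caller via `condition`-independent
        # waypoints: the track descends and pauses mid-stage; the final leg to
        # excluded/group is appended by the simulator when the outcome is known
        tracks = (
            _moving(
                "Neutral",
                [(markers["neutral_descent"], (560, 200)), (20_000, (560, 430)),
                 (ARRIVAL_MS, (560, 430))],
                CHARACTER_SIZE,
                dur,
                origin,
            ),
            _static("Excluded", (180, 480), CHARACTER_SIZE, dur, origin),
            _static("Gatekeeper", (830, 330), CHARACTER_SIZE, dur, origin),
            _static("GroupMemberA", (960, 310), CHARACTER_SIZE, dur, origin),
            _static("GroupMemberB", (1090, 330), CHARACTER_SIZE, dur, origin),
        )
        return SceneScript(scene_type, condition, experiment, dur, tracks, markers, colors)

    # familiarization scenes (acceptance / exclusion), 48 s
    dur = FAMILIARIZATION_MS
    markers = {"group_bounce": 0, "entry": 3_000, "approach": 4_000, "call_response": 11_500}
    if scene_type == "acceptance":
        markers["synchrony"] = 14_000
        individual_waypoints = [
            (markers["entry"], (60, 400)),
            (11_000, (640, 370)),
            (dur, (640, 370)),  # joins the group and bounces in place
        ]
    else:
        event = "push" if scene_type == "explicit_exclusion" else "ignore"
        markers[event] = 13_000
        markers["retreat"] = 15_000
        markers["synchrony"] = 19_000
        individual_waypoints = [
            (markers["entry"], (60, 400)),
            (11_000, (640, 370)),
            (markers["retreat"], (640, 370)),
            (19_000, (250, 430)),
            (dur, (250, 430)),  # remains at a distance from the group
        ]

    tracks = [
        _moving("Excluded", individual_waypoints, CHARACTER_SIZE, dur, origin),
        _static("Gatekeeper", (830, 330), CHARACTER_SIZE, dur, origin),
        _static("GroupMemberA", (960, 310), CHARACTER_SIZE, dur, origin),
        _static("GroupMemberB", (1090, 330), CHARACTER_SIZE, dur, origin),
        _static("Resource", (960, 560), RESOURCE_SIZE, dur, origin),
    ]
    if experiment == 2:
        tracks.append(_static("Neutral", (450, 180), CHARACTER_SIZE, dur, origin))
    return SceneScript(scene_type, condition, experiment, dur, tuple(tracks), markers, colors)
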