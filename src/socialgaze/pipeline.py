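"""End-to-end analysis pipelines for the two experiment designs.

``run_experiment1`` mirrors the preferential-reaching design: familiarization
gaze analysis (proportion tables, attentional synchrony, offscreen-aversion
contingency, transition entropy) plus binomial tests on the reaching choice.
``run_experiment2`` mirrors the anticipatory-looking design: first-transition
Markov analysis in the test trial's critical window, VOE looking times after
the 24,000 ms arrival, test-trial and exclusion-trial proportion tables, and
entropy.  Both operate on a cohort of sessions — simulated in memory or
loaded from the on-disk formats written by ``save_cohort`` — and return a
bundle of tidy tables plus a JSON-ready summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from socialgaze import aoi as aoi_mod
from socialgaze.aoi import (
    ENTRY_SYNCHRONY_PATTERN,
    GROUP_AOIS,
    AoiTrack,
    ScanpathSequence,
    aversion_contingency,
    extract_scanpath,
    synchrony_summary,
    tracks_from_json,
    tracks_to_json,
)
from socialgaze.errors import ConfigError, DataError
from socialgaze.events import (
    GEOMETRY_PRESETS,
    detect_offscreen_looks,
    segment_stream,
)
from socialgaze.gaze_io import (
    GazeStream,
    SessionRecord,
    TrialRecord,
    read_gaze_export,
    write_gaze_export,
    write_report,
)
from socialgaze.inference import binomial_test, group_contrast, inclusion_filter
from socialgaze.metrics import (
    AnalysisWindow,
    proportion_fixation,
    proportion_table,
    voe_looking_time,
)
from socialgaze.simulate import CohortSpec, SimSession, simulate_cohort
from socialgaze.transitions import (
    entropy_report,
    first_transition_probability,
)

logger = logging.getLogger(__name__)

PRIMARY_AOIS = ("Excluded", "Gatekeeper")


@dataclass
class PipelineConfig:
    """Validated knobs for a full pipeline run."""

    experiment: int = 1
    geometry_preset: str = "17in-1280x1024"
    n_per_condition: int = 16
    invalid_fraction: float = 0.0
    velocity_threshold_deg_s: float = 30.0
    min_fixation_ms: int = 100
    max_gap_fill_ms: int = 75
    min_offscreen_ms: int = 500
    aoi_padding_px: float = 20.0
    stat_reps: int = 2000
    seed: int = 0

    def validate(self) -> None:
        if self.experiment not in (1, 2):
            raise ConfigError("experiment must be 1 or 2")
        if self.geometry_preset not in GEOMETRY_PRESETS:
            raise ConfigError(
                f"unknown geometry preset {self.geometry_preset!r}; "
                f"choose from {sorted(GEOMETRY_PRESETS)}"
            )
        if self.velocity_threshold_deg_s <= 0 or self.min_fixation_ms <= 0:
            raise ConfigError("classifier thresholds must be positive")
        if self.stat_reps < 100:
            raise ConfigError("stat_reps below 100 gives unusable resampling")
        if not 0 <= self.invalid_fraction <= 1:
            raise ConfigError("invalid_fraction must lie in [0, 1]")

    @property
    def geometry(self):
        return GEOMETRY_PRESETS[self.geometry_preset]

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        doc = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(doc) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        cfg.validate()
        return cfg


@dataclass
class AnalysisTrial:
    """One trial ready for analysis: stream plus its stimulus description."""

    record: TrialRecord
    stream: GazeStream
    tracks: tuple[AoiTrack, ...]
    markers: dict[str, int]
    colors: dict[str, str]
    duration_ms: int

    @property
    def scene_type(self) -> str:
        return self.record.scene_type

    @property
    def exclusion_event_end_ms(self) -> int | None:
        for key in ("push", "ignore"):
            if key in self.markers:
                return self.markers[key] + 2_000
        return None


Cohort = list[tuple[SessionRecord, list[AnalysisTrial]]]


def cohort_from_sim(sessions: Sequence[SimSession]) -> Cohort:
    """Adapt simulator output to the analysis-side trial container."""
    out: Cohort = []
    for sim in sessions:
        trials = [
            AnalysisTrial(
                record=t.record,
                stream=t.stream,
                tracks=t.script.tracks,
                markers=dict(t.script.markers),
                colors=dict(t.script.colors),
                duration_ms=t.script.duration_ms,
            )
            for t in sim.trials
        ]
        out.append((sim.session, trials))
    return out


# ---------------------------------------------------------------------------
# on-disk cohort format (stage isolation: simulate -> analyze round-trips)


def save_cohort(sessions: Sequence[SimSession], outdir: str | Path, dialect: str = "vendor-tsv") -> None:
    outdir = Path(outdir)
    (outdir / "streams").mkdir(parents=True, exist_ok=True)
    (outdir / "tracks").mkdir(parents=True, exist_ok=True)
    manifest = []
    for sim in sessions:
        s = sim.session
        trials = []
        for t in sim.trials:
            stem = t.stream.recording_id
            write_gaze_export(t.stream, outdir / "streams" / f"{stem}.tsv", dialect)
            tracks_to_json(t.script.tracks, outdir / "tracks" / f"{stem}.json")
            trials.append(
                {
                    "trial_index": t.record.trial_index,
                    "scene_type": t.record.scene_type,
                    "t_start_ms": t.record.t_start_ms,
                    "t_end_ms": t.record.t_end_ms,
                    "critical_event_seen": t.record.critical_event_seen,
                    "duration_ms": t.script.duration_ms,
                    "markers": t.script.markers,
                    "colors": t.script.colors,
                    "stream": f"streams/{stem}.tsv",
                    "tracks": f"tracks/{stem}.json",
                }
            )
        manifest.append(
            {
                "infant_id": s.infant_id,
                "age_days": s.age_days,
                "experiment": s.experiment,
                "condition": s.condition,
                "choice_outcome": s.choice_outcome,
                "anticipation_first_direction": s.anticipation_first_direction,
                "voe_direction": s.voe_direction,
                "flags": sorted(s.flags),
                "trials": trials,
            }
        )
    (outdir / "sessions.json").write_text(json.dumps({"dialect": dialect, "sessions": manifest}, indent=2))


def load_cohort(indir: str | Path) -> Cohort:
    indir = Path(indir)
    manifest_path = indir / "sessions.json"
    if not manifest_path.exists():
        raise DataError(f"no sessions.json found in {indir}")
    doc = json.loads(manifest_path.read_text())
    dialect = doc.get("dialect", "vendor-tsv")
    cohort: Cohort = []
    for entry in doc["sessions"]:
        records = []
        trials = []
        for tr in entry["trials"]:
            record = TrialRecord(
                infant_id=entry["infant_id"],
                experiment=entry["experiment"],
                condition=entry["condition"],
                trial_index=tr["trial_index"],
                scene_type=tr["scene_type"],
                t_start_ms=tr["t_start_ms"],
                t_end_ms=tr["t_end_ms"],
                critical_event_seen=tr["critical_event_seen"],
            )
            records.append(record)
            trials.append(
                AnalysisTrial(
                    record=record,
                    stream=read_gaze_export(indir / tr["stream"], dialect),
                    tracks=tuple(tracks_from_json(indir / tr["tracks"])),
                    markers={k: int(v) for k, v in tr["markers"].items()},
                    colors=tr["colors"],
                    duration_ms=tr["duration_ms"],
                )
            )
        session = SessionRecord(
            infant_id=entry["infant_id"],
            age_days=entry["age_days"],
            experiment=entry["experiment"],
            condition=entry["condition"],
            trials=records,
            choice_outcome=entry["choice_outcome"],
            anticipation_first_direction=entry["anticipation_first_direction"],
            voe_direction=entry["voe_direction"],
            flags=frozenset(entry["flags"]),
        )
        cohort.append((session, trials))
    return cohort


# ---------------------------------------------------------------------------
# shared per-trial processing


@dataclass
class ProcessedTrial:
    trial: AnalysisTrial
    events: list
    offscreen: list
    scanpath: ScanpathSequence


def process_trial(trial: AnalysisTrial, config: PipelineConfig) -> ProcessedTrial:
    events = segment_stream(
        trial.stream,
        config.geometry,
        velocity_threshold_deg_s=config.velocity_threshold_deg_s,
        min_fixation_ms=config.min_fixation_ms,
        max_gap_fill_ms=config.max_gap_fill_ms,
        min_offscreen_ms=config.min_offscreen_ms,
    )
    offscreen = [e for e in events if e.kind == "offscreen"]
    seq = extract_scanpath(events, trial.tracks, trial_id=trial.stream.recording_id)
    return ProcessedTrial(trial, events, offscreen, seq)


def _gaze_sample_ok(session: SessionRecord) -> bool:
    """Infants kept for gaze analyses: included, or excluded for outcome only."""
    decision = inclusion_filter(session)
    return decision.included or decision.outcome_only


def _exclusion_trials(trials: Sequence[AnalysisTrial]) -> list[AnalysisTrial]:
    return [t for t in trials if t.scene_type == "exclusion"]


# ---------------------------------------------------------------------------
# experiment 1


def run_experiment1(cohort: Cohort, config: PipelineConfig) -> dict:
    """Reaching-task binomials plus the familiarization gaze analyses."""
    config.validate()
    if config.experiment != 1:
        raise ConfigError("config.experiment must be 1 for run_experiment1")

    included = [(s, trs) for s, trs in cohort if inclusion_filter(s).included]
    gaze_sample = [(s, trs) for s, trs in cohort if _gaze_sample_ok(s)]

    # --- reaching choice binomials -------------------------------------
    choice_rows = []
    color_counts = {"k": 0, "n": 0}
    for condition, predicted in (("explicit", "excluded"), ("implicit", "gatekeeper")):
        sessions = [s for s, _ in included if s.condition == condition]
        n = sum(1 for s in sessions if s.choice_outcome != "none")
        k = sum(1 for s in sessions if s.choice_outcome == predicted)
        if n == 0:
            continue
        cc = binomial_test(k, n, 0.5, "greater", "normal_cc")
        ex = binomial_test(k, n, 0.5, "greater", "exact")
        choice_rows.append(
            {
                "condition": condition, "predicted": predicted, "k": k, "n": n,
                "share": round(k / n, 3),
                "p_normal_cc": round(cc.p_value, 4), "p_exact": round(ex.p_value, 4),
            }
        )
    for s, trs in included:
        if s.choice_outcome == "none" or not trs:
            continue
        chosen_aoi = "Excluded" if s.choice_outcome == "excluded" else "Gatekeeper"
        color = trs[0].colors.get(chosen_aoi)
        color_counts["n"] += 1
        color_counts["k"] += int(color == "turquoise")
    color_p = (
        binomial_test(color_counts["k"], color_counts["n"], 0.5, "two_sided", "exact").p_value
        if color_counts["n"]
        else float("nan")
    )
    choice_table = pd.DataFrame(choice_rows)

    # --- process familiarization gaze ----------------------------------
    processed: dict[str, list[ProcessedTrial]] = {}
    for s, trs in gaze_sample:
        processed[s.infant_id] = [process_trial(t, config) for t in _exclusion_trials(trs)]

    # proportions over exclusion trials (whole trial window)
    prop_rows = []
    per_infant_props: dict[str, dict[str, float]] = {}
    for s, trs in gaze_sample:
        pooled: dict[str, float] = {}
        weight = 0.0
        for pt in processed[s.infant_id]:
            window = AnalysisWindow("whole_trial", 0, pt.trial.duration_ms)
            aois = [tr.aoi_id for tr in pt.trial.tracks]
            props = proportion_fixation(pt.events, pt.scanpath, window, aois)
            if props is None:
                continue
            for a, v in props.items():
                pooled[a] = pooled.get(a, 0.0) + v
            weight += 1
        if weight:
            per_infant_props[s.infant_id] = {a: v / weight for a, v in pooled.items()}
            prop_rows.append(
                (s.infant_id, s.condition, per_infant_props[s.infant_id])
            )
    aois_exp1 = ("Excluded", "Gatekeeper", "GroupMemberA", "GroupMemberB", "Resource")
    proportions = proportion_table(
        [(i, c, p) for i, c, p in prop_rows], aois_exp1
    )

    # between-condition contrast of P_Excluded - P_Gatekeeper
    diffs = {"explicit": [], "implicit": []}
    for infant_id, condition, props in prop_rows:
        diffs[condition].append(props.get("Excluded", 0.0) - props.get("Gatekeeper", 0.0))
    contrast = None
    if len(diffs["implicit"]) >= 2 and len(diffs["explicit"]) >= 2:
        contrast = group_contrast(
            diffs["implicit"], diffs["explicit"],
            label="(P_Excluded-P_Gatekeeper) implicit-explicit",
            reps=config.stat_reps, seed=config.seed,
        )

    # attentional synchrony on exclusion trials
    synchrony_input = [
        (s, [pt.scanpath for pt in processed[s.infant_id]]) for s, _ in gaze_sample
    ]
    synchrony = synchrony_summary(synchrony_input, ENTRY_SYNCHRONY_PATTERN)

    # offscreen aversion after fixating the gatekeeper
    seqs_by_cond = {"explicit": [], "implicit": []}
    for s, _ in gaze_sample:
        for pt in processed[s.infant_id]:
            seqs_by_cond[s.condition].append(pt.scanpath)
    rates = {
        cond: aversion_contingency(seqs, "Gatekeeper") if seqs else float("nan")
        for cond, seqs in seqs_by_cond.items()
    }
    ratio = (
        rates["explicit"] / rates["implicit"]
        if rates.get("implicit") else float("nan")
    )

    # transition entropy (on-screen only)
    entropy_entries = []
    for s, _ in gaze_sample:
        for pt in processed[s.infant_id]:
            entropy_entries.append(
                (s.infant_id, s.condition, pt.trial.record.trial_index, pt.scanpath)
            )
    entropy = entropy_report(entropy_entries)

    tables = {
        "choice_binomials": choice_table,
        "proportions_exclusion": proportions,
        "synchrony_trials": synchrony,
        "entropy_trials": entropy.table,
        "entropy_by_condition": entropy.by_condition(),
    }
    summary = {
        "experiment": 1,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_sessions": len(cohort),
        "n_included": len(included),
        "n_gaze_sample": len(gaze_sample),
        "choice": choice_rows,
        "color_control": {**color_counts, "p_exact_two_sided": round(color_p, 4)},
        "synchrony_fraction": synchrony.attrs["fraction"],
        "synchrony_counts": [synchrony.attrs["n_matched"], synchrony.attrs["n_trials"]],
        "aversion_rates": rates,
        "aversion_ratio": ratio,
        "entropy_mean": entropy.mean,
        "entropy_sd": entropy.sd,
    }
    if contrast is not None:
        summary["proportion_contrast"] = {
            "label": contrast.label,
            "estimate": contrast.estimate,
            "ci": [contrast.ci_low, contrast.ci_high],
            "p": contrast.p_value,
        }
    return {"tables": tables, "summary": summary}


# ---------------------------------------------------------------------------
# experiment 2


def run_experiment2(cohort: Cohort, config: PipelineConfig) -> dict:
    """Anticipatory-looking Markov analysis, VOE looking times, gaze tables."""
    config.validate()
    if config.experiment != 2:
        raise ConfigError("config.experiment must be 2 for run_experiment2")

    outcome_sample = [(s, trs) for s, trs in cohort if inclusion_filter(s).included]
    gaze_sample = [(s, trs) for s, trs in cohort if _gaze_sample_ok(s)]

    # --- anticipation: first transition from the neutral character ------
    anticipation_rows = []
    color_counts = {"k": 0, "n": 0}
    pooled_by_condition = {}
    test_processed: dict[str, ProcessedTrial] = {}
    for s, trs in outcome_sample:
        test_trials = [t for t in trs if t.scene_type == "test"]
        if not test_trials:
            continue
        t = test_trials[0]
        pt = process_trial(t, config)
        test_processed[s.infant_id] = pt

    for condition in ("explicit", "implicit"):
        entries = []
        windows = None
        for s, trs in outcome_sample:
            if s.condition != condition or s.infant_id not in test_processed:
                continue
            pt = test_processed[s.infant_id]
            markers = pt.trial.markers
            windows = (markers["neutral_descent"], markers["arrival"])
            entries.append((s.infant_id, pt.scanpath))
        if not entries:
            continue
        frame = first_transition_probability(
            entries,
            source_aoi="Neutral",
            target_groups={"group": set(GROUP_AOIS), "excluded": {"Excluded"}},
            window=windows,
        )
        counts = frame["first_direction"].value_counts()
        k_group = int(counts.get("group", 0))
        n = int(counts.get("group", 0) + counts.get("excluded", 0))
        if n:
            predicted_dir = "group" if condition == "implicit" else "excluded"
            k_pred = k_group if predicted_dir == "group" else n - k_group
            anticipation_rows.append(
                {
                    "condition": condition,
                    "k_group": k_group,
                    "n": n,
                    "share_group": round(k_group / n, 3),
                    "p_exact_two_sided": round(
                        binomial_test(k_group, n, 0.5, "two_sided", "exact").p_value, 4
                    ),
                    "p_normal_cc_pred": round(
                        binomial_test(k_pred, n, 0.5, "greater", "normal_cc").p_value, 4
                    ),
                }
            )
        pooled_by_condition[condition] = frame.attrs["pooled"]
        # colour control: colour of the character first looked at
        for (infant_id, _), (_, row) in zip(entries, frame.iterrows()):
            session = next(s for s, _ in outcome_sample if s.infant_id == infant_id)
            trs = next(t for s, t in outcome_sample if s.infant_id == infant_id)
            if row["first_direction"] == "excluded":
                color = trs[0].colors.get("Excluded")
            elif row["first_direction"] == "group":
                color = trs[0].colors.get("Gatekeeper")
            else:
                continue
            color_counts["n"] += 1
            color_counts["k"] += int(color == "purple")
    color_p = (
        binomial_test(color_counts["k"], color_counts["n"], 0.5, "two_sided", "exact").p_value
        if color_counts["n"]
        else float("nan")
    )
    anticipation_table = pd.DataFrame(anticipation_rows)
    markov_table = pd.DataFrame(
        [
            {"condition": cond, "target": tgt, "pooled_probability": round(p, 3)}
            for cond, pooled in pooled_by_condition.items()
            for tgt, p in pooled.items()
        ]
    )

    # --- VOE looking times ----------------------------------------------
    voe_rows = []
    for s, trs in outcome_sample:
        if s.infant_id not in test_processed:
            continue
        pt = test_processed[s.infant_id]
        arrival = pt.trial.markers["arrival"]
        res = voe_looking_time(pt.trial.stream, pt.events, pt.offscreen, t0_ms=arrival)
        voe_rows.append(
            {
                "infant_id": s.infant_id,
                "condition": s.condition,
                "direction": s.voe_direction,
                "expected": s.anticipation_first_direction,
                "looking_ms": res.looking_ms,
                "log_looking": res.log_looking,
                "n_offscreen_used": res.n_offscreen_used,
            }
        )
    voe_table = pd.DataFrame(voe_rows)
    voe_means = (
        voe_table.groupby(["direction", "condition"])["looking_ms"]
        .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
        if len(voe_rows)
        else pd.DataFrame()
    )

    # --- proportions ----------------------------------------------------
    aois_exp2 = ("Excluded", "Gatekeeper", "GroupMemberA", "GroupMemberB", "Resource", "Neutral")
    prop_rows = []
    processed_fam: dict[str, list[ProcessedTrial]] = {}
    for s, trs in gaze_sample:
        processed_fam[s.infant_id] = [process_trial(t, config) for t in _exclusion_trials(trs)]
        pooled: dict[str, float] = {}
        weight = 0.0
        for pt in processed_fam[s.infant_id]:
            window = AnalysisWindow("whole_trial", 0, pt.trial.duration_ms)
            props = proportion_fixation(
                pt.events, pt.scanpath, window, [tr.aoi_id for tr in pt.trial.tracks]
            )
            if props is None:
                continue
            for a, v in props.items():
                pooled[a] = pooled.get(a, 0.0) + v
            weight += 1
        if weight:
            prop_rows.append(
                (s.infant_id, s.condition, {a: v / weight for a, v in pooled.items()})
            )
    proportions_exclusion = proportion_table(prop_rows, aois_exp2)

    test_prop_rows = []
    for s, trs in outcome_sample:
        if s.infant_id not in test_processed:
            continue
        pt = test_processed[s.infant_id]
        window = AnalysisWindow("voe", pt.trial.markers["arrival"], pt.trial.duration_ms)
        props = proportion_fixation(
            pt.events, pt.scanpath, window, [tr.aoi_id for tr in pt.trial.tracks]
        )
        test_prop_rows.append(
            (s.infant_id, f"{s.voe_direction}/{s.condition}", props)
        )
    proportions_test = proportion_table(
        test_prop_rows, ("Excluded", "Gatekeeper", "Neutral")
    )

    # --- entropy ---------------------------------------------------------
    entropy_entries = [
        (s.infant_id, s.condition, pt.trial.record.trial_index, pt.scanpath)
        for s, _ in gaze_sample
        for pt in processed_fam[s.infant_id]
    ]
    entropy_fam = entropy_report(entropy_entries)
    test_entries = [
        (infant_id, "test", 1, pt.scanpath)
        for infant_id, pt in test_processed.items()
    ]
    entropy_test = entropy_report(test_entries) if test_entries else None

    tables = {
        "anticipation_binomials": anticipation_table,
        "markov_first_transitions": markov_table,
        "voe_looking": voe_table,
        "voe_means": voe_means,
        "proportions_test": proportions_test,
        "proportions_exclusion": proportions_exclusion,
        "entropy_trials": entropy_fam.table,
    }
    summary = {
        "experiment": 2,
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_sessions": len(cohort),
        "n_outcome_sample": len(outcome_sample),
        "n_gaze_sample": len(gaze_sample),
        "no_expectation_infants": [
            s.infant_id for s, _ in cohort if inclusion_filter(s).outcome_only
        ],
        "anticipation": anticipation_rows,
        "color_control": {**color_counts, "p_exact_two_sided": round(color_p, 4)},
        "markov_pooled": pooled_by_condition,
        "entropy_mean_familiarization": entropy_fam.mean,
        "entropy_mean_test": entropy_test.mean if entropy_test else float("nan"),
    }
    return {"tables": tables, "summary": summary}


def run_pipeline(config: PipelineConfig, cohort: Cohort | None = None) -> dict:
    """Simulate (when no cohort is given) and analyze under one config."""
    config.validate()
    if cohort is None:
        spec = CohortSpec(
            n_per_condition=config.n_per_condition,
            experiment=config.experiment,
            invalid_fraction=config.invalid_fraction,
            seed=config.seed,
        )
        cohort = cohort_from_sim(simulate_cohort(spec, geometry=config.geometry))
    runner = run_experiment1 if config.experiment == 1 else run_experiment2
    return runner(cohort, config)


def write_bundle(result: dict, outdir: str | Path) -> None:
    """Write a report bundle: one CSV per table plus a JSON summary."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_report(result["tables"], outdir, format="csv")
    (outdir / "summary.json").write_text(
        json.dumps(result["summary"], indent=2, sort_keys=True, default=float)
    )
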