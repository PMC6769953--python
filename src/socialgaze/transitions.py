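"""Gaze-transition matrices, Markov statistics, and standardized entropy.

A transition matrix counts ordered adjacent visit pairs of a scanpath.
Because visits are collapsed (consecutive same-AOI fixations merge), the
diagonal is structurally zero.  Scanning randomness is summarised as the
stationary-weighted conditional Shannon entropy of the transition
probabilities,

    H = -sum_i pi_i sum_j p_ij log2 p_ij,

normalized by ``log2`` of the number of visited states so that ``H_norm`` lies
in [0, 1]: a deterministic scanning cycle scores 0, uniformly random
transitions score 1.  The stationary distribution ``pi`` solves ``pi P = pi``
by power iteration; for reducible chains (common in short infant trials) the
empirical visit frequencies are used instead, and they are also available as
an explicit weighting variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from socialgaze.aoi import OFFSCREEN, ScanpathSequence
from socialgaze.errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class TransitionMatrix:
    """Counts and row-normalized probabilities over an ordered state list."""

    states: tuple[str, ...]
    counts: np.ndarray  # (n, n) int, entry [i, j] = visits i followed by j

    def __post_init__(self) -> None:
        n = len(self.states)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (n, n):
            raise ConfigError("counts shape does not match the state list")
        if (self.counts < 0).any():
            raise DataError("negative transition count")

    @property
    def n_transitions(self) -> int:
        return int(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        """Row-normalized where the row has outgoing transitions, else zero."""
        row = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(row > 0, self.counts / row, 0.0)
        return p

    @property
    def visited(self) -> np.ndarray:
        """States that take part in any transition (row or column)."""
        return (self.counts.sum(axis=1) + self.counts.sum(axis=0)) > 0

    def visit_frequencies(self) -> np.ndarray:
        """Empirical state occupancy among transition endpoints (sums to 1)."""
        occ = self.counts.sum(axis=1) + self.counts.sum(axis=0)
        total = occ.sum()
        if total == 0:
            raise DataError("empty transition matrix")
        return occ / total

    def to_frame(self, kind: str = "counts") -> pd.DataFrame:
        data = self.counts if kind == "counts" else self.probabilities
        return pd.DataFrame(data, index=list(self.states), columns=list(self.states))


def build_transition_matrix(
    seqs: ScanpathSequence | Sequence[ScanpathSequence],
    states: Sequence[str] | None = None,
    include_offscreen: bool = False,
) -> TransitionMatrix:
    """Count adjacent visit pairs, pooling sequences without bridging them.

    With ``include_offscreen=False`` (the on-screen analysis) Offscreen visits
    are removed first and the sequence re-collapsed, so an A -> Offscreen -> A
    excursion contributes no transition.
    """
    if isinstance(seqs, ScanpathSequence):
        seqs = [seqs]
    prepared = [s if include_offscreen else s.onscreen() for s in seqs]
    if states is None:
        seen: list[str] = []
        for s in prepared:
            for lab in s.labels:
                if lab not in seen:
                    seen.append(lab)
        states = sorted(seen)
    states = tuple(states)
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)), dtype=np.int64)
    for s in prepared:
        labs = s.labels
        for a, b in zip(labs, labs[1:]):
            if a not in index or b not in index:
                raise DataError(f"visit label {a!r}/{b!r} outside state list")
            counts[index[a], index[b]] += 1
    return TransitionMatrix(states, counts)


def stationary_distribution(
    m: TransitionMatrix, tol: float = 1e-10, max_iter: int = 100_000
) -> np.ndarray:
    """Stationary distribution over ``m.states`` (zeros on unvisited states).

    Power iteration on the visited-state submatrix when the chain restricted
    to visited states is irreducible (every visited state reachable from every
    other, treating transitions as directed edges); otherwise falls back to
    empirical visit frequencies, which is the natural weighting for short
    sequences that wander off and never return.
    """
    if m.n_transitions == 0:
        raise DataError("empty transition matrix")
    visited = m.visited
    sub = m.counts[np.ix_(visited, visited)].astype(float)
    rows = sub.sum(axis=1)
    irreducible = (rows > 0).all()
    if irreducible:
        n_comp, _ = connected_components(sub > 0, directed=True, connection="strong")
        irreducible = n_comp == 1
    full = np.zeros(len(m.states))
    if not irreducible:
        logger.debug("chain not irreducible; using empirical visit frequencies")
        full[visited] = m.visit_frequencies()[visited]
        full /= full.sum()
        return full
    p = sub / rows[:, None]
    pi = np.full(len(sub), 1.0 / len(sub))
    for _ in range(max_iter):
        nxt = pi @ p
        if np.abs(nxt - pi).max() < tol:
            pi = nxt
            break
        pi = nxt
    pi = pi / pi.sum()
    full[visited] = pi
    return full


def normalized_entropy(
    m: TransitionMatrix, weighting: str = "stationary"
) -> float:
    """Standardized gaze-transition entropy in [0, 1].

    ``weighting`` selects the state weights: ``"stationary"`` (default) or
    ``"empirical"`` visit frequencies.  Raises :class:`DataError` when fewer
    than two states were visited (entropy undefined).
    """
    if m.n_transitions == 0:
        raise DataError("empty transition matrix")
    visited = m.visited
    n_visited = int(visited.sum())
    if n_visited < 2:
        raise DataError("entropy undefined with a single visited state")
    if weighting == "stationary":
        w = stationary_distribution(m)
    elif weighting == "empirical":
        w = np.zeros(len(m.states))
        w[visited] = m.visit_frequencies()[visited]
        w /= w.sum()
    else:
        raise ConfigError(f"unknown weighting {weighting!r}")
    p = m.probabilities
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    h_rows = -plogp.sum(axis=1)
    h = float((w * h_rows).sum())
    return h / np.log2(n_visited)


@dataclass
class EntropyReport:
    """Per-trial standardized entropies with per-group summaries."""

    table: pd.DataFrame  # columns: infant_id, condition, trial_index, h_norm

    @property
    def mean(self) -> float:
        return float(self.table["h_norm"].mean())

    @property
    def sd(self) -> float:
        return float(self.table["h_norm"].std(ddof=1))

    def by_condition(self) -> pd.DataFrame:
        return (
            self.table.groupby("condition")["h_norm"]
            .agg(n="count", mean="mean", sd=lambda v: v.std(ddof=1))
            .reset_index()
        )


def entropy_report(
    entries: Sequence[tuple[str, str, int, ScanpathSequence]],
    states: Sequence[str] | None = None,
    include_offscreen: bool = False,
    weighting: str = "stationary",
) -> EntropyReport:
    """Per-trial entropy over (infant_id, condition, trial_index, sequence) entries.

    Trials whose matrix has fewer than two visited states are dropped with a
    log entry (entropy undefined), mirroring how sparse infant trials are
    handled in practice.
    """
    rows = []
    for infant_id, condition, trial_index, seq in entries:
        try:
            matrix = build_transition_matrix(seq, states, include_offscreen)
            h = normalized_entropy(matrix, weighting)
        except DataError as exc:
            logger.info("trial %s/%s dropped from entropy: %s", infant_id, trial_index, exc)
            continue
        rows.append((infant_id, condition, trial_index, h))
    if not rows:
        raise DataError("no trial yielded a defined entropy")
    return EntropyReport(
        pd.DataFrame(rows, columns=["infant_id", "condition", "trial_index", "h_norm"])
    )


def first_transition_probability(
    seqs: Sequence[tuple[str, ScanpathSequence]],
    source_aoi: str,
    target_groups: dict[str, frozenset | set],
    window: tuple[int, int],
) -> pd.DataFrame:
    """Direction of the first look away from *source_aoi* plus pooled Markov rows.

    For each (infant_id, sequence): restrict to the analysis window, find the
    first visit to the source AOI, and record which target group is reached
    first afterwards, skipping Offscreen (the first *on-screen* target wins).
    Infants who never visit the source are flagged ``no_expectation``.  The
    pooled probabilities aggregate the window-restricted transition-matrix row
    from the source over each target group and are stored in
    ``frame.attrs["pooled"]``.
    """
    rows = []
    window_seqs = []
    for infant_id, seq in seqs:
        sub = seq.restrict(*window)
        window_seqs.append(sub)
        labels = sub.labels
        try:
            src_pos = labels.index(source_aoi)
        except ValueError:
            rows.append((infant_id, "no_expectation"))
            continue
        direction = "none"
        for lab in labels[src_pos + 1:]:
            if lab == OFFSCREEN:
                continue
            group = next((g for g, members in target_groups.items() if lab in members), None)
            if group is not None:
                direction = group
                break
        rows.append((infant_id, direction))
    frame = pd.DataFrame(rows, columns=["infant_id", "first_direction"])

    matrix = build_transition_matrix(
        [s for s in window_seqs if s.visits], states=None, include_offscreen=False
    )
    if source_aoi in matrix.states:
        src = matrix.states.index(source_aoi)
        row = matrix.probabilities[src]
        pooled = {
            g: float(sum(row[matrix.states.index(t)] for t in members if t in matrix.states))
            for g, members in target_groups.items()
        }
    else:
        pooled = {g: float("nan") for g in target_groups}
    frame.attrs["pooled"] = pooled
    return frame
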