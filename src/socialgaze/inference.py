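"""Outcome statistics and the pre-registered inclusion filter.

Binomial tests come in two flavours, both reported wherever an outcome is
tested:

* ``exact`` — tail sums of the binomial pmf (two-sided doubles the smaller
  tail, capped at 1);
* ``normal_cc`` — the normal approximation N(n p0, n p0 (1 - p0)) with a
  ±0.5 continuity correction.

By convention the continuity-corrected one-sided test is used for
pre-registered directional predictions (did more infants than chance choose
the predicted character?) and the exact two-sided test for non-directional
controls (colour preference).

Group contrasts (difference of means between conditions) use a two-sided
permutation test for the p-value and a percentile bootstrap for the 95% CI —
transparent and valid at the very small per-cell sample sizes typical of
infant eye-tracking work.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from socialgaze.errors import ConfigError
from socialgaze.gaze_io import SessionRecord

#: reasons an infant can be excluded from analysis
EXCLUSION_REASONS = frozenset(
    {
        "too_few_trials",
        "too_few_critical_trials",
        "fussiness",
        "technical",
        "task_error",
        "color_preference",
        "no_reach",
        "no_expectation",
        "poor_gaze_quality",
    }
)

MIN_FAMILIARIZATION_TRIALS = 4
MIN_CRITICAL_TRIALS = 2


@dataclass(frozen=True)
class BinomialResult:
    k: int
    n: int
    p0: float
    alternative: str  # "greater" | "less" | "two_sided"
    method: str  # "exact" | "normal_cc"
    p_value: float


@dataclass(frozen=True)
class ContrastResult:
    label: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    reps: int
    seed: int


@dataclass(frozen=True)
class InclusionDecision:
    included: bool
    reason_codes: frozenset = frozenset()
    #: exclusions that only remove the infant from the outcome analysis,
    #: leaving it in the gaze analyses
    outcome_only: bool = False


def binomial_test(
    k: int,
    n: int,
    p0: float = 0.5,
    alternative: str = "greater",
    method: str = "exact",
) -> BinomialResult:
    """Test k successes in n trials against success probability p0."""
    if n <= 0:
        raise ConfigError("binomial test needs n > 0")
    if not 0 <= k <= n:
        raise ConfigError("k must lie in [0, n]")
    if not 0 < p0 < 1:
        raise ConfigError("p0 must lie strictly in (0, 1)")
    if alternative not in ("greater", "less", "two_sided"):
        raise ConfigError(f"unknown alternative {alternative!r}")

    if method == "exact":
        if alternative == "two_sided":
            # double the smaller tail, capped at 1 (symmetric-tail convention)
            lower = stats.binom.cdf(k, n, p0)
            upper = stats.binom.sf(k - 1, n, p0)
            p = min(1.0, 2.0 * min(lower, upper))
        else:
            p = float(stats.binomtest(k, n, p0, alternative=alternative).pvalue)
    elif method == "normal_cc":
        mu = n * p0
        sigma = math.sqrt(n * p0 * (1 - p0))
        if alternative == "greater":
            p = float(stats.norm.sf((k - 0.5 - mu) / sigma))
        elif alternative == "less":
            p = float(stats.norm.cdf((k + 0.5 - mu) / sigma))
        else:
            z = (abs(k - mu) - 0.5) / sigma
            p = float(2.0 * stats.norm.sf(max(z, 0.0)))
        p = min(1.0, p)
    else:
        raise ConfigError(f"unknown method {method!r}")
    return BinomialResult(k, n, p0, alternative, method, p)


def group_contrast(
    values_a,
    values_b,
    label: str = "A-B",
    reps: int = 10_000,
    seed: int = 0,
) -> ContrastResult:
    """Mean difference A - B with permutation p-value and bootstrap 95% CI."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ConfigError("each group needs at least two values")
    estimate = float(a.mean() - b.mean())
    rng = np.random.default_rng(seed)

    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        return ContrastResult(label, estimate, estimate, estimate, 1.0, reps, seed)

    n_a = len(a)
    perm_stats = np.empty(reps)
    for i in range(reps):
        perm = rng.permutation(pooled)
        perm_stats[i] = perm[:n_a].mean() - perm[n_a:].mean()
    # add-one correction keeps p > 0 and is exact under exchangeability
    p = float((np.sum(np.abs(perm_stats) >= abs(estimate)) + 1) / (reps + 1))

    boot = np.empty(reps)
    for i in range(reps):
        boot[i] = rng.choice(a, n_a).mean() - rng.choice(b, len(b)).mean()
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return ContrastResult(label, estimate, float(lo), float(hi), p, reps, seed)


def inclusion_filter(session: SessionRecord, experiment: int | None = None) -> InclusionDecision:
    """Apply the pre-registered inclusion rules to one session.

    An infant must complete at least four familiarization trials in total
    (acceptance + exclusion) and at least two exclusion trials during which
    the critical exclusion event was actually watched.  Coder flags
    (fussiness, technical error, reaching-task errors, a reported colour
    preference) exclude directly.  In experiment 2, missing the test trial's
    critical window or showing no expectation excludes the infant from the
    outcome analysis only: it stays in the gaze analyses.
    """
    experiment = experiment or session.experiment
    reasons: set[str] = set()

    fam = [t for t in session.trials if t.scene_type in ("acceptance", "exclusion")]
    if len(fam) < MIN_FAMILIARIZATION_TRIALS:
        reasons.add("too_few_trials")
    critical = [
        t
        for t in session.trials
        if t.scene_type == "exclusion" and t.critical_event_seen
    ]
    if len(critical) < MIN_CRITICAL_TRIALS:
        reasons.add("too_few_critical_trials")

    for flag in ("fussiness", "technical", "poor_gaze_quality", "color_preference"):
        if flag in session.flags:
            reasons.add(flag)
    if session.flags & {"both_reach", "lunge_grab"}:
        reasons.add("task_error")
    if "no_reach" in session.flags:
        reasons.add("no_reach")

    if experiment == 2:
        test_trials = session.trials_of("test")
        missed_test = bool(test_trials) and not any(
            t.critical_event_seen for t in test_trials
        )
        if missed_test or "no_expectation" in session.flags:
            reasons.add("no_expectation")

    # "no expectation" alone removes the infant from the outcome analysis but
    # keeps it in the gaze analyses
    outcome_only = reasons == {"no_expectation"}
    return InclusionDecision(
        included=not reasons,
        reason_codes=frozenset(reasons),
        outcome_only=outcome_only,
    )
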