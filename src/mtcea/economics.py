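"""Economic endpoints: incremental analysis, validation, sensitivity.

The incremental comparison is index arm minus control.  Because the two
arms of the underlying trial differed in mean SF-6D utility at baseline,
the QALY difference is baseline-adjusted by difference-in-differences:
the baseline utility gap times the horizon in years is subtracted from
the raw QALY difference.  With equal baselines the adjustment is a
no-op.

Dominance follows the usual cost-effectiveness quadrants: the index arm
*dominates* when it gains QALYs at lower cost, is *dominated* in the
mirror quadrant, and otherwise the incremental cost-effectiveness ratio
(ICER, SEK per QALY) is reported.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence

import numpy as np

from .markov import CohortTrace
from .types import (
    EconResult,
    FollowUpRecord,
    Group,
    SensitivityResult,
    ValidationResult,
)

__all__ = [
    "incremental_analysis",
    "dominance_verdict",
    "individual_cost_totals",
    "mean_cost_per_participant",
    "bootstrap_ci",
    "validate_model",
    "sensitivity_two_sd",
]

BOOTSTRAP_RESAMPLES = 10_000


def dominance_verdict(delta_cost: float, delta_qaly: float) -> tuple[str, float | None]:
    """Classify the (delta_cost, delta_qaly) point and compute the ICER
    where one is meaningful.  Exhaustive over the sign grid."""
    if delta_qaly > 0 and delta_cost < 0:
        return "dominant", None
    if delta_qaly < 0 and delta_cost > 0:
        return "dominated", None
    if delta_qaly == 0:
        if delta_cost == 0:
            return "icer", None  # indifferent: no trade-off to price
        return "undefined", None  # cost difference with zero effect
    return "icer", delta_cost / delta_qaly


def incremental_analysis(
    trace_index: CohortTrace,
    trace_control: CohortTrace,
    baseline_utilities: tuple[float, float] = (0.0, 0.0),
) -> EconResult:
    """Incremental QALYs, costs and ICER/dominance from two arm traces.

    ``baseline_utilities`` is (index, control) at trial baseline; their
    gap times the horizon in years is removed from the QALY difference
    (difference-in-differences).  Defaults to no adjustment.
    """
    ti, tc = trace_index.table, trace_control.table
    if len(ti) != len(tc) or list(ti["month_end"]) != list(tc["month_end"]):
        raise ValueError("traces cover different horizons or cycle grids")
    horizon_years = float(ti["month_end"].iloc[-1]) / 12.0
    adjust = (baseline_utilities[0] - baseline_utilities[1]) * horizon_years

    dq = trace_index.total_qaly - trace_control.total_qaly - adjust
    dc = trace_index.total_cost - trace_control.total_cost
    dq_d = trace_index.total_qaly_discounted - trace_control.total_qaly_discounted - adjust
    dc_d = trace_index.total_cost_discounted - trace_control.total_cost_discounted

    verdict, icer = dominance_verdict(dc, dq)
    verdict_d, icer_d = dominance_verdict(dc_d, dq_d)
    return EconResult(
        delta_qaly=dq,
        delta_cost_sek=dc,
        icer=icer,
        verdict=verdict,
        delta_qaly_discounted=dq_d,
        delta_cost_sek_discounted=dc_d,
        icer_discounted=icer_d,
        verdict_discounted=verdict_d,
    )


# --------------------------------------------------------------------------
# per-participant cost summaries


def individual_cost_totals(records: Iterable[FollowUpRecord]) -> dict[Group, dict[str, float]]:
    """Total cost over the whole horizon per participant, by arm."""
    totals: dict[Group, dict[str, float]] = {g: defaultdict(float) for g in Group}
    for r in records:
        totals[r.group][r.participant_id] += r.cost_sek
    return {g: dict(d) for g, d in totals.items()}


def bootstrap_ci(
    values: Sequence[float],
    seed: int,
    n_resamples: int = BOOTSTRAP_RESAMPLES,
    level: float = 0.95,
) -> tuple[float, float]:
    """Seeded nonparametric percentile bootstrap CI for a mean.

    Percentile intervals are asymmetric for skewed data, which matches
    the heavy right tail of health-care costs.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("cannot bootstrap an empty sample")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(n_resamples, values.size))
    means = values[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def mean_cost_per_participant(
    records: Iterable[FollowUpRecord],
    arm: Group,
    denominator: int | None = None,
    seed: int = 0,
    n_resamples: int = BOOTSTRAP_RESAMPLES,
) -> tuple[float, tuple[float, float]]:
    """Arithmetic mean 96-month cost per participant in one arm, with a
    seeded percentile-bootstrap 95% CI.

    ``denominator`` overrides the number of contributing participants
    (the trial reports some means over the originally randomised arm
    size rather than the completers)."""
    totals = individual_cost_totals(records)[arm]
    if not totals:
        raise ValueError(f"no participants with cost records in arm {arm.value}")
    values = list(totals.values())
    n = denominator if denominator is not None else len(values)
    if n <= 0:
        raise ValueError("denominator must be positive")
    mean = sum(values) / n
    return mean, bootstrap_ci(values, seed=seed, n_resamples=n_resamples)


# --------------------------------------------------------------------------
# model validation


def validate_model(
    predicted_curve: Sequence[tuple[int, float]],
    observed_proportions: Sequence[tuple[int, float]],
    tolerance_pct: float = 5.0,
) -> ValidationResult:
    """Compare model-predicted against observed recovery percentages.

    Valid iff the largest absolute percentage-point gap across
    follow-ups is within the tolerance."""
    pred = dict(predicted_curve)
    obs = dict(observed_proportions)
    if sorted(pred) != sorted(obs):
        raise ValueError(
            f"follow-up grids differ: predicted {sorted(pred)} vs observed {sorted(obs)}"
        )
    months = tuple(sorted(obs))
    diffs = tuple(abs(pred[m] - obs[m]) for m in months)
    return ValidationResult(
        months=months,
        observed_pct=tuple(obs[m] for m in months),
        predicted_pct=tuple(pred[m] for m in months),
        abs_diff_pct=diffs,
        tolerance_pct=tolerance_pct,
        valid=max(diffs) <= tolerance_pct,
    )


# --------------------------------------------------------------------------
# 2-SD outlier sensitivity analysis


def sensitivity_two_sd(
    records: Iterable[FollowUpRecord],
    seed: int = 0,
    n_resamples: int = BOOTSTRAP_RESAMPLES,
) -> SensitivityResult:
    """Univariate sensitivity analysis excluding high-cost outliers.

    Individual 96-month cost totals are pooled across both arms; anyone
    whose total strictly exceeds pooled mean + 2 pooled (sample) SDs is
    excluded, and per-arm means with bootstrap CIs are recomputed.  Only
    expensive individuals are ever removed, so the after-exclusion mean
    cannot rise.  A degenerate zero SD excludes no one.
    """
    totals = individual_cost_totals(records)
    pooled = [v for d in totals.values() for v in d.values()]
    if len(pooled) < 3:
        raise ValueError("need at least 3 individuals with cost totals")
    pooled_arr = np.asarray(pooled, dtype=float)
    mean = float(pooled_arr.mean())
    sd = float(pooled_arr.std(ddof=1))
    threshold = mean + 2.0 * sd
    excluded = tuple(
        sorted(pid for d in totals.values() for pid, v in d.items() if sd > 0 and v > threshold)
    )

    mean_before, mean_after, ci_before, ci_after = {}, {}, {}, {}
    for g in Group:
        vals = list(totals[g].values())
        kept = [v for pid, v in totals[g].items() if pid not in excluded]
        if not vals:
            continue
        mean_before[g] = float(np.mean(vals))
        ci_before[g] = bootstrap_ci(vals, seed=seed, n_resamples=n_resamples)
        mean_after[g] = float(np.mean(kept)) if kept else float("nan")
        ci_after[g] = (
            bootstrap_ci(kept, seed=seed, n_resamples=n_resamples) if kept else (float("nan"),) * 2
        )
    return SensitivityResult(
        excluded_ids=excluded,
        pooled_mean=mean,
        pooled_sd=sd,
        threshold=threshold,
        mean_before=mean_before,
        mean_after=mean_after,
        ci_before=ci_before,
        ci_after=ci_after,
    )
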