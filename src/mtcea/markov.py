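"""Two-state Markov cohort engine.

A closed cohort starts 100% non-recovered and moves between *recovered*
and *non-recovered* at 3-month cycle boundaries under per-cycle
recovery/relapse probabilities.  Each cycle accrues quality-adjusted
life years (occupancy-weighted utility times cycle length, the
area-under-the-curve reading of QALYs) and costs (non-recovered
occupancy times the arm's mean cost per non-recovered participant).
Future increments are discounted at an annual rate applied continuously
in years at the cycle midpoint.

There is no death or other absorbing state: the trial population is of
working age and the horizon is eight years, so occupancy fractions sum
to one at every cycle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import Group, ModelSpec

__all__ = ["CohortTrace", "run_cohort", "discount_factor", "predicted_recovery_curve"]


@dataclass
class CohortTrace:
    """Per-cycle occupancy and accrued endpoints for one arm.

    ``table`` has one row per cycle (1-based ``cycle``; ``month_start``/
    ``month_end`` delimit it) with occupancy fractions during the cycle,
    per-cycle increments and cumulative totals, discounted and not.
    """

    group: Group
    table: pd.DataFrame

    @property
    def total_qaly(self) -> float:
        return float(self.table["qaly_cum"].iloc[-1])

    @property
    def total_cost(self) -> float:
        return float(self.table["cost_cum"].iloc[-1])

    @property
    def total_qaly_discounted(self) -> float:
        return float(self.table["qaly_disc_cum"].iloc[-1])

    @property
    def total_cost_discounted(self) -> float:
        return float(self.table["cost_disc_cum"].iloc[-1])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def discount_factor(cycle_index: int, spec: ModelSpec) -> float:
    """Present-value factor (1+r)^(-t) for a 1-based cycle, with t the
    cycle midpoint in years.  A zero rate (or discounting disabled)
    gives 1."""
    if cycle_index < 1:
        raise ValueError("cycle_index is 1-based")
    r = spec.effective_rate
    if r == 0.0:
        return 1.0
    t_years = ((cycle_index - 1) * spec.cycle_length + spec.cycle_length / 2.0) / 12.0
    return float((1.0 + r) ** (-t_years))


def run_cohort(spec: ModelSpec, arm: Group) -> CohortTrace:
    """Run the cohort model for one arm over the full horizon.

    Cycle 1 is the per-protocol period: the whole cohort is
    non-recovered and carries the arm-specific per-protocol utility.
    From cycle 2 the pooled recovered/non-recovered utilities apply.
    The state update at the end of cycle k is
    f_N' = f_N (1 - p_recover[k]) + f_R p_relapse[k].
    """
    n = spec.n_cycles
    try:
        costs = spec.costs.per_cycle[arm]
        p_rec = spec.transitions.p_recover[arm]
        p_rel = spec.transitions.p_relapse[arm]
    except KeyError as exc:
        raise ValueError(f"model spec has no schedule for arm {arm.value}") from exc
    for name, arr in (("costs", costs), ("p_recover", p_rec), ("p_relapse", p_rel)):
        if len(arr) < n:
            raise ValueError(
                f"{name} schedule for {arm.value} covers {len(arr)} cycles; "
                f"cycle {len(arr) + 1} is missing"
            )

    u_protocol = spec.utilities.protocol(arm)
    u_r, u_n = spec.utilities.u_recovered, spec.utilities.u_non_recovered
    cycle_years = spec.cycle_length / 12.0

    f_n, f_r = 1.0, 0.0
    rows = []
    for k in range(1, n + 1):
        if k == 1:
            mean_u = u_protocol  # whole cohort non-recovered, arm-specific value
        else:
            mean_u = f_r * u_r + f_n * u_n
        if spec.half_cycle_correction and k < n:
            # trapezoidal occupancy: average the states bracketing the cycle
            f_n_next = f_n * (1.0 - p_rec[k - 1]) + f_r * p_rel[k - 1]
            f_r_next = 1.0 - f_n_next
            mean_u_next = f_r_next * u_r + f_n_next * u_n
            mean_u = 0.5 * (mean_u + mean_u_next)
        qaly_inc = mean_u * cycle_years
        cost_inc = f_n * costs[k - 1]
        disc = discount_factor(k, spec)
        rows.append(
            {
                "cycle": k,
                "month_start": (k - 1) * spec.cycle_length,
                "month_end": k * spec.cycle_length,
                "fraction_recovered": f_r,
                "fraction_non_recovered": f_n,
                "discount_factor": disc,
                "qaly_inc": qaly_inc,
                "cost_inc": cost_inc,
                "qaly_disc_inc": qaly_inc * disc,
                "cost_disc_inc": cost_inc * disc,
            }
        )
        f_n, f_r = (
            f_n * (1.0 - p_rec[k - 1]) + f_r * p_rel[k - 1],
            f_r * (1.0 - p_rel[k - 1]) + f_n * p_rec[k - 1],
        )
    table = pd.DataFrame(rows)
    for col in ("qaly", "cost", "qaly_disc", "cost_disc"):
        table[f"{col}_cum"] = table[f"{col}_inc"].cumsum()
    return CohortTrace(group=arm, table=table)


def predicted_recovery_curve(
    trace: CohortTrace, months: tuple[int, ...] | None = None
) -> list[tuple[int, float]]:
    """Model-predicted percentage recovered at given follow-up months.

    The value at month m is the recovered occupancy during the cycle
    ending at m — the state a follow-up questionnaire at m would
    observe.  Defaults to every cycle end in the trace.
    """
    t = trace.table
    by_month_end = dict(zip(t["month_end"], t["fraction_recovered"]))
    if months is None:
        months = tuple(int(m) for m in t["month_end"])
    curve = []
    for m in months:
        if m not in by_month_end:
            raise ValueError(f"no cycle ends at month {m}")
        curve.append((int(m), 100.0 * float(by_month_end[m])))
    return curve
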