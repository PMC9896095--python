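"""Follow-up panel: state classification and Markov-input estimation.

This module turns individual follow-up records (or an aggregate state
panel transcribed from published tables) into the three input sets the
cohort model needs: SF-6D utilities, per-cycle costs per non-recovered
participant, and recovery/relapse transition probabilities.

State classification is dual.  The *cost state* follows the health-care
perspective: a participant with no treatment in a period generated no
cost and counts as recovered, symptoms or not.  The *utility state*
additionally keeps untreated-but-symptomatic participants in the
non-recovered pool, because their quality-of-life values belong there.
"""

from __future__ import annotations

from collections import defaultdict
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    CYCLE_MONTHS,
    FOLLOW_UP_MONTHS,
    N_CYCLES,
    NON_RECOVERED_NO_TREATMENT,
    RECOVERED_NO_TREATMENT,
    TREATED_CATEGORIES,
    CostSchedule,
    FollowUpRecord,
    Group,
    HealthState,
    PanelError,
    StateLabel,
    TransitionSchedule,
    Treatment,
    UtilitySet,
)

__all__ = [
    "StatePanel",
    "classify_state",
    "build_state_panel",
    "weighted_utility",
    "estimate_utility_set",
    "estimate_cost_schedule",
    "estimate_transitions",
    "recovery_proportion",
    "per_cycle_probability",
    "read_panel_csv",
    "write_panel_csv",
]


# --------------------------------------------------------------------------
# state classification


def classify_state(records: Sequence[FollowUpRecord]) -> StateLabel:
    """Classify one participant-period under the dual scheme.

    ``cost_state`` is non-recovered iff any record carries a treatment;
    ``utility_state`` is non-recovered iff any treatment occurred *or*
    the participant is flagged untreated-but-not-recovered.  An empty
    record set means no care and no flag: recovered on both axes.
    """
    records = list(records)
    if records:
        pids = {r.participant_id for r in records}
        periods = {(r.period_start_month, r.period_end_month) for r in records}
        if len(pids) > 1 or len(periods) > 1:
            raise PanelError(
                f"records for participant(s) {sorted(pids)} mix periods "
                f"{sorted(periods)}; classify one participant-period at a time"
            )
        treated = [r for r in records if r.treated]
        untreated = [r for r in records if not r.treated]
        if treated and untreated:
            raise PanelError(
                f"{records[0].participant_id}: conflicting duplicate records for "
                f"period {periods.pop()} (both treated and 'none' rows)"
            )
    else:
        treated = []

    any_treatment = bool(treated)
    flagged = any(r.untreated_nonrecovered_flag for r in records)
    cost_state = HealthState.NON_RECOVERED if any_treatment else HealthState.RECOVERED
    utility_state = (
        HealthState.NON_RECOVERED if (any_treatment or flagged) else HealthState.RECOVERED
    )
    return StateLabel(cost_state=cost_state, utility_state=utility_state)


def _classification_window(follow_up_month: int, cycle_months: int = CYCLE_MONTHS) -> tuple[int, int]:
    """Half-open month window whose records determine the state reported
    at a follow-up: the single model cycle ending at that follow-up."""
    return follow_up_month - cycle_months, follow_up_month


# --------------------------------------------------------------------------
# the state panel


@dataclass
class StatePanel:
    """Counts and mean utilities per (group, follow-up, category).

    The in-memory form of the published state table: one cell per
    treatment category plus the two no-treatment categories
    (``recovered_no_treatment`` and ``non_recovered_no_treatment``).
    """

    table: pd.DataFrame  # columns: group, follow_up_month, category, count, mean_utility

    _COLUMNS = ("group", "follow_up_month", "category", "count", "mean_utility")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.table.columns)
        if missing:
            raise PanelError(f"state panel missing columns: {sorted(missing)}")
        if (self.table["count"] < 0).any():
            raise PanelError("state panel contains negative counts")

    @property
    def follow_ups(self) -> tuple[int, ...]:
        return tuple(sorted(self.table["follow_up_month"].unique()))

    def _cells(self, group: Group, month: int) -> pd.DataFrame:
        t = self.table
        sub = t[(t["group"] == group.value) & (t["follow_up_month"] == month)]
        if sub.empty:
            raise PanelError(f"no panel cells for {group.value} at {month} months")
        return sub

    def enrolled(self, group: Group, month: int) -> int:
        return int(self._cells(group, month)["count"].sum())

    def count(self, group: Group, month: int, category: str) -> int:
        sub = self._cells(group, month)
        sub = sub[sub["category"] == category]
        return int(sub["count"].sum())

    def recovered_count(self, group: Group, month: int) -> int:
        """Cost-state recovered: participants with no treatment in the
        period, whether or not they still reported the disorder."""
        sub = self._cells(group, month)
        mask = sub["category"].isin([RECOVERED_NO_TREATMENT, NON_RECOVERED_NO_TREATMENT])
        return int(sub.loc[mask, "count"].sum())

    def treated_count(self, group: Group, month: int) -> int:
        return self.enrolled(group, month) - self.recovered_count(group, month)

    def utility_cells(
        self, group: Group | None, month: int, categories: Iterable[str]
    ) -> list[tuple[float, int]]:
        """(mean_utility, count) pairs for the requested categories,
        pooled over both groups when ``group`` is None."""
        t = self.table
        mask = (t["follow_up_month"] == month) & t["category"].isin(list(categories))
        if group is not None:
            mask &= t["group"] == group.value
        sub = t[mask].dropna(subset=["mean_utility"])
        return [(float(u), int(n)) for u, n in zip(sub["mean_utility"], sub["count"])]

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StatePanel":
        df = pd.read_csv(path)
        return cls(df)


def build_state_panel(
    records: Iterable[FollowUpRecord],
    utility_flags: dict[str, dict[int, bool]] | None = None,
    follow_ups: Sequence[int] = FOLLOW_UP_MONTHS,
) -> StatePanel:
    """Tally records into a state panel at the measurement follow-ups.

    A participant is enrolled at a follow-up while they still contribute
    records to the cycle ending there (withdrawn participants simply
    stop appearing; their earlier data remain).  The treated category of
    a multi-record period is the costliest record's category.

    ``utility_flags`` optionally overrides the per-record
    untreated-but-not-recovered flag: mapping participant -> follow-up
    month -> bool.
    """
    records = list(records)
    utility_flags = utility_flags or {}
    by_participant: dict[str, list[FollowUpRecord]] = defaultdict(list)
    groups: dict[str, Group] = {}
    for r in records:
        by_participant[r.participant_id].append(r)
        if groups.setdefault(r.participant_id, r.group) is not r.group:
            raise PanelError(f"{r.participant_id}: inconsistent group labels")

    _check_disjoint_periods(by_participant)

    rows: list[dict] = []
    tallies: dict[tuple[str, int, str], list[float | None]] = defaultdict(list)
    for pid, recs in by_participant.items():
        group = groups[pid]
        for month in follow_ups:
            lo, hi = _classification_window(month)
            window = [r for r in recs if r.period_start_month < hi and r.period_end_month > lo]
            if not window:
                continue  # withdrawn before this follow-up
            flag = utility_flags.get(pid, {}).get(month)
            if flag is not None:
                window = [
                    FollowUpRecord(
                        r.participant_id, r.group, r.period_start_month, r.period_end_month,
                        r.treatment_category, r.cost_sek, r.utility, flag,
                    )
                    for r in window
                ]
            label = classify_state(_one_period(window))
            if label.cost_state is HealthState.NON_RECOVERED:
                category = max(window, key=lambda r: r.cost_sek).treatment_category.value
            elif label.utility_state is HealthState.NON_RECOVERED:
                category = NON_RECOVERED_NO_TREATMENT
            else:
                category = RECOVERED_NO_TREATMENT
            utilities = [r.utility for r in window if r.utility is not None]
            tallies[(group.value, month, category)].append(utilities[-1] if utilities else None)

    for (group, month, category), utils in sorted(tallies.items(), key=lambda kv: (kv[0][1], kv[0][0], kv[0][2])):
        present = [u for u in utils if u is not None]
        rows.append(
            {
                "group": group,
                "follow_up_month": month,
                "category": category,
                "count": len(utils),
                "mean_utility": float(np.mean(present)) if present else np.nan,
            }
        )
    return StatePanel(pd.DataFrame(rows, columns=list(StatePanel._COLUMNS)))


def _one_period(window: list[FollowUpRecord]) -> list[FollowUpRecord]:
    """Collapse a window's records onto a single nominal period so that
    classify_state's one-period precondition holds."""
    lo = min(r.period_start_month for r in window)
    hi = max(r.period_end_month for r in window)
    return [
        FollowUpRecord(
            r.participant_id, r.group, lo, hi, r.treatment_category,
            r.cost_sek, r.utility, r.untreated_nonrecovered_flag,
        )
        for r in window
    ]


def _check_disjoint_periods(by_participant: dict[str, list[FollowUpRecord]]) -> None:
    for pid, recs in by_participant.items():
        periods = sorted({(r.period_start_month, r.period_end_month) for r in recs})
        for (s1, e1), (s2, e2) in zip(periods, periods[1:]):
            if s2 < e1 and (s1, e1) != (s2, e2):
                raise PanelError(
                    f"{pid}: overlapping periods [{s1},{e1}) and [{s2},{e2})"
                )


# --------------------------------------------------------------------------
# utilities


def weighted_utility(
    cells: Sequence[tuple[float, int]], ndigits: int | None = None
) -> float:
    """Count-weighted mean utility over panel cells: sum(u*n)/sum(n).

    ``ndigits`` optionally rounds to the reporting precision (the
    published tables print 3 decimals).
    """
    cells = list(cells)
    if not cells:
        raise PanelError("no cells supplied")
    counts = np.array([n for _, n in cells], dtype=float)
    utils = np.array([u for u, _ in cells], dtype=float)
    if (counts < 0).any():
        raise PanelError("negative cell count")
    total = counts.sum()
    if total == 0:
        raise PanelError("empty stratum: all cell counts are zero")
    value = float(utils @ counts / total)
    return round(value, ndigits) if ndigits is not None else value


def estimate_utility_set(panel: StatePanel, ndigits: int | None = 3) -> UtilitySet:
    """Derive the model's four utilities from a state panel.

    Cycle 1 uses the arm-specific per-protocol means (all participants,
    first follow-up).  For months 4-96 the values are pooled over both
    arms: *non-recovered* pools the treated categories together with the
    untreated-but-not-recovered column, *recovered* is the no-treatment
    recovered column — the split that reproduces the published pooled
    values.
    """
    first, *rest = panel.follow_ups
    nonrec_cats = list(TREATED_CATEGORIES) + [NON_RECOVERED_NO_TREATMENT]
    all_cats = nonrec_cats + [RECOVERED_NO_TREATMENT]

    u_index = weighted_utility(panel.utility_cells(Group.INDEX, first, all_cats), ndigits)
    u_control = weighted_utility(panel.utility_cells(Group.CONTROL, first, all_cats), ndigits)

    nonrec_cells: list[tuple[float, int]] = []
    rec_cells: list[tuple[float, int]] = []
    for month in rest:
        nonrec_cells += panel.utility_cells(None, month, nonrec_cats)
        rec_cells += panel.utility_cells(None, month, [RECOVERED_NO_TREATMENT])
    return UtilitySet(
        u_index_protocol=u_index,
        u_control_protocol=u_control,
        u_recovered=weighted_utility(rec_cells, ndigits),
        u_non_recovered=weighted_utility(nonrec_cells, ndigits),
    )


# --------------------------------------------------------------------------
# costs


def estimate_cost_schedule(
    records: Iterable[FollowUpRecord],
    panel: StatePanel | None = None,
    n_cycles: int = N_CYCLES,
    cycle_months: int = CYCLE_MONTHS,
) -> CostSchedule:
    """Per-cycle mean cost per non-recovered participant, from records.

    The first cycle is the arm's total cost in months 0-3 divided by the
    arm size (everyone counts as non-recovered during the per-protocol
    period).  For every later record period, the period's cost total is
    divided by the number of cost-state non-recovered (treated)
    participants in that period and spread uniformly over the period's
    3-month cycles.
    """
    records = list(records)
    out = {g: np.zeros(n_cycles) for g in Group}
    for group in Group:
        recs = [r for r in records if r.group is group]
        if not recs:
            continue
        arm_ids = {r.participant_id for r in recs}
        # per-protocol cycle: mean per participant
        first = [r for r in recs if r.period_start_month < cycle_months]
        out[group][0] = sum(r.cost_sek for r in first) / len(arm_ids)
        # later periods: mean per non-recovered, spread over the period's cycles
        periods = sorted(
            {(r.period_start_month, r.period_end_month) for r in recs if r.period_start_month >= cycle_months}
        )
        for start, end in periods:
            in_period = [r for r in recs if (r.period_start_month, r.period_end_month) == (start, end)]
            total = sum(r.cost_sek for r in in_period)
            non_recovered = {r.participant_id for r in in_period if r.treated}
            if total > 0 and not non_recovered:
                raise PanelError(
                    f"{group.value} period [{start},{end}): positive cost "
                    f"{total} with zero non-recovered participants"
                )
            if not non_recovered:
                continue
            span_cycles = range(start // cycle_months, min(end // cycle_months, n_cycles))
            mean_per_cycle = total / len(non_recovered) / len(span_cycles)
            for c in span_cycles:
                out[group][c] += mean_per_cycle
    return CostSchedule(out, n_cycles=n_cycles)


# --------------------------------------------------------------------------
# transition probabilities


def per_cycle_probability(p_span: float, span_months: float, cycle_months: int = CYCLE_MONTHS) -> float:
    """Convert a probability observed over an arbitrary span to a
    per-cycle probability under a constant hazard:
    p_cycle = 1 - (1 - p_span)^(cycle/span).

    Keeps probabilities in [0, 1] for any valid input, unlike linear
    division, and compounding the cycle probability over the span
    returns the span probability exactly.
    """
    if not 0.0 <= p_span <= 1.0:
        raise ValueError(f"span probability {p_span} outside [0, 1]")
    if span_months <= 0:
        raise ValueError("span must be positive")
    return 1.0 - (1.0 - p_span) ** (cycle_months / span_months)


def estimate_transitions(
    panel: StatePanel,
    n_cycles: int = N_CYCLES,
    cycle_months: int = CYCLE_MONTHS,
) -> TransitionSchedule:
    """Recovery/relapse probabilities per group and cycle from the panel.

    Between consecutive follow-ups the net flow of the cost-state
    recovered fraction is attributed to one direction: an increase is
    newly-recovered participants divided by the previously non-recovered
    pool, a decrease is newly-non-recovered divided by the previously
    recovered pool.  Fractions (not raw counts) absorb withdrawals.
    Spans longer than one cycle are converted to per-cycle probabilities
    under a constant hazard.
    """
    p_rec = {g: np.zeros(n_cycles) for g in Group}
    p_rel = {g: np.zeros(n_cycles) for g in Group}
    months = panel.follow_ups
    for group in Group:
        for m_prev, m_next in zip(months, months[1:]):
            f_prev = panel.recovered_count(group, m_prev) / panel.enrolled(group, m_prev)
            f_next = panel.recovered_count(group, m_next) / panel.enrolled(group, m_next)
            delta = f_next - f_prev
            span = m_next - m_prev
            if delta >= 0:
                f_n = 1.0 - f_prev
                if delta > 0 and f_n <= 0:
                    raise PanelError(
                        f"{group.value} {m_prev}->{m_next} months: recovered fraction "
                        f"rose by {delta:.3f} with no non-recovered pool at {m_prev}"
                    )
                p_span_rec, p_span_rel = (delta / f_n if f_n > 0 else 0.0), 0.0
            else:
                if f_prev <= 0:
                    raise PanelError(
                        f"{group.value} {m_prev}->{m_next} months: recovered fraction "
                        f"fell with no recovered pool at {m_prev}"
                    )
                p_span_rec, p_span_rel = 0.0, -delta / f_prev
            pc_rec = per_cycle_probability(p_span_rec, span, cycle_months)
            pc_rel = per_cycle_probability(p_span_rel, span, cycle_months)
            for k in range(m_prev // cycle_months, min(m_next // cycle_months, n_cycles)):
                # boundary index k-1 ends cycle k (1-based)
                p_rec[group][k - 1] = pc_rec
                p_rel[group][k - 1] = pc_rel
    return TransitionSchedule(p_rec, p_rel, n_cycles=n_cycles)


def recovery_proportion(panel: StatePanel, group: Group, follow_up_month: int) -> int:
    """Cost-state recovery percentage at a follow-up, rounded to the
    integer percent the trial reports."""
    if follow_up_month not in panel.follow_ups:
        raise PanelError(f"no follow-up at {follow_up_month} months (have {panel.follow_ups})")
    enrolled = panel.enrolled(group, follow_up_month)
    recovered = panel.recovered_count(group, follow_up_month)
    return int(round(100.0 * recovered / enrolled))


# --------------------------------------------------------------------------
# panel CSV dialect

_PANEL_COLUMNS = [
    "participant_id",
    "group",
    "period_start_month",
    "period_end_month",
    "treatment_category",
    "cost_sek",
    "utility",
    "untreated_nonrecovered_flag",
]


def read_panel_csv(path: str | Path) -> list[FollowUpRecord]:
    """Read the long-format follow-up panel (one row per participant x
    period x treatment record).  Malformed rows raise a PanelError naming
    the file, line and field."""
    df = pd.read_csv(path, dtype={"participant_id": str}, float_precision="round_trip")
    missing = set(_PANEL_COLUMNS) - set(df.columns)
    if missing:
        raise PanelError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            group = Group(row["group"])
        except ValueError:
            raise PanelError(f"{path}:{line}: field 'group': unknown value {row['group']!r}") from None
        try:
            category = Treatment(row["treatment_category"])
        except ValueError:
            raise PanelError(
                f"{path}:{line}: field 'treatment_category': unknown value "
                f"{row['treatment_category']!r}"
            ) from None
        utility = row["utility"]
        try:
            records.append(
                FollowUpRecord(
                    participant_id=str(row["participant_id"]),
                    group=group,
                    period_start_month=int(row["period_start_month"]),
                    period_end_month=int(row["period_end_month"]),
                    treatment_category=category,
                    cost_sek=float(row["cost_sek"]),
                    utility=None if pd.isna(utility) else float(utility),
                    untreated_nonrecovered_flag=bool(row["untreated_nonrecovered_flag"]),
                )
            )
        except (PanelError, ValueError) as exc:
            raise PanelError(f"{path}:{line}: {exc}") from None
    return records


def write_panel_csv(records: Iterable[FollowUpRecord], path: str | Path) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "group": r.group.value,
            "period_start_month": r.period_start_month,
            "period_end_month": r.period_end_month,
            "treatment_category": r.treatment_category.value,
            "cost_sek": r.cost_sek,
            "utility": "" if r.utility is None else r.utility,
            "untreated_nonrecovered_flag": r.untreated_nonrecovered_flag,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_PANEL_COLUMNS).to_csv(path, index=False)
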