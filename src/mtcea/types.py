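"""Domain types for the two-state recovery cost-effectiveness model.

The analysis follows a two-arm trial (specialised manual therapy vs
orthopaedic care-as-usual) through follow-ups at 3, 6, 12 and 96 months.
Participants occupy one of two health states, *recovered* or
*non-recovered*.  Under the health-care perspective, a participant who
consumed no care in a period is "recovered" for costing purposes
regardless of symptoms; quality-of-life bookkeeping keeps a separate
state so that untreated-but-symptomatic participants can carry a
non-recovered utility.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

#: Months measured with the SF-36/SF-6D instrument.
FOLLOW_UP_MONTHS = (3, 6, 12, 96)

#: Model defaults: 3-month cycles over an 8-year horizon.
CYCLE_MONTHS = 3
HORIZON_MONTHS = 96
N_CYCLES = HORIZON_MONTHS // CYCLE_MONTHS


class Group(str, enum.Enum):
    """Trial arm under the original (intention-to-treat) allocation."""

    INDEX = "index"
    CONTROL = "control"


class Treatment(str, enum.Enum):
    """Intervention category a cost record belongs to."""

    SPECIALISED_MT = "specialised_MT"
    PHYSIOTHERAPY = "physiotherapy"
    ORTHOPAEDICS = "orthopaedics"
    SURGERY = "surgery"
    ORTHOTICS = "orthotics"
    RADIOGRAPHY_TESTS = "radiography_tests"
    DRUGS_INJECTIONS = "drugs_injections"
    PARAMEDICAL = "paramedical"
    NONE = "none"


#: Panel categories for participants with no treatment in a period.
RECOVERED_NO_TREATMENT = "recovered_no_treatment"
NON_RECOVERED_NO_TREATMENT = "non_recovered_no_treatment"

#: Categories that mark a participant as cost-state non-recovered.
TREATED_CATEGORIES = tuple(t.value for t in Treatment if t is not Treatment.NONE)


class HealthState(str, enum.Enum):
    RECOVERED = "recovered"
    NON_RECOVERED = "non_recovered"


class PanelError(ValueError):
    """Raised when follow-up records violate the panel contract."""


@dataclass(frozen=True)
class FollowUpRecord:
    """One participant x period observation.

    ``period_start_month``/``period_end_month`` delimit a half-open month
    interval within [0, 96).  ``utility`` is an SF-6D value in [0, 1] and
    is present only on rows covering a measurement follow-up.
    ``untreated_nonrecovered_flag`` marks a participant who consumed no
    care in the period but still reported the disorder (utility-state
    non-recovered while cost-state recovered).
    """

    participant_id: str
    group: Group
    period_start_month: int
    period_end_month: int
    treatment_category: Treatment
    cost_sek: float
    utility: float | None = None
    untreated_nonrecovered_flag: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.period_start_month < self.period_end_month <= HORIZON_MONTHS:
            raise PanelError(
                f"{self.participant_id}: period "
                f"[{self.period_start_month}, {self.period_end_month}) "
                f"outside [0, {HORIZON_MONTHS})"
            )
        if self.cost_sek < 0:
            raise PanelError(f"{self.participant_id}: negative cost {self.cost_sek}")
        if self.treatment_category is Treatment.NONE and self.cost_sek != 0:
            raise PanelError(
                f"{self.participant_id}: cost {self.cost_sek} without treatment"
            )
        if self.utility is not None and not 0.0 <= self.utility <= 1.0:
            raise PanelError(
                f"{self.participant_id}: utility {self.utility} outside [0, 1]"
            )

    @property
    def treated(self) -> bool:
        return self.treatment_category is not Treatment.NONE


@dataclass(frozen=True)
class StateLabel:
    """Dual state classification of one participant-period.

    ``cost_state`` follows the health-care perspective (no treatment =>
    recovered); ``utility_state`` may remain non-recovered for untreated
    participants who still report symptoms.
    """

    cost_state: HealthState
    utility_state: HealthState


@dataclass(frozen=True)
class UtilitySet:
    """SF-6D utilities feeding the model.

    The first cycle uses arm-specific per-protocol values; months 4-96
    use values pooled over both arms by recovery state.
    """

    u_index_protocol: float
    u_control_protocol: float
    u_recovered: float
    u_non_recovered: float

    def __post_init__(self) -> None:
        for name in ("u_index_protocol", "u_control_protocol", "u_recovered", "u_non_recovered"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    def protocol(self, group: Group) -> float:
        return self.u_index_protocol if group is Group.INDEX else self.u_control_protocol


@dataclass
class CostSchedule:
    """Mean cost (SEK) per non-recovered participant, per 3-month cycle.

    The first cycle is a mean per *participant* (all are considered
    non-recovered during the per-protocol period, so the two readings
    coincide in the model where the cohort starts 100% non-recovered).
    """

    per_cycle: dict[Group, np.ndarray]
    n_cycles: int = N_CYCLES

    def __post_init__(self) -> None:
        for g, arr in self.per_cycle.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.n_cycles,):
                raise ValueError(f"{g.value}: expected {self.n_cycles} cycle costs, got {arr.shape}")
            if (arr < 0).any():
                raise ValueError(f"{g.value}: negative cycle cost")
            self.per_cycle[g] = arr

    @classmethod
    def zeros(cls, n_cycles: int = N_CYCLES) -> "CostSchedule":
        return cls({g: np.zeros(n_cycles) for g in Group}, n_cycles=n_cycles)


@dataclass
class TransitionSchedule:
    """Per-group, per-cycle transition probabilities.

    ``p_recover[k]``/``p_relapse[k]`` apply at the boundary ending cycle
    k+1 (0-based index k).  Stay probabilities are the complements, so
    each row of the implied transition matrix is stochastic by
    construction.
    """

    p_recover: dict[Group, np.ndarray]
    p_relapse: dict[Group, np.ndarray]
    n_cycles: int = N_CYCLES

    def __post_init__(self) -> None:
        for d in (self.p_recover, self.p_relapse):
            for g, arr in d.items():
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (self.n_cycles,):
                    raise ValueError(f"{g.value}: expected {self.n_cycles} probabilities")
                if ((arr < 0) | (arr > 1)).any():
                    raise ValueError(f"{g.value}: probability outside [0, 1]")
                d[g] = arr

    @classmethod
    def zeros(cls, n_cycles: int = N_CYCLES) -> "TransitionSchedule":
        return cls(
            {g: np.zeros(n_cycles) for g in Group},
            {g: np.zeros(n_cycles) for g in Group},
            n_cycles=n_cycles,
        )


@dataclass
class ModelSpec:
    """Complete input set for the cohort model."""

    utilities: UtilitySet
    costs: CostSchedule
    transitions: TransitionSchedule
    cycle_length: int = CYCLE_MONTHS
    horizon: int = HORIZON_MONTHS
    discount_rate: float = 0.03
    discounting_enabled: bool = True
    half_cycle_correction: bool = False

    def __post_init__(self) -> None:
        if self.horizon % self.cycle_length != 0:
            raise ValueError("horizon must be a multiple of cycle_length")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount rate must lie in [0, 1)")

    @property
    def n_cycles(self) -> int:
        return self.horizon // self.cycle_length

    @property
    def effective_rate(self) -> float:
        return self.discount_rate if self.discounting_enabled else 0.0


@dataclass(frozen=True)
class EconResult:
    """Incremental endpoints of the index arm versus control."""

    delta_qaly: float
    delta_cost_sek: float
    icer: float | None
    verdict: str  # "dominant", "dominated", "icer" or "undefined"
    delta_qaly_discounted: float
    delta_cost_sek_discounted: float
    icer_discounted: float | None
    verdict_discounted: str


@dataclass(frozen=True)
class SensitivityResult:
    """Outcome of the 2-SD cost-outlier exclusion analysis."""

    excluded_ids: tuple[str, ...]
    pooled_mean: float
    pooled_sd: float
    threshold: float
    mean_before: dict[Group, float]
    mean_after: dict[Group, float]
    ci_before: dict[Group, tuple[float, float]]
    ci_after: dict[Group, tuple[float, float]]


@dataclass(frozen=True)
class ValidationResult:
    """Observed-vs-predicted recovery comparison at each follow-up."""

    months: tuple[int, ...]
    observed_pct: tuple[float, ...]
    predicted_pct: tuple[float, ...]
    abs_diff_pct: tuple[float, ...]
    tolerance_pct: float
    valid: bool
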