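"""Synthetic two-arm trial generator.

Emulates the structure the analysis assumes: a closed two-arm cohort
(40 index, 38 control) followed at 3, 6, 12 and 96 months, where each
participant runs a two-state recovery/relapse chain at 3-month
resolution, treated cycles draw an intervention category and a
log-normally distributed cost, SF-6D utilities are drawn around
state-specific means, some untreated participants still report the
disorder, and dropout is rare.  Every draw is recorded in a ground-truth
ledger so estimators can be checked against the generating process.

Default transition probabilities, utility means and cost magnitudes are
set to the values implied by the packaged aggregate tables, so the
default simulation reproduces the study's conditions.  Each
inter-follow-up span carries a single nonzero flow direction (recovery
or relapse), which is also what those tables imply.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .panel import per_cycle_probability
from .types import (
    CYCLE_MONTHS,
    FOLLOW_UP_MONTHS,
    HORIZON_MONTHS,
    N_CYCLES,
    FollowUpRecord,
    Group,
    Treatment,
)

__all__ = ["SimConfig", "TrialTruth", "simulate_trial"]


def _default_span_transitions() -> dict[str, list[tuple[int, int, float, float]]]:
    # (span start month, span end month, p_recover, p_relapse) per arm,
    # the net flows implied by the packaged state table:
    # control 0 -> 22/38 -> 24/37 -> 25/37 recovered,
    # index   0 -> 29/40 -> 36/38 -> 30/38 recovered.
    return {
        "control": [
            (3, 6, 22 / 38, 0.0),
            (6, 12, (24 / 37 - 22 / 38) / (16 / 38), 0.0),
            (12, 96, (25 / 37 - 24 / 37) / (13 / 37), 0.0),
        ],
        "index": [
            (3, 6, 29 / 40, 0.0),
            (6, 12, (36 / 38 - 29 / 40) / (11 / 40), 0.0),
            (12, 96, 0.0, (36 / 38 - 30 / 38) / (36 / 38)),
        ],
    }


def _default_cost_means() -> dict[str, float]:
    # mean SEK per treated 3-month cycle, by category; magnitudes follow
    # the published cost table (surgery dominates, drugs are cheap)
    return {
        "specialised_MT": 2600.0,
        "physiotherapy": 6000.0,
        "orthopaedics": 2800.0,
        "surgery": 25000.0,
        "orthotics": 1300.0,
        "radiography_tests": 1500.0,
        "drugs_injections": 350.0,
        "paramedical": 3500.0,
    }


def _default_protocol_categories() -> dict[str, dict[str, float]]:
    # per-protocol care: the index arm receives only specialised manual
    # therapy; the control arm the orthopaedic-care mix of the trial
    return {
        "index": {"specialised_MT": 1.0},
        "control": {"physiotherapy": 13 / 38, "orthopaedics": 20 / 38, "surgery": 5 / 38},
    }


def _default_later_categories() -> dict[str, float]:
    return {
        "physiotherapy": 0.45,
        "orthopaedics": 0.15,
        "surgery": 0.10,
        "paramedical": 0.15,
        "orthotics": 0.05,
        "radiography_tests": 0.05,
        "drugs_injections": 0.05,
    }


@dataclass
class SimConfig:
    """Generating parameters for a synthetic trial.

    Probabilities are per inter-follow-up span (converted internally to
    per-cycle values under a constant hazard); utilities are truncated
    normal around state means; costs are log-normal per treated cycle
    with ``cost_sigma`` the log-scale shape (0 gives deterministic
    costs).
    """

    n_index: int = 40
    n_control: int = 38
    span_transitions: dict[str, list[tuple[int, int, float, float]]] = field(
        default_factory=_default_span_transitions
    )
    u_mean_protocol: dict[str, float] = field(
        default_factory=lambda: {"index": 0.737, "control": 0.695}
    )
    u_mean_recovered: float = 0.811
    u_mean_non_recovered: float = 0.672
    u_sd: float = 0.08
    p_untreated_nonrecovered: float = 0.3
    dropout_per_follow_up: float = 0.01
    cost_means: dict[str, float] = field(default_factory=_default_cost_means)
    cost_sigma: float = 0.6
    category_probs_protocol: dict[str, dict[str, float]] = field(
        default_factory=_default_protocol_categories
    )
    category_probs_later: dict[str, float] = field(default_factory=_default_later_categories)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_index < 1 or self.n_control < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not 0.0 <= self.dropout_per_follow_up < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        probs = [self.p_untreated_nonrecovered, *(
            p for spans in self.span_transitions.values() for _, _, p_r, p_l in spans for p in (p_r, p_l)
        )]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.u_sd < 0 or self.cost_sigma < 0:
            raise ValueError("dispersions must be >= 0")

    def per_cycle_transitions(self, group: Group) -> tuple[np.ndarray, np.ndarray]:
        """Per-cycle (p_recover, p_relapse) arrays, boundary ending cycle
        k at index k-1, matching the panel estimator's convention."""
        p_rec = np.zeros(N_CYCLES)
        p_rel = np.zeros(N_CYCLES)
        for m_start, m_end, pr, pl in self.span_transitions[group.value]:
            pr_c = per_cycle_probability(pr, m_end - m_start)
            pl_c = per_cycle_probability(pl, m_end - m_start)
            for k in range(m_start // CYCLE_MONTHS, min(m_end // CYCLE_MONTHS, N_CYCLES)):
                p_rec[k - 1] = pr_c
                p_rel[k - 1] = pl_c
        return p_rec, p_rel


@dataclass
class TrialTruth:
    """Ground-truth ledger of one simulated trial.

    ``non_recovered`` maps participant -> boolean list over the 32
    cycles (True while in the non-recovered state); the tallies are the
    generator's own bookkeeping, kept independent of the panel builder.
    """

    config: SimConfig
    group_of: dict[str, str]
    non_recovered: dict[str, list[bool]]
    withdrawal_month: dict[str, int | None]
    category_tally: dict[str, int]  # "group|month|category" -> count
    recovered_fraction: dict[str, float]  # "group|month" -> cost-state fraction
    total_cost: dict[str, float]  # participant -> 96-month total
    flags: dict[str, list[int]]  # participant -> flagged follow-up months

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["config"] = {
            k: v for k, v in asdict(self.config).items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=float)


def _draw_category(rng: np.random.Generator, probs: dict[str, float]) -> Treatment:
    names = sorted(probs)
    weights = np.array([probs[n] for n in names], dtype=float)
    return Treatment(rng.choice(names, p=weights / weights.sum()))


def _draw_cost(rng: np.random.Generator, mean: float, sigma: float) -> float:
    if sigma == 0.0:
        return mean
    # parameterise the log-normal so its expectation equals `mean`
    mu = math.log(mean) - sigma**2 / 2.0
    return float(rng.lognormal(mu, sigma))


def _draw_utility(rng: np.random.Generator, mean: float, sd: float) -> float:
    # truncation to the SF-6D range by clipping; biases extreme means
    # slightly toward the interior, documented in the methods note
    return float(np.clip(rng.normal(mean, sd), 0.0, 1.0))


def simulate_trial(config: SimConfig, seed: int | None = None) -> tuple[list[FollowUpRecord], TrialTruth]:
    """Simulate one trial; identical seeds give identical output.

    Emits one record per participant per 3-month cycle until withdrawal
    (treated cycles carry a category and cost, untreated cycles a
    zero-cost 'none' row) with SF-6D measurements on the cycles ending
    at the follow-up months.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[FollowUpRecord] = []
    group_of: dict[str, str] = {}
    non_recovered: dict[str, list[bool]] = {}
    withdrawal: dict[str, int | None] = {}
    total_cost: dict[str, float] = {}
    flags: dict[str, list[int]] = {}
    category_tally: dict[str, int] = {}
    state_tally: dict[tuple[str, int], list[int]] = {}

    for group, n, prefix in (
        (Group.INDEX, config.n_index, "I"),
        (Group.CONTROL, config.n_control, "C"),
    ):
        p_rec, p_rel = config.per_cycle_transitions(group)
        for i in range(n):
            pid = f"{prefix}{i + 1:04d}"
            group_of[pid] = group.value
            # state path: non-recovered during cycle 1 (per-protocol care)
            path = [True]
            for k in range(1, N_CYCLES):
                cur = path[-1]
                u = rng.random()
                path.append((u >= p_rec[k - 1]) if cur else (u < p_rel[k - 1]))
            non_recovered[pid] = path

            # rare withdrawal before one of the later follow-ups
            w_month: int | None = None
            for f in FOLLOW_UP_MONTHS[1:]:
                if rng.random() < config.dropout_per_follow_up:
                    w_month = f - CYCLE_MONTHS
                    break
            withdrawal[pid] = w_month

            total = 0.0
            flags[pid] = []
            for k in range(1, N_CYCLES + 1):
                start, end = (k - 1) * CYCLE_MONTHS, k * CYCLE_MONTHS
                if w_month is not None and start >= w_month:
                    break
                in_nonrec = path[k - 1]
                if in_nonrec:
                    probs = (
                        config.category_probs_protocol[group.value]
                        if k == 1
                        else config.category_probs_later
                    )
                    category = _draw_category(rng, probs)
                    cost = _draw_cost(rng, config.cost_means[category.value], config.cost_sigma)
                else:
                    category, cost = Treatment.NONE, 0.0
                total += cost

                utility = None
                flagged = False
                if end in FOLLOW_UP_MONTHS:
                    if k == 1:
                        u_mean = config.u_mean_protocol[group.value]
                    elif in_nonrec:
                        u_mean = config.u_mean_non_recovered
                    else:
                        flagged = rng.random() < config.p_untreated_nonrecovered
                        u_mean = (
                            config.u_mean_non_recovered if flagged else config.u_mean_recovered
                        )
                    utility = _draw_utility(rng, u_mean, config.u_sd)
                    if flagged:
                        flags[pid].append(end)
                    # generator-side tallies for oracle tests
                    if in_nonrec:
                        tally_cat = category.value
                    elif flagged:
                        tally_cat = "non_recovered_no_treatment"
                    else:
                        tally_cat = "recovered_no_treatment"
                    key = f"{group.value}|{end}|{tally_cat}"
                    category_tally[key] = category_tally.get(key, 0) + 1
                    state_tally.setdefault((group.value, end), []).append(0 if in_nonrec else 1)

                records.append(
                    FollowUpRecord(
                        participant_id=pid,
                        group=group,
                        period_start_month=start,
                        period_end_month=end,
                        treatment_category=category,
                        cost_sek=cost,
                        utility=utility,
                        untreated_nonrecovered_flag=flagged,
                    )
                )
            total_cost[pid] = total

    recovered_fraction = {
        f"{g}|{m}": float(np.mean(v)) for (g, m), v in sorted(state_tally.items())
    }
    truth = TrialTruth(
        config=config,
        group_of=group_of,
        non_recovered=non_recovered,
        withdrawal_month=withdrawal,
        category_tally=category_tally,
        recovered_fraction=recovered_fraction,
        total_cost=total_cost,
        flags=flags,
    )
    return records, truth
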