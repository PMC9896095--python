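"""Incremental endpoints, bootstrap CIs, validation, 2-SD analysis."""

import numpy as np
import pytest

from mtcea import Group, Treatment, FollowUpRecord, run_cohort
from mtcea.economics import (
    bootstrap_ci,
    dominance_verdict,
    incremental_analysis,
    mean_cost_per_participant,
    sensitivity_two_sd,
    validate_model,
)

from conftest import make_spec


def cost_record(pid, group, total):
    return FollowUpRecord(pid, group, 0, 3, Treatment.PHYSIOTHERAPY, total)


class TestDominance:
    @pytest.mark.parametrize(
        "dc, dq, verdict, icer",
        [
            (-40_270.0, 0.159, "dominant", None),   # more QALYs at lower cost
            (40_270.0, -0.159, "dominated", None),
            (10_000.0, 0.5, "icer", 20_000.0),      # simple quotient
            (-10_000.0, -0.5, "icer", 20_000.0),    # SW quadrant still priced
            (0.0, 0.0, "icer", None),
            (5_000.0, 0.0, "undefined", None),      # cost difference, no effect
        ],
    )
    def test_quadrants(self, dc, dq, verdict, icer):
        v, i = dominance_verdict(dc, dq)
        assert v == verdict
        if icer is None:
            assert i is None
        else:
            assert i == pytest.approx(icer)

    def test_quadrants_exhaustive_and_exclusive(self):
        for dc in (-1.0, 0.0, 1.0):
            for dq in (-1.0, 0.0, 1.0):
                v, _ = dominance_verdict(dc, dq)
                assert v in {"dominant", "dominated", "icer", "undefined"}


class TestIncrementalAnalysis:
    def test_identical_traces_give_zero(self):
        spec = make_spec(p_recover=0.3, cost_per_cycle=500.0)
        t = run_cohort(spec, Group.INDEX)
        res = incremental_analysis(t, t)
        assert res.delta_qaly == 0.0
        assert res.delta_cost_sek == 0.0

    def test_dominant_when_cheaper_and_better(self):
        good = make_spec(u_non_recovered=0.7, u_recovered=0.85, p_recover=0.5, cost_per_cycle=100.0)
        bad = make_spec(u_non_recovered=0.6, u_recovered=0.8, p_recover=0.1, cost_per_cycle=1000.0)
        res = incremental_analysis(run_cohort(good, Group.INDEX), run_cohort(bad, Group.CONTROL))
        assert res.delta_qaly > 0
        assert res.delta_cost_sek < 0
        assert res.verdict == "dominant"
        assert res.verdict_discounted == "dominant"

    def test_baseline_adjustment_shift_invariance(self):
        # shifting one arm's baseline and all its utilities by a
        # constant leaves the adjusted QALY gain unchanged
        base = make_spec(
            u_protocol_index=0.6, u_protocol_control=0.6,
            u_recovered=0.8, u_non_recovered=0.6, p_recover=0.3,
        )
        c = 0.05
        shifted = make_spec(
            u_protocol_index=0.6 + c, u_protocol_control=0.6,
            u_recovered=0.8 + c, u_non_recovered=0.6 + c, p_recover=0.3,
        )
        control = run_cohort(base, Group.CONTROL)
        res0 = incremental_analysis(run_cohort(base, Group.INDEX), control,
                                    baseline_utilities=(0.6, 0.6))
        res1 = incremental_analysis(run_cohort(shifted, Group.INDEX), control,
                                    baseline_utilities=(0.6 + c, 0.6))
        assert res1.delta_qaly == pytest.approx(res0.delta_qaly, abs=1e-9)

    def test_mismatched_horizons_rejected(self):
        t1 = run_cohort(make_spec(n_cycles=8), Group.INDEX)
        t2 = run_cohort(make_spec(n_cycles=4), Group.CONTROL)
        with pytest.raises(ValueError):
            incremental_analysis(t1, t2)


class TestMeanCost:
    def test_constant_costs_zero_width_ci(self):
        records = [cost_record(f"p{i}", Group.INDEX, 500.0) for i in range(10)]
        mean, (lo, hi) = mean_cost_per_participant(records, Group.INDEX, seed=1)
        assert mean == 500.0
        assert lo == hi == 500.0

    def test_explicit_denominator(self):
        records = [cost_record(f"p{i}", Group.INDEX, 100.0) for i in range(4)]
        mean, _ = mean_cost_per_participant(records, Group.INDEX, denominator=5, seed=1)
        assert mean == pytest.approx(80.0)

    def test_empty_arm_rejected(self):
        with pytest.raises(ValueError):
            mean_cost_per_participant([], Group.CONTROL)

    def test_bootstrap_coverage_on_skewed_costs(self):
        # ~95% of percentile intervals should cover the true log-normal mean
        rng = np.random.default_rng(7)
        sigma, mean_true = 1.0, float(np.exp(0.5))  # lognormal(0, 1)
        hits = 0
        reps = 200
        for i in range(reps):
            sample = rng.lognormal(0.0, sigma, size=80)
            lo, hi = bootstrap_ci(sample, seed=1000 + i, n_resamples=600)
            hits += lo <= mean_true <= hi
        assert 0.85 <= hits / reps <= 0.99


class TestValidateModel:
    def test_perfect_agreement(self):
        obs = [(3, 0.0), (6, 58.0), (12, 65.0), (96, 68.0)]
        v = validate_model(obs, obs, tolerance_pct=5.0)
        assert v.valid
        assert max(v.abs_diff_pct) == 0.0

    def test_planted_discrepancy_fails(self):
        obs = [(6, 58.0), (12, 65.0)]
        pred = [(6, 58.0), (12, 75.0)]
        v = validate_model(pred, obs, tolerance_pct=5.0)
        assert not v.valid
        assert max(v.abs_diff_pct) == pytest.approx(10.0)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError, match="grids"):
            validate_model([(6, 50.0)], [(12, 50.0)])


class TestSensitivityTwoSd:
    def test_planted_outliers_are_the_only_exclusions(self):
        records = [cost_record(f"i{i}", Group.INDEX, 1000.0 + i) for i in range(20)]
        records += [cost_record(f"c{i}", Group.CONTROL, 1200.0 + i) for i in range(18)]
        records += [
            cost_record("c_out1", Group.CONTROL, 250_000.0),
            cost_record("c_out2", Group.CONTROL, 300_000.0),
        ]
        res = sensitivity_two_sd(records, seed=3)
        assert res.excluded_ids == ("c_out1", "c_out2")
        assert res.mean_after[Group.CONTROL] < res.mean_before[Group.CONTROL]
        # the untouched arm is reproduced exactly
        assert res.mean_after[Group.INDEX] == res.mean_before[Group.INDEX]
        assert res.ci_after[Group.INDEX] == res.ci_before[Group.INDEX]

    def test_no_outliers_reproduces_primary_result(self):
        records = [cost_record(f"p{i}", Group.INDEX, 900.0 + 10 * i) for i in range(6)]
        records += [cost_record(f"q{i}", Group.CONTROL, 1100.0 + 10 * i) for i in range(6)]
        res = sensitivity_two_sd(records, seed=5)
        assert res.excluded_ids == ()
        for g in Group:
            assert res.mean_after[g] == res.mean_before[g]
            assert res.ci_after[g] == res.ci_before[g]

    def test_small_set_below_threshold_kept(self):
        # {1,1,1,1,100}: pooled mean 20.8, sample SD ~44.3, so even the
        # 100 stays below mean + 2 SD and nothing is excluded
        records = [cost_record(f"p{i}", Group.INDEX, 1.0) for i in range(4)]
        records.append(cost_record("p_big", Group.INDEX, 100.0))
        res = sensitivity_two_sd(records, seed=2)
        assert res.pooled_mean == pytest.approx(20.8)
        assert res.pooled_sd == pytest.approx(44.28, abs=0.01)
        assert res.excluded_ids == ()

    def test_never_excludes_below_pooled_mean(self):
        rng = np.random.default_rng(9)
        records = [
            cost_record(f"p{i}", Group.INDEX if i % 2 else Group.CONTROL, float(v))
            for i, v in enumerate(rng.lognormal(8, 1.5, size=60))
        ]
        res = sensitivity_two_sd(records, seed=4)
        totals = {r.participant_id: r.cost_sek for r in records}
        for pid in res.excluded_ids:
            assert totals[pid] > res.pooled_mean

    def test_degenerate_zero_sd_excludes_nothing(self):
        records = [cost_record(f"p{i}", Group.INDEX, 100.0) for i in range(5)]
        res = sensitivity_two_sd(records, seed=6)
        assert res.pooled_sd == 0.0
        assert res.excluded_ids == ()

    def test_requires_three_individuals(self):
        with pytest.raises(ValueError):
            sensitivity_two_sd([cost_record("a", Group.INDEX, 1.0)])
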