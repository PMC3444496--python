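"""Individual simulation and cohort aggregation: hand-walked ledger checks,
determinism, Monte-Carlo consistency, and trajectory invariants."""

import copy
import math

import numpy as np
import pytest

from hivdes.cohort import PatientState
from hivdes.economics import replay_ledger
from hivdes.simulate import (
    compare_strategies,
    simulate_cohort,
    simulate_individual,
    summary_from_values,
)


def _degenerate_params(params_nnrti):
    """All event times pushed to the horizon except suppression at 6 months;
    flat markers, zero discounting, constant costs."""
    p = copy.deepcopy(params_nnrti)
    for spec in p.survival.values():
        spec.covariate_effects = {}
        spec.baseline_median = 1e6
    for strata in p.survival_strata.values():
        for spec in strata.values():
            spec.covariate_effects = {}
            spec.baseline_median = 1e6
    p.survival["viral_suppression_l12"].baseline_median = 6.0
    p.costs.discount_rate = 0.0
    p.costs.art_glm_intercept = math.log(600.0)
    p.costs.art_glm_effects = {}
    p.costs.nonart_glm_intercept = math.log(60.0)
    p.costs.nonart_glm_effects = {}
    p.adherence_effects = {}
    p.trajectory.cd4_a = {1: 0.0, 2: 0.0, 3: 0.0}
    p.trajectory.vl_a = {1: 0.0, 2: 0.0, 3: 0.0}
    # certain non-HIV death in the year starting at age 41
    p.life_table = [(float(a), 0.0, 0.0) for a in range(0, 41)]
    p.life_table.append((41.0, 1.0, 1.0))
    p.life_table += [(float(a), 1.0, 1.0) for a in range(42, 106)]
    return p


def _patient(age=39.0, death_age=41.0, cd4=300.0):
    return PatientState(
        female=0, age=age, employed=0, hcv=0, transmission="Heterosexual",
        aids=False, cd4=cd4, log10vl=4.9, adherence=0.89,
        resistance_level=0.5, resistance_class=1, line=1, nonsuppressive=False,
        regimen_number=1, n_pis=0, doses_per_day=2, pills_per_day=3,
        year_art=2003, nrti_pair="AZT+3TC", suppressed=False,
        n_failures_after_suppression=0, n_failures_no_suppression=0,
        nonhiv_death_age=death_age, baseline_log10vl=4.9,
        baseline_adherence=0.89, baseline_cd4=cd4,
    )


class TestHandWalkedScenarios:
    def test_immediate_death_absorbs_everything(self, params_nnrti, fixed_rng):
        state = _patient(death_age=39.0)
        out = simulate_individual(params_nnrti, state, fixed_rng)
        assert out.lifetime_months == 0.0
        assert out.ledger.life_years == 0.0
        assert out.ledger.total_cost == 0.0
        assert out.regimen_switches == out.line_switches == 0
        assert out.death_cause == "other"

    def test_degenerate_ledger_matches_hand_computation(self, params_nnrti, fixed_rng):
        # timeline: suppression at month 6 (median with u=0.5), certain
        # other-cause death at 24 months (age 42); constant 600/60 EUR months
        p = _degenerate_params(params_nnrti)
        out = simulate_individual(p, _patient(), fixed_rng)
        assert out.lifetime_months == pytest.approx(24.0)
        assert out.death_cause == "other"
        assert out.suppression_attained[1]
        L = out.ledger
        assert L.art_cost == pytest.approx(600.0 * 24.0)
        assert L.nonart_cost == pytest.approx(60.0 * 24.0)
        assert L.event_cost == 0.0
        assert L.life_years == pytest.approx(2.0)
        w_unsupp = p.utilities.unsuppressed[2]  # CD4 > 200
        w_supp = p.utilities.suppressed[2]
        assert L.qalys == pytest.approx(0.5 * w_unsupp + 1.5 * w_supp, abs=1e-9)
        # zero discount rate collapses the two ledgers
        assert L.art_cost == L.art_cost_undisc
        assert L.qalys == L.qalys_undisc

    def test_deadline_triggers_line_switch(self, params_nnrti, fixed_rng):
        p = _degenerate_params(params_nnrti)
        p.survival["viral_suppression_l12"].baseline_median = 1e6  # never suppress
        p.life_table = [(float(a), 0.0, 0.0) for a in range(0, 45)]
        p.life_table.append((45.0, 1.0, 1.0))
        p.life_table += [(float(a), 1.0, 1.0) for a in range(46, 106)]
        out = simulate_individual(p, _patient(death_age=46.0), fixed_rng)
        # deadline breaches at 12, 24 (lines 1, 2), then line 3 retries
        assert out.line_switches == 2
        assert out.failures_no_suppression >= 3
        assert out.suppression_attained == {1: False, 2: False, 3: False}
        assert out.ledger.event_cost == pytest.approx(
            582.0 * out.failures_no_suppression
        )


class TestLedgerReplay:
    def test_replay_reproduces_ledger_exactly(self, params_nnrti):
        from hivdes.cohort import sample_baseline

        for i in range(40):
            rng = np.random.default_rng([31, i])
            s = sample_baseline(params_nnrti, rng)
            out, trace = simulate_individual(params_nnrti, s, rng, collect_trace=True)
            replayed = replay_ledger(trace, params_nnrti)
            for f in out.ledger.__dataclass_fields__:
                assert getattr(replayed, f) == pytest.approx(
                    getattr(out.ledger, f), rel=1e-9, abs=1e-9
                ), f


class TestCohortContracts:
    def test_same_seed_is_bit_identical(self, params_nnrti):
        a = simulate_cohort(params_nnrti, 300, seed=9)
        b = simulate_cohort(params_nnrti, 300, seed=9)
        assert a.means == b.means
        assert a.ses == b.ses
        assert a.pct_attaining_suppression == b.pct_attaining_suppression

    def test_disjoint_seeds_agree_within_sampling_noise(self, params_nnrti):
        a = simulate_cohort(params_nnrti, 2500, seed=101)
        b = simulate_cohort(params_nnrti, 2500, seed=202)
        for f in ("life_years", "qalys", "total_cost"):
            gap = abs(a.means[f] - b.means[f])
            tol = 4.0 * math.hypot(a.ses[f], b.ses[f])
            assert gap <= tol, (f, gap, tol)

    def test_standard_errors_shrink_with_sqrt_n(self, params_nnrti):
        small = simulate_cohort(params_nnrti, 800, seed=7)
        large = simulate_cohort(params_nnrti, 3200, seed=7)
        ratio = large.ses["total_cost"] / small.ses["total_cost"]
        assert 0.35 < ratio < 0.7  # expect ~0.5

    def test_outcome_invariants(self, params_nnrti):
        _, outcomes = simulate_cohort(params_nnrti, 2000, seed=33,
                                      return_outcomes=True)
        for o in outcomes:
            assert o.line_switches <= 2
            assert sum(o.months_per_line.values()) == pytest.approx(
                o.lifetime_months, abs=1e-6
            )
            assert o.ledger.life_years <= o.ledger.life_years_undisc + 1e-12
            assert o.ledger.qalys <= o.ledger.life_years + 1e-12
            assert o.virological_failures == (
                o.failures_after_suppression + o.failures_no_suppression
            )
            assert min(o.regimen_switches, o.hospitalizations, o.aids_events,
                       o.resistance_events) >= 0
            assert o.death_cause in ("hiv", "other")

    def test_no_suppression_after_nonsuppressive_entry(self, params_nnrti):
        from hivdes.cohort import sample_baseline

        seen_ns = 0
        for i in range(300):
            rng = np.random.default_rng([37, i])
            s = sample_baseline(params_nnrti, rng)
            out, trace = simulate_individual(params_nnrti, s, rng, collect_trace=True)
            ns_entered = False
            for row in trace:
                if row["kind"] == "interval" and row["nonsuppressive"]:
                    ns_entered = True
                if row["kind"] == "event" and ns_entered:
                    assert row["event"] != "viral_suppression"
            seen_ns += ns_entered
        assert seen_ns > 0  # the scenario actually exercises the rule


class TestCompareStrategies:
    def test_identical_arms_have_zero_deltas(self, params_nnrti):
        s = simulate_cohort(params_nnrti, 200, seed=3)
        inc = compare_strategies(s, s)
        assert inc.delta_cost == 0.0
        assert inc.delta_qalys == 0.0
        assert inc.classification == "undefined"
        assert inc.icer_per_qaly is None

    def test_dominance_classification(self):
        a = summary_from_values("NNRTI", 100, total_cost=90.0, life_years=10.0, qalys=8.0)
        b = summary_from_values("PIr", 100, total_cost=100.0, life_years=9.9, qalys=7.9)
        assert compare_strategies(a, b).classification == "dominant"
        assert compare_strategies(b, a).classification == "dominated"

    def test_icer_computation(self):
        a = summary_from_values("NNRTI", 100, total_cost=110.0, life_years=10.0, qalys=8.5)
        b = summary_from_values("PIr", 100, total_cost=100.0, life_years=10.0, qalys=8.0)
        inc = compare_strategies(a, b)
        assert inc.classification == "icer"
        assert inc.icer_per_qaly == pytest.approx(10.0 / 0.5)

    def test_percent_difference_uses_comparator_denominator(self):
        a = summary_from_values("NNRTI", 100, total_cost=90.0, life_years=10.0,
                                qalys=8.0, regimen_switches=4.16)
        b = summary_from_values("PIr", 100, total_cost=100.0, life_years=9.0,
                                qalys=7.0, regimen_switches=5.02)
        inc = compare_strategies(a, b)
        assert inc.percent_differences["regimen_switches"] == pytest.approx(
            100.0 * (4.16 - 5.02) / 5.02
        )
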