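"""State-update rules: marker trajectories, suppression/rebound, the
adherence GLM, the resistance ladder, line rules, and regimen redraws."""

import copy
import math

import numpy as np
import pytest
from scipy import stats

from hivdes.cohort import sample_baseline
from hivdes.progression import (
    NONSUPPRESSIVE,
    advance_resistance,
    adherence_logit_coefficient,
    apply_rebound,
    apply_suppression,
    assign_switch_cause,
    cd4_change,
    classify_aids,
    draw_regimen_characteristics,
    evaluate_line_rules,
    update_adherence,
)


def _patient(params, seed=0, **overrides):
    s = sample_baseline(params, np.random.default_rng([555, seed]))
    for k, v in overrides.items():
        setattr(s, k, v)
    return s


class TestCd4Trajectory:
    def test_anchored_at_zero(self, params_nnrti):
        assert cd4_change(1, 0.0, params_nnrti.trajectory) == 0.0

    def test_first_year_gains_match_line_rates(self, params_nnrti):
        traj = params_nnrti.trajectory
        # yearly CD4 gains of 28 / 24 / 21 cells per uL in lines 1-3
        assert cd4_change(1, 12.0, traj) == pytest.approx(28.0, abs=1e-9)
        assert cd4_change(2, 12.0, traj) == pytest.approx(24.0, abs=1e-9)
        assert cd4_change(3, 12.0, traj) == pytest.approx(21.0, abs=1e-9)

    def test_nonsuppressive_decline_rate(self, params_nnrti):
        assert cd4_change(NONSUPPRESSIVE, 12.0, params_nnrti.trajectory) == pytest.approx(-17.0)

    def test_monotone_and_concave(self, params_nnrti):
        traj = params_nnrti.trajectory
        vals = [cd4_change(1, t, traj) for t in (0.0, 6.0, 12.0, 24.0, 120.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert vals[2] - vals[1] < vals[1] - vals[0]  # plateauing gains

    def test_negative_dt_rejected(self, params_nnrti):
        with pytest.raises(ValueError):
            cd4_change(1, -1.0, params_nnrti.trajectory)


class TestSuppressionRebound:
    def test_suppression_sets_detectability_floor(self, params_nnrti):
        s = _patient(params_nnrti)
        apply_suppression(s, params_nnrti.vl_floor)
        assert s.suppressed and s.log10vl == 1.69

    def test_rebound_requires_suppression(self, params_nnrti, rng):
        s = _patient(params_nnrti, suppressed=False)
        with pytest.raises(ValueError, match="suppression"):
            apply_rebound(s, rng, params_nnrti.rebound_bounds)

    def test_rebound_within_bounds(self, params_nnrti, rng):
        lo, hi = params_nnrti.rebound_bounds
        for _ in range(2000):
            s = _patient(params_nnrti, suppressed=True)
            apply_rebound(s, rng, params_nnrti.rebound_bounds)
            assert lo <= s.log10vl <= hi and not s.suppressed

    def test_mean_rebound_ratio_calibration(self, params_nnrti):
        # mean rebound-to-baseline log10 viral-load ratio of 0.83
        ratios = np.empty(100_000)
        for i in range(len(ratios)):
            r = np.random.default_rng([881, i])
            s = sample_baseline(params_nnrti, r)
            apply_suppression(s, params_nnrti.vl_floor)
            apply_rebound(s, r, params_nnrti.rebound_bounds)
            ratios[i] = s.log10vl / s.baseline_log10vl
        assert ratios.mean() == pytest.approx(0.83, abs=0.01)


class TestAdherence:
    def test_zero_linear_predictor_gives_half(self, params_nnrti):
        s = _patient(params_nnrti, baseline_adherence=0.5)
        p = update_adherence(s, params_nnrti, {}, {})
        assert p == pytest.approx(0.5)

    def test_once_daily_dosing_effect_size(self, params_nnrti):
        # 1 vs 2 doses/day moves adherence by ~1.8 percentage points at the
        # reference mean (logit slope evaluated at p=0.88)
        s = _patient(params_nnrti, baseline_adherence=0.88)
        base = update_adherence(s, params_nnrti, {"doses_1": 0.0}, {"doses_1": 0.0})
        once = update_adherence(s, params_nnrti, {"doses_1": 1.0}, {"doses_1": 0.0})
        # the marginal effect is exact on the logit scale; on the probability
        # scale the exact inverse-logit curves slightly below the 1.8-point
        # linearisation
        assert (once - base) * 100.0 == pytest.approx(1.8, abs=0.15)
        eta_diff = math.log(once / (1 - once)) - math.log(base / (1 - base))
        assert eta_diff == pytest.approx(adherence_logit_coefficient(1.8, 0.88), rel=1e-9)

    def test_output_strictly_inside_unit_interval(self, params_nnrti):
        s = _patient(params_nnrti, baseline_adherence=0.999)
        dev = {name: 1e4 for name in params_nnrti.adherence_effects}
        p = update_adherence(s, params_nnrti, dev, {})
        assert 0.0 < p < 1.0
        dev = {name: -1e4 for name in params_nnrti.adherence_effects}
        assert 0.0 < update_adherence(s, params_nnrti, dev, {}) < 1.0

    def test_logit_conversion_formula(self):
        assert adherence_logit_coefficient(1.8, 0.88) == pytest.approx(
            0.018 / (0.88 * 0.12)
        )


class TestResistanceLadder:
    def test_single_class_step_with_uniform_level(self, params_nnrti, rng):
        s = _patient(params_nnrti, resistance_level=0.5, resistance_class=1)
        advance_resistance(s, rng, params_nnrti)
        assert s.resistance_class == 2
        assert 1.0 <= s.resistance_level < 5.0

    def test_within_class_draws_are_uniform(self, params_nnrti):
        levels = np.empty(100_000)
        for i in range(len(levels)):
            r = np.random.default_rng([882, i])
            s = _patient(params_nnrti, resistance_level=2.0, resistance_class=2)
            advance_resistance(s, r, params_nnrti)
            levels[i] = s.resistance_level
        ks = stats.kstest(levels, stats.uniform(5.0, 5.0).cdf).statistic
        assert ks < 0.01

    def test_class_four_never_decreases(self, params_nnrti):
        for i in range(2000):
            r = np.random.default_rng([883, i])
            s = _patient(params_nnrti, resistance_level=20.0, resistance_class=4)
            advance_resistance(s, r, params_nnrti)
            assert s.resistance_level >= 20.0
            assert s.resistance_class == 4

    def test_class_four_triangular_support(self, params_nnrti):
        lo, mode, hi = params_nnrti.class4_triangular
        for i in range(2000):
            r = np.random.default_rng([884, i])
            s = _patient(params_nnrti, resistance_level=10.5, resistance_class=4)
            advance_resistance(s, r, params_nnrti)
            assert 10.5 <= s.resistance_level <= hi


class TestLineRules:
    def test_deadline_breach_switches_line(self, params_nnrti):
        s = _patient(params_nnrti, line=1, suppressed=False)
        action = evaluate_line_rules(s, "deadline", params_nnrti)
        assert action.action == "line_switch"
        assert action.cause == "failure_no_suppression"

    def test_line_three_failure_stays_below_class_four(self, params_nnrti):
        s = _patient(params_nnrti, line=3, resistance_class=2, resistance_level=3.0)
        action = evaluate_line_rules(s, "virological_failure", params_nnrti)
        assert action.action == "stay"
        assert action.cause == "failure_after_suppression"

    def test_line_three_class_four_starts_nonsuppressive(self, params_nnrti):
        s = _patient(params_nnrti, line=3, resistance_class=4, resistance_level=15.0)
        action = evaluate_line_rules(s, "deadline", params_nnrti)
        assert action.action == "enter_nonsuppressive"

    def test_unknown_event_rejected(self, params_nnrti):
        s = _patient(params_nnrti)
        with pytest.raises(ValueError):
            evaluate_line_rules(s, "hospitalization", params_nnrti)

    def test_no_rules_on_nonsuppressive(self, params_nnrti):
        s = _patient(params_nnrti, nonsuppressive=True)
        with pytest.raises(ValueError):
            evaluate_line_rules(s, "deadline", params_nnrti)


class TestAidsClassification:
    def test_cd4_below_two_hundred_classifies(self, params_nnrti):
        s = _patient(params_nnrti, cd4=199.0, aids=False)
        assert classify_aids(s).aids

    def test_flag_is_absorbing(self, params_nnrti):
        s = _patient(params_nnrti, cd4=450.0, aids=True)
        assert classify_aids(s).aids

    def test_boundary_is_strict(self, params_nnrti):
        s = _patient(params_nnrti, cd4=200.0, aids=False)
        assert not classify_aids(s).aids


class TestRegimenCharacteristics:
    def test_degenerate_tables_deterministic(self, params_nnrti, rng):
        p = copy.deepcopy(params_nnrti)
        p.regimen_tables[2] = {
            "n_pis": {"1": 1.0}, "doses_per_day": {"2": 1.0},
            "pills_per_day": {"4": 1.0},
        }
        for _ in range(20):
            assert draw_regimen_characteristics(2, p, rng) == (1, 2, 4)

    def test_frequencies_match_tables(self, params_nnrti):
        table = params_nnrti.regimen_tables[3]["n_pis"]
        n = 100_000
        counts = {}
        for i in range(n):
            r = np.random.default_rng([885, i])
            n_pis, _, _ = draw_regimen_characteristics(3, params_nnrti, r)
            counts[n_pis] = counts.get(n_pis, 0) + 1
        for key, prob in table.items():
            se = math.sqrt(prob * (1 - prob) / n)
            assert counts[int(key)] / n == pytest.approx(prob, abs=3 * se + 1e-9)

    def test_missing_table_rejected(self, params_nnrti, rng):
        with pytest.raises(KeyError, match="regimen table"):
            draw_regimen_characteristics(9, params_nnrti, rng)


class TestSwitchCause:
    @pytest.mark.parametrize("p,expected", [(1.0, "toxicity"), (0.0, "other")])
    def test_degenerate_probabilities(self, p, expected, rng):
        assert all(assign_switch_cause(rng, p) == expected for _ in range(50))

    def test_toxicity_fraction(self):
        n = 100_000
        hits = sum(
            assign_switch_cause(np.random.default_rng([886, i]), 0.54) == "toxicity"
            for i in range(n)
        )
        assert hits / n == pytest.approx(0.54, abs=0.005)

    def test_invalid_probability_rejected(self, rng):
        with pytest.raises(ValueError):
            assign_switch_cause(rng, 1.5)
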