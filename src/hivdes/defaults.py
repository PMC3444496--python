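"""Default two-arm parameter bundles.

Weibull shapes and covariate effects come from the published marginal-effect
table; baseline medians are calibrated to printed summary anchors (Kaplan-
Meier switch medians of 6.7 y / 2.7 y, 28 y to first resistance, 7 y between
subsequent class switches).  Quantities the source never prints (fitted
intercepts, the death Weibulls, the national life table, utility weights)
ship as documented package defaults; see docs/methods.md.
"""

from __future__ import annotations

import math

from .cohort import make_gompertz_makeham_life_table
from .params import (
    BaselineProfile,
    CostParameters,
    ModelParameters,
    SurvivalSpec,
    TrajectorySpec,
    UtilityTable,
)

# CD4 gains of 28 / 24 / 21 cells/uL over the first 12 months of lines 1-3,
# with log-curve curvature b = 0.2 / month: a = gain / ln(1 + 0.2 * 12).
_LN34 = math.log(1.0 + 0.2 * 12.0)

_CD4_A = {1: 28.0 / _LN34, 2: 24.0 / _LN34, 3: 21.0 / _LN34}
_CD4_B = {1: 0.2, 2: 0.2, 3: 0.2}

# Published marginal covariate effects on median time to event (months per
# unit deviation from the reference profile).  Non-significant effects are
# included; delete entries from a config file to switch them off.
_EFFECTS = {
    "viral_suppression_l12": {
        "female": -0.554, "age": -0.111, "log10vl": 0.951, "cd4": 0.000,
        "hcv": -1.680, "adherence_pct": -0.062, "year_art": 0.022,
        # the line-2 shift is calibrated to the reported 55% line-2
        # attainment (the published at-mean marginal, +0.485 mo, cannot
        # reproduce it under the additive-median reading)
        "n_pis": 0.297, "resistance_level": -0.847, "line2": 4.0,
    },
    "virological_failure_l12": {
        "female": 7.653, "age": 0.559, "log10vl": -19.563, "cd4": 0.026,
        "hcv": 10.094, "adherence_pct": 0.184, "year_art": 2.448,
        "n_pis": -6.120, "resistance_level": -1.894,
        "regimen_number": -8.963, "line2": -10.658,
    },
    "virological_failure_l3": {
        "female": 0.643, "age": -0.080, "log10vl": -1.550,
        "year_art": -5.188, "n_pis": -0.618, "regimen_number": 0.239,
        "resclass_2": -6.225, "resclass_3": -7.348, "resclass_4": -7.021,
    },
    "regimen_switch": {
        "female": -2.702, "age": -0.079, "log10vl": 1.321, "cd4": 0.003,
        "hcv": -5.223, "adherence_pct": -0.940, "year_art": -1.189,
        "n_pis": -5.678, "resistance_level": 0.269,
        "regimen_number": 1.071, "line2": -2.836, "line3": -1.444,
    },
    "first_resistance": {
        "female": 8.590, "age": -5.180, "log10vl": -84.450, "hcv": -26.000,
        "adherence_pct": 2.910, "year_art": -22.290, "n_pis": -33.890,
        "regimen_number": 3.990,
    },
    "resistance_class_switch": {
        "female": -0.486, "age": -0.555, "log10vl": -3.249,
        "year_art": 0.020, "n_pis": 6.850, "regimen_number": -6.310,
    },
    "hospitalization": {
        "female": 11.149, "age": -2.502, "log10vl": -18.216, "cd4": 0.146,
        "hcv": -32.008, "adherence_pct": 0.424, "year_art": 1.295,
        "n_pis": -3.453, "resistance_level": -7.927,
        "line2": -34.500, "line3": -64.061,
    },
}

_ART_GLM = {
    "female": -0.029, "age": 0.0001, "log10vl": -0.030, "cd4": -0.0001,
    "hcv": -0.015, "year_art": 0.035, "resistance_level": 0.039,
    "line2": 0.028, "prev_vf_1": 0.028, "prev_vf_gt1": 0.307,
}
_NONART_GLM = {
    "female": 0.046, "age": 0.0001, "log10vl": 0.028, "cd4": -0.0001,
    "hcv": 0.020, "adherence_pct": 0.010, "year_art": 0.042,
    "resistance_level": 0.021, "line2": 0.0001,
    "prev_vf_1": 0.0001, "prev_vf_gt1": 0.166,
}

# Percentage-point marginal effects on adherence, converted to logit scale at
# the reference adherence (0.88) inside the progression module.
_ADHERENCE_EFFECTS = {
    "female": 1.4, "age": 0.1, "hcv": -1.0, "n_pis": -1.2,
    "regimen_number": -1.6, "line2": -1.7, "line3": -3.1,
    "doses_1": 1.8, "doses_3": -2.5, "pills_per_day": 0.001,
    "art_duration_years": -0.01, "monthly_art_cost": 0.001,
}

# GLM intercepts (log euros/month at the reference profile), calibrated so
# the first-line cohort medians reproduce the printed anchors
# (ART 613/1057 euros, non-ART 63/98 euros).
_ART_INTERCEPT = {"NNRTI": 6.411006, "PIr": 6.953363}
_NONART_INTERCEPT = {"NNRTI": 4.121897, "PIr": 4.567576}

# Rebound uniform bounds on log10VL, calibrated per arm so the mean
# rebound-to-baseline log10 ratio is 0.83.
_REBOUND_BOUNDS = {"NNRTI": (3.604, 4.304), "PIr": (3.627, 4.327)}

# HIV-death Weibulls by AIDS stratum (shape, median months): unprinted in the
# source; calibrated by simulation so undiscounted life expectancy is about
# 24.3 years at the baseline case mix.
_HIV_DEATH = {
    "non_aids": (1.3, 800.0),
    "aids": (1.3, 435.0),
}

# AIDS-defining-event Weibulls stratified by current CD4 stratum (placeholder
# stand-in for the published staging model, which is cited but not printed),
# with additive transmission-group shifts in months.
_AIDS_EVENT = {
    "cd4_lt100": (1.2, 36.0),
    "cd4_100_200": (1.2, 90.0),
    "cd4_gt200": (1.2, 200.0),
}
_AIDS_TRANSMISSION_EFFECTS = {"idu": -24.0, "homosexual": 12.0, "other_transmission": 0.0}

_BASELINES = {
    "NNRTI": dict(
        p_female=0.323,
        log10vl_anchors=(4.3, 4.9, 5.4),
        cd4_anchors=(128.0, 234.0, 349.0),
        p_hcv=0.298,
        adherence_anchors=(0.71, 0.89, 0.98),
        year_art=2003,
        nrti_pair_table={"AZT+3TC": 0.55, "TDF+FTC": 0.19, "TDF+3TC": 0.09,
                         "ABC+3TC": 0.03, "Other": 0.14},
        third_agent_table={"EFV": 0.64, "NVP": 0.36},
        p_resistance_gt1=0.0127,
    ),
    "PIr": dict(
        p_female=0.340,
        log10vl_anchors=(4.3, 5.1, 5.5),
        cd4_anchors=(108.0, 219.0, 350.0),
        p_hcv=0.296,
        adherence_anchors=(0.73, 0.88, 0.96),
        year_art=2005,
        nrti_pair_table={"AZT+3TC": 0.52, "TDF+FTC": 0.23, "TDF+3TC": 0.09,
                         "ABC+3TC": 0.11, "Other": 0.05},
        third_agent_table={"LPVr": 0.73, "OtherPI": 0.27},
        p_resistance_gt1=0.0063,
    ),
}

_TRANSMISSION_TABLE = {"IDU": 0.278, "Homosexual": 0.137,
                       "Heterosexual": 0.575, "Other": 0.010}

# Regimen-characteristic tables per line (invented defaults; the fitted line-
# conditional tables are not printed).  Values: category -> probability.
_REGIMEN_TABLES = {
    "NNRTI": {
        1: {"n_pis": {"0": 0.85, "1": 0.15},
            "doses_per_day": {"1": 0.5, "2": 0.5},
            "pills_per_day": {"2": 0.2, "3": 0.5, "4": 0.3}},
        2: {"n_pis": {"0": 0.25, "1": 0.65, "2": 0.10},
            "doses_per_day": {"1": 0.25, "2": 0.65, "3": 0.10},
            "pills_per_day": {"3": 0.3, "4": 0.4, "5": 0.2, "6": 0.1}},
        3: {"n_pis": {"1": 0.50, "2": 0.40, "3": 0.10},
            "doses_per_day": {"2": 0.6, "3": 0.4},
            "pills_per_day": {"4": 0.3, "5": 0.3, "6": 0.4}},
    },
    "PIr": {
        1: {"n_pis": {"1": 0.9, "2": 0.1},
            "doses_per_day": {"1": 0.2, "2": 0.8},
            "pills_per_day": {"4": 0.3, "5": 0.3, "6": 0.4}},
        2: {"n_pis": {"0": 0.40, "1": 0.50, "2": 0.10},
            "doses_per_day": {"1": 0.3, "2": 0.6, "3": 0.1},
            "pills_per_day": {"3": 0.3, "4": 0.4, "5": 0.2, "6": 0.1}},
        3: {"n_pis": {"1": 0.50, "2": 0.40, "3": 0.10},
            "doses_per_day": {"2": 0.6, "3": 0.4},
            "pills_per_day": {"4": 0.3, "5": 0.3, "6": 0.4}},
    },
}

# Baseline medians (months) for the event-time Weibulls.  Anchored values:
# regimen switch 80.4 / 32.4 (6.7 y / 2.7 y KM medians), first resistance 336
# (28 y), class switch 84 (7 y).  The rest are package calibrations
# documented in docs/methods.md.
_BASE_MEDIANS = {
    "viral_suppression_l12": 8.5,
    "viral_suppression_l3": 13.5,
    "virological_failure_l12": 100.0,
    "virological_failure_l3": 30.0,
    "regimen_switch": {"NNRTI": 80.4, "PIr": 32.4},
    "first_resistance": 336.0,
    "resistance_class_switch": 84.0,
    "hospitalization": 78.0,
}

_SHAPES = {
    "viral_suppression_l12": 1.030,
    "viral_suppression_l3": 1.030,
    "virological_failure_l12": 1.447,
    "virological_failure_l3": 1.873,
    "regimen_switch": 1.499,
    "first_resistance": 1.501,
    "resistance_class_switch": 1.524,
    "hospitalization": 0.733,
}


def default_parameters(arm: str = "NNRTI") -> ModelParameters:
    """Build the validated default :class:`ModelParameters` for one arm."""
    if arm not in _BASELINES:
        raise ValueError(f"unknown arm {arm!r}; expected NNRTI or PIr")
    base = BaselineProfile(transmission_table=dict(_TRANSMISSION_TABLE),
                           **_BASELINES[arm])
    survival = {}
    for name, shape in _SHAPES.items():
        med = _BASE_MEDIANS[name]
        if isinstance(med, dict):
            med = med[arm]
        effects = dict(_EFFECTS.get(name, {}))
        if name == "viral_suppression_l3":
            effects = {}  # trial-based fit, not conditioned on characteristics
        survival[name] = SurvivalSpec(
            event_name=name, shape_p=shape, baseline_median=float(med),
            covariate_effects=effects,
        )
    survival_strata = {
        "hiv_death": {
            k: SurvivalSpec(event_name="hiv_death", shape_p=s,
                            baseline_median=m, strata="aids")
            for k, (s, m) in _HIV_DEATH.items()
        },
        "aids_event": {
            k: SurvivalSpec(
                event_name="aids_event", shape_p=s, baseline_median=m,
                covariate_effects=dict(_AIDS_TRANSMISSION_EFFECTS),
                strata="cd4_stratum",
            )
            for k, (s, m) in _AIDS_EVENT.items()
        },
    }
    traj = TrajectorySpec(
        cd4_a=dict(_CD4_A), cd4_b=dict(_CD4_B),
        vl_a={1: 0.0, 2: 0.0, 3: 0.0}, vl_b={1: 0.2, 2: 0.2, 3: 0.2},
        nonsuppressive_cd4_decline=17.0,
    )
    costs = CostParameters(
        art_glm_intercept=_ART_INTERCEPT[arm],
        art_glm_effects=dict(_ART_GLM),
        nonart_glm_intercept=_NONART_INTERCEPT[arm],
        nonart_glm_effects=dict(_NONART_GLM),
    )
    reference = {
        "female": 0.0,
        "age": 39.0,
        "log10vl": base.log10vl_anchors[1],
        "cd4": base.cd4_anchors[1],
        "hcv": 0.0,
        "adherence_pct": base.adherence_anchors[1] * 100.0,
        "year_art": float(base.year_art),
        "n_pis": 0.0 if arm == "NNRTI" else 1.0,
        "resistance_level": 0.0,
        "regimen_number": 1.0,
        "line2": 0.0, "line3": 0.0,
        "resclass_2": 0.0, "resclass_3": 0.0, "resclass_4": 0.0,
        "idu": 0.0, "homosexual": 0.0, "other_transmission": 0.0,
        "doses_1": 0.0, "doses_3": 0.0,
        "pills_per_day": 3.0 if arm == "NNRTI" else 6.0,
        "art_duration_years": 0.0,
        "monthly_art_cost": 613.0 if arm == "NNRTI" else 1057.0,
        "prev_vf_1": 0.0, "prev_vf_gt1": 0.0,
        "employed": 0.0,
    }
    params = ModelParameters(
        arm=arm,
        baseline=base,
        survival=survival,
        survival_strata=survival_strata,
        trajectory=traj,
        costs=costs,
        utilities=UtilityTable(),
        rebound_bounds=_REBOUND_BOUNDS[arm],
        covariate_reference=reference,
        adherence_effects=dict(_ADHERENCE_EFFECTS),
        regimen_tables={
            line: {var: dict(tab) for var, tab in tables.items()}
            for line, tables in _REGIMEN_TABLES[arm].items()
        },
        life_table=make_gompertz_makeham_life_table(),
    )
    params.validate()
    return params


def default_two_arm_parameters() -> dict[str, ModelParameters]:
    return {"NNRTI": default_parameters("NNRTI"), "PIr": default_parameters("PIr")}
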