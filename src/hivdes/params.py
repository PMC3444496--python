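"""Model parameter objects: validation, Weibull calibration, YAML IO.

Every quantity the simulation consumes lives in a :class:`ModelParameters`
bundle, one per strategy arm.  Time-to-event models are Weibull distributions
specified by a shape and a *baseline median* (months) -- the paper-style
parameterisation in which covariates shift the median additively -- and the
scale is recovered analytically so that S(median) = 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import yaml

# Registry of covariate names survival/cost models may reference.  Values fed
# to the models are deviations from the arm's reference profile (dummies have
# reference 0), so the calibrated baseline median is the median at reference.
COVARIATE_REGISTRY = frozenset(
    {
        "female",
        "age",
        "log10vl",
        "cd4",
        "hcv",
        "adherence_pct",
        "year_art",
        "n_pis",
        "resistance_level",
        "regimen_number",
        "line2",
        "line3",
        "resclass_2",
        "resclass_3",
        "resclass_4",
        "employed",
        "idu",
        "homosexual",
        "other_transmission",
        "doses_1",
        "doses_3",
        "pills_per_day",
        "art_duration_years",
        "monthly_art_cost",
        "prev_vf_1",
        "prev_vf_gt1",
    }
)

EVENT_NAMES = (
    "viral_suppression",
    "virological_failure_l12",
    "virological_failure_l3",
    "regimen_switch",
    "first_resistance",
    "resistance_class_switch",
    "hospitalization",
    "hiv_death",
)

LN2 = math.log(2.0)


def calibrate_weibull_scale(shape_p: float, target_median: float) -> float:
    """Weibull scale lambda such that Weibull(shape_p, lambda) has the given median.

    S(t) = exp(-(t/lambda)^p) = 1/2 at t = median  =>  lambda = m / (ln 2)^(1/p).
    """
    if not shape_p > 0:
        raise ValueError(f"shape_p must be > 0, got {shape_p}")
    if not target_median > 0:
        raise ValueError(f"target_median must be > 0, got {target_median}")
    return target_median / LN2 ** (1.0 / shape_p)


@dataclass
class SurvivalSpec:
    """A covariate-shifted Weibull time-to-event model.

    ``baseline_median`` is the median (months) at the reference covariate
    profile; ``covariate_effects`` maps covariate names to additive median
    shifts in months per unit deviation from reference.
    """

    event_name: str
    shape_p: float
    baseline_median: float
    covariate_effects: dict[str, float] = field(default_factory=dict)
    strata: str | None = None

    def validate(self, errors: list[str], ctx: str = "") -> None:
        if not self.shape_p > 0:
            errors.append(f"{ctx}shape_p must be > 0 (got {self.shape_p})")
        if not self.baseline_median > 0:
            errors.append(
                f"{ctx}baseline_median must be > 0 (got {self.baseline_median})"
            )
        for name in self.covariate_effects:
            if name not in COVARIATE_REGISTRY:
                errors.append(f"{ctx}unknown covariate {name!r}")


def shifted_median(
    spec: SurvivalSpec,
    covariates: dict[str, float],
    floor: float = 3.0,
    rel_floor: float = 0.25,
) -> float:
    """Median time (months) after applying additive covariate shifts.

    ``covariates`` holds deviations from the reference profile.  Additive
    marginal effects are only locally valid, so the result is floored at
    ``max(floor, rel_floor * baseline_median)`` months to keep out-of-sample
    covariate combinations from driving the median toward (or past) zero.
    """
    m = spec.baseline_median
    for name, effect in spec.covariate_effects.items():
        try:
            m += effect * covariates[name]
        except KeyError:
            raise KeyError(
                f"covariate {name!r} required by {spec.event_name} "
                "is missing from the supplied covariate map"
            ) from None
    return max(m, floor, rel_floor * spec.baseline_median)


@dataclass
class TrajectorySpec:
    """Logarithmic marker trajectories, per therapy line.

    The accumulated change after ``dt`` months in a line is
    ``a * ln(1 + b * dt)`` (zero at dt=0).  Non-suppressive therapy instead
    uses a constant CD4 decline (cells/uL per year).
    """

    cd4_a: dict[int, float] = field(default_factory=dict)  # line -> a
    cd4_b: dict[int, float] = field(default_factory=dict)  # line -> b (1/month)
    vl_a: dict[int, float] = field(default_factory=dict)
    vl_b: dict[int, float] = field(default_factory=dict)
    nonsuppressive_cd4_decline: float = 17.0  # cells/uL per year (decline)

    def validate(self, errors: list[str], ctx: str = "") -> None:
        for line in (1, 2, 3):
            if line not in self.cd4_a or line not in self.cd4_b:
                errors.append(f"{ctx}missing CD4 trajectory for line {line}")


@dataclass
class CostParameters:
    """Unit costs (2009 euros), cost GLMs, discounting."""

    discount_rate: float = 0.05
    line_switch_cost: float = 582.0
    regimen_switch_cost: float = 495.0
    adverse_event_cost_2005: float = 1126.0
    inflation_factor_2005_to_2009: float = 1.10
    aids_event_cost: float = 4765.0
    hospitalization_cost: float = 4742.0
    art_glm_intercept: float = 0.0  # log euros/month at reference
    art_glm_effects: dict[str, float] = field(default_factory=dict)
    nonart_glm_intercept: float = 0.0
    nonart_glm_effects: dict[str, float] = field(default_factory=dict)
    nonsuppressive_daily_cost_location: float = math.log(28.0)  # log euros/day
    nonsuppressive_daily_cost_scale: float = 0.3

    def validate(self, errors: list[str], ctx: str = "") -> None:
        for name in (
            "line_switch_cost",
            "regimen_switch_cost",
            "adverse_event_cost_2005",
            "aids_event_cost",
            "hospitalization_cost",
        ):
            if getattr(self, name) < 0:
                errors.append(f"{ctx}{name} must be >= 0")
        if self.discount_rate < 0:
            errors.append(f"{ctx}discount_rate must be >= 0")
        if self.nonsuppressive_daily_cost_scale < 0:
            errors.append(f"{ctx}nonsuppressive_daily_cost_scale must be >= 0")
        for glm in ("art_glm_effects", "nonart_glm_effects"):
            for name in getattr(self, glm):
                if name not in COVARIATE_REGISTRY:
                    errors.append(f"{ctx}unknown covariate {name!r} in {glm}")


@dataclass
class UtilityTable:
    """Health-state utilities by CD4 stratum x virological suppression.

    ``cd4_bounds`` are the upper bounds of each stratum; the last must be
    infinite so the strata partition [0, inf).
    """

    cd4_bounds: tuple[float, ...] = (100.0, 200.0, math.inf)
    suppressed: tuple[float, ...] = (0.854, 0.933, 0.946)
    unsuppressed: tuple[float, ...] = (0.812, 0.931, 0.933)

    def validate(self, errors: list[str], ctx: str = "") -> None:
        if list(self.cd4_bounds) != sorted(self.cd4_bounds):
            errors.append(f"{ctx}cd4_bounds must be increasing")
        if not math.isinf(self.cd4_bounds[-1]):
            errors.append(f"{ctx}last CD4 stratum bound must be inf")
        if len(self.suppressed) != len(self.cd4_bounds) or len(
            self.unsuppressed
        ) != len(self.cd4_bounds):
            errors.append(f"{ctx}utility rows must match number of CD4 strata")
        for w in tuple(self.suppressed) + tuple(self.unsuppressed):
            if not 0.0 <= w <= 1.0:
                errors.append(f"{ctx}utility weight {w} outside [0, 1]")

    def stratum(self, cd4: float) -> int:
        for i, b in enumerate(self.cd4_bounds):
            if cd4 < b:
                return i
        return len(self.cd4_bounds) - 1


@dataclass
class BaselineProfile:
    """Marginal distributions of characteristics at ART initiation."""

    p_female: float = 0.323
    age_anchors: tuple[float, float, float] = (33.0, 39.0, 47.0)  # q1, med, q3
    age_bounds: tuple[float, float] = (18.0, 80.0)
    p_employed: float = 0.66
    log10vl_anchors: tuple[float, float, float] = (4.3, 4.9, 5.4)
    log10vl_bounds: tuple[float, float] = (1.7, 7.0)
    cd4_anchors: tuple[float, float, float] = (128.0, 234.0, 349.0)
    cd4_bounds: tuple[float, float] = (0.0, 1500.0)
    p_hcv: float = 0.298
    adherence_anchors: tuple[float, float, float] = (0.71, 0.89, 0.98)
    adherence_bounds: tuple[float, float] = (0.0, 1.0)
    year_art: int = 2003
    nrti_pair_table: dict[str, float] = field(default_factory=dict)
    third_agent_table: dict[str, float] = field(default_factory=dict)
    p_resistance_gt1: float = 0.0127
    transmission_table: dict[str, float] = field(default_factory=dict)
    p_aids: float = 0.322

    def validate(self, errors: list[str], ctx: str = "") -> None:
        for name in ("p_female", "p_employed", "p_hcv", "p_resistance_gt1", "p_aids"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                errors.append(f"{ctx}{name}={p} outside [0, 1]")
        for name in ("age_anchors", "log10vl_anchors", "cd4_anchors", "adherence_anchors"):
            q1, med, q3 = getattr(self, name)
            if not q1 <= med <= q3:
                errors.append(f"{ctx}{name} quartile anchors not ordered: {q1}, {med}, {q3}")
        for name in ("nrti_pair_table", "third_agent_table", "transmission_table"):
            tab = getattr(self, name)
            if not tab:
                errors.append(f"{ctx}{name} is empty")
            elif abs(sum(tab.values()) - 1.0) > 1e-6:
                errors.append(f"{ctx}{name} probabilities sum to {sum(tab.values())}")


@dataclass
class ModelParameters:
    """Complete parameter bundle for one strategy arm."""

    arm: str  # "NNRTI" | "PIr"
    baseline: BaselineProfile
    survival: dict[str, SurvivalSpec] = field(default_factory=dict)
    # stratified models: event name -> {stratum value -> SurvivalSpec}
    survival_strata: dict[str, dict[str, SurvivalSpec]] = field(default_factory=dict)
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    costs: CostParameters = field(default_factory=CostParameters)
    utilities: UtilityTable = field(default_factory=UtilityTable)
    rebound_bounds: tuple[float, float] = (3.57, 4.27)
    resistance_bounds: tuple[float, float, float, float] = (1.0, 5.0, 10.0, 25.0)
    class4_triangular: tuple[float, float, float] = (10.0, 12.0, 25.0)
    toxicity_switch_prob: float = 0.54
    suppression_deadline: float = 12.0  # months
    max_suppressive_lines: int = 3
    vl_floor: float = 1.69  # log10(49), detectability floor
    median_floor: float = 3.0  # months, absolute floor for shifted medians
    median_rel_floor: float = 0.25  # fraction of baseline median, relative floor
    covariate_reference: dict[str, float] = field(default_factory=dict)
    adherence_effects: dict[str, float] = field(default_factory=dict)  # pp per unit
    adherence_reference_mean: float = 0.88
    regimen_tables: dict[int, dict[str, dict[str, float]]] = field(default_factory=dict)
    life_table: list[tuple[float, float, float]] = field(default_factory=list)
    max_age: float = 105.0

    REQUIRED_EVENTS = (
        "viral_suppression_l12",
        "viral_suppression_l3",
        "virological_failure_l12",
        "virological_failure_l3",
        "regimen_switch",
        "first_resistance",
        "resistance_class_switch",
        "hospitalization",
    )

    def validate(self) -> None:
        """Raise ValueError listing every violated invariant."""
        errors: list[str] = []
        if self.arm not in ("NNRTI", "PIr"):
            errors.append(f"arm must be NNRTI or PIr (got {self.arm!r})")
        self.baseline.validate(errors, "baseline: ")
        for name in self.REQUIRED_EVENTS:
            if name not in self.survival:
                errors.append(f"missing survival spec {name!r}")
        for name, spec in self.survival.items():
            spec.validate(errors, f"survival[{name}]: ")
        for ev, strata in self.survival_strata.items():
            for key, spec in strata.items():
                spec.validate(errors, f"survival_strata[{ev}][{key}]: ")
        if "hiv_death" not in self.survival_strata:
            errors.append("missing stratified survival model 'hiv_death'")
        self.trajectory.validate(errors, "trajectory: ")
        self.costs.validate(errors, "costs: ")
        self.utilities.validate(errors, "utilities: ")
        lo, hi = self.rebound_bounds
        if not lo < hi:
            errors.append(f"rebound_bounds must be increasing (got {lo}, {hi})")
        if list(self.resistance_bounds) != sorted(self.resistance_bounds) or len(
            set(self.resistance_bounds)
        ) != 4:
            errors.append("resistance_bounds must be strictly increasing")
        a, c, b = self.class4_triangular
        if not a <= c <= b:
            errors.append("class4_triangular must satisfy low <= mode <= high")
        if not 0.0 <= self.toxicity_switch_prob <= 1.0:
            errors.append("toxicity_switch_prob outside [0, 1]")
        if not self.suppression_deadline > 0:
            errors.append("suppression_deadline must be > 0")
        if not self.median_floor > 0:
            errors.append("median_floor must be > 0")
        if not 0.0 <= self.median_rel_floor < 1.0:
            errors.append("median_rel_floor must be in [0, 1)")
        for name in self.adherence_effects:
            if name not in COVARIATE_REGISTRY:
                errors.append(f"unknown covariate {name!r} in adherence_effects")
        for name in self.covariate_reference:
            if name not in COVARIATE_REGISTRY:
                errors.append(f"unknown covariate {name!r} in covariate_reference")
        if not self.life_table:
            errors.append("life_table is empty")
        for line in (1, 2, 3):
            if line not in self.regimen_tables:
                errors.append(f"missing regimen table for line {line}")
        if errors:
            raise ValueError(
                "invalid ModelParameters:\n  " + "\n  ".join(errors)
            )


# ---------------------------------------------------------------------------
# serialization

def _listify(x):
    if isinstance(x, dict):
        return {k: _listify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_listify(v) for v in x]
    return x


def _params_to_dict(p: ModelParameters) -> dict:
    return _listify(asdict(p))


def _spec_from_dict(d: dict) -> SurvivalSpec:
    return SurvivalSpec(
        event_name=d["event_name"],
        shape_p=float(d["shape_p"]),
        baseline_median=float(d["baseline_median"]),
        covariate_effects={k: float(v) for k, v in (d.get("covariate_effects") or {}).items()},
        strata=d.get("strata"),
    )


def _params_from_dict(d: dict) -> ModelParameters:
    base = d["baseline"]
    profile = BaselineProfile(
        p_female=base["p_female"],
        age_anchors=tuple(base["age_anchors"]),
        age_bounds=tuple(base["age_bounds"]),
        p_employed=base["p_employed"],
        log10vl_anchors=tuple(base["log10vl_anchors"]),
        log10vl_bounds=tuple(base["log10vl_bounds"]),
        cd4_anchors=tuple(base["cd4_anchors"]),
        cd4_bounds=tuple(base["cd4_bounds"]),
        p_hcv=base["p_hcv"],
        adherence_anchors=tuple(base["adherence_anchors"]),
        adherence_bounds=tuple(base["adherence_bounds"]),
        year_art=int(base["year_art"]),
        nrti_pair_table=dict(base["nrti_pair_table"]),
        third_agent_table=dict(base["third_agent_table"]),
        p_resistance_gt1=base["p_resistance_gt1"],
        transmission_table=dict(base["transmission_table"]),
        p_aids=base["p_aids"],
    )
    traj = TrajectorySpec(
        cd4_a={int(k): float(v) for k, v in d["trajectory"]["cd4_a"].items()},
        cd4_b={int(k): float(v) for k, v in d["trajectory"]["cd4_b"].items()},
        vl_a={int(k): float(v) for k, v in d["trajectory"]["vl_a"].items()},
        vl_b={int(k): float(v) for k, v in d["trajectory"]["vl_b"].items()},
        nonsuppressive_cd4_decline=float(
            d["trajectory"]["nonsuppressive_cd4_decline"]
        ),
    )
    costs = CostParameters(**d["costs"])
    ut = d["utilities"]
    bounds = [math.inf if b in ("inf", ".inf", None) else float(b) for b in ut["cd4_bounds"]]
    utilities = UtilityTable(
        cd4_bounds=tuple(bounds),
        suppressed=tuple(float(w) for w in ut["suppressed"]),
        unsuppressed=tuple(float(w) for w in ut["unsuppressed"]),
    )
    params = ModelParameters(
        arm=d["arm"],
        baseline=profile,
        survival={k: _spec_from_dict(v) for k, v in d["survival"].items()},
        survival_strata={
            ev: {k: _spec_from_dict(v) for k, v in strata.items()}
            for ev, strata in d["survival_strata"].items()
        },
        trajectory=traj,
        costs=costs,
        utilities=utilities,
        rebound_bounds=tuple(d["rebound_bounds"]),
        resistance_bounds=tuple(d["resistance_bounds"]),
        class4_triangular=tuple(d["class4_triangular"]),
        toxicity_switch_prob=d["toxicity_switch_prob"],
        suppression_deadline=d["suppression_deadline"],
        max_suppressive_lines=int(d["max_suppressive_lines"]),
        vl_floor=d["vl_floor"],
        median_floor=d["median_floor"],
        median_rel_floor=d.get("median_rel_floor", 0.25),
        covariate_reference={k: float(v) for k, v in d["covariate_reference"].items()},
        adherence_effects={k: float(v) for k, v in d["adherence_effects"].items()},
        adherence_reference_mean=d["adherence_reference_mean"],
        regimen_tables={
            int(line): {var: dict(tab) for var, tab in tables.items()}
            for line, tables in d["regimen_tables"].items()
        },
        life_table=[tuple(row) for row in d["life_table"]],
        max_age=d["max_age"],
    )
    return params


def save_parameters(params: dict[str, ModelParameters], path) -> None:
    """Write a two-arm parameter bundle to YAML (one document, arm-keyed)."""
    doc = {arm: _params_to_dict(p) for arm, p in params.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, default_flow_style=None, sort_keys=False)


def load_parameters(path) -> dict[str, ModelParameters]:
    """Load and validate a parameter file; returns {arm: ModelParameters}."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = {}
    for arm, d in doc.items():
        p = _params_from_dict(d)
        p.validate()
        out[arm] = p
    return out


def export_parameter_table(params: dict[str, ModelParameters], path) -> None:
    """CSV audit dump of the resolved survival parameters per arm."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arm", "event", "stratum", "shape_p", "baseline_median_months", "scale_months"])
        for arm, p in params.items():
            for name, spec in p.survival.items():
                w.writerow(
                    [arm, name, "", spec.shape_p, spec.baseline_median,
                     calibrate_weibull_scale(spec.shape_p, spec.baseline_median)]
                )
            for ev, strata in p.survival_strata.items():
                for key, spec in strata.items():
                    w.writerow(
                        [arm, ev, key, spec.shape_p, spec.baseline_median,
                         calibrate_weibull_scale(spec.shape_p, spec.baseline_median)]
                    )
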