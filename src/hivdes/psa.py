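"""Probabilistic sensitivity analysis and results reporting.

Second-order (parameter) uncertainty is propagated by drawing complete
parameter sets from a prior specification, simulating both arms with common
random numbers for each set, and summarising the resulting (delta cost,
delta QALY) cloud as dominance fractions and a cost-effectiveness
acceptability curve (CEAC).
"""

from __future__ import annotations

import copy
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters
from .simulate import CohortSummary, IncrementalResult, simulate_cohort

_RESAMPLE_CAP = 100


@dataclass
class Prior:
    """One uncertain scalar parameter.

    ``target`` is a dotted path into :class:`ModelParameters`
    (e.g. ``survival.regimen_switch.baseline_median`` or
    ``costs.hospitalization_cost`` or ``toxicity_switch_prob``),
    ``family`` one of ``lognormal`` (hyper: log-space mean implied by the
    base-case value, sd = ``sd``), ``beta`` (hyper: ``alpha``, ``beta``),
    ``normal`` or ``degenerate``.  ``bounds`` truncate by resampling.
    """

    target: str
    family: str = "lognormal"
    sd: float = 0.1
    alpha: float | None = None
    beta: float | None = None
    bounds: tuple[float, float] = (-math.inf, math.inf)
    shared_across_arms: bool = True


@dataclass
class PriorSet:
    priors: list[Prior] = field(default_factory=list)


def default_priors() -> PriorSet:
    """Documented default priors: lognormal (10% log-sd) on event-time
    medians and unit costs, beta on the toxicity-switch probability."""
    priors = [
        Prior(f"survival.{name}.baseline_median", "lognormal", sd=0.1,
              bounds=(0.5, math.inf), shared_across_arms=(name != "regimen_switch"))
        for name in (
            "viral_suppression_l12", "viral_suppression_l3",
            "virological_failure_l12", "virological_failure_l3",
            "regimen_switch", "first_resistance",
            "resistance_class_switch", "hospitalization",
        )
    ]
    priors += [
        Prior(f"survival_strata.hiv_death.{key}.baseline_median",
              "lognormal", sd=0.1, bounds=(1.0, math.inf))
        for key in ("aids", "non_aids")
    ]
    priors += [
        Prior(f"costs.{name}", "lognormal", sd=0.1, bounds=(0.0, math.inf))
        for name in (
            "line_switch_cost", "regimen_switch_cost",
            "adverse_event_cost_2005", "aids_event_cost",
            "hospitalization_cost",
        )
    ]
    priors += [
        Prior(f"costs.{name}", "normal", sd=0.05)
        for name in ("art_glm_intercept", "nonart_glm_intercept")
    ]
    priors.append(Prior("toxicity_switch_prob", "beta", alpha=54.0, beta=46.0))
    return PriorSet(priors)


def _get_path(obj, path: str):
    parts = path.split(".")
    for p in parts[:-1]:
        obj = obj[p] if isinstance(obj, dict) else getattr(obj, p)
    last = parts[-1]
    return obj, last


def _read(obj, path):
    parent, last = _get_path(obj, path)
    return parent[last] if isinstance(parent, dict) else getattr(parent, last)


def _write(obj, path, value):
    parent, last = _get_path(obj, path)
    if isinstance(parent, dict):
        parent[last] = value
    else:
        setattr(parent, last, value)


def _draw_prior(prior: Prior, base_value: float, rng) -> float:
    lo, hi = prior.bounds
    for _ in range(_RESAMPLE_CAP):
        if prior.family == "degenerate":
            return base_value
        if prior.family == "lognormal":
            v = base_value * math.exp(prior.sd * rng.standard_normal())
        elif prior.family == "normal":
            v = base_value + prior.sd * rng.standard_normal()
        elif prior.family == "beta":
            v = rng.beta(prior.alpha, prior.beta)
        else:
            raise ValueError(f"unknown prior family {prior.family!r}")
        if lo <= v <= hi:
            return v
    raise RuntimeError(f"prior for {prior.target} kept violating its bounds")


def sample_parameter_set(
    priors: PriorSet,
    base: dict[str, ModelParameters],
    rng,
) -> dict[str, ModelParameters]:
    """Draw one complete two-arm parameter bundle; revalidates invariants."""
    drawn = {arm: copy.deepcopy(p) for arm, p in base.items()}
    arms = list(drawn)
    for prior in priors.priors:
        if prior.shared_across_arms:
            # one multiplier/draw applied to every arm's base value
            if prior.family in ("lognormal", "normal"):
                z = rng.standard_normal()
                for arm in arms:
                    bv = _read(base[arm], prior.target)
                    v = (bv * math.exp(prior.sd * z) if prior.family == "lognormal"
                         else bv + prior.sd * z)
                    lo, hi = prior.bounds
                    v = min(max(v, lo), hi)
                    _write(drawn[arm], prior.target, v)
            else:
                v = _draw_prior(prior, _read(base[arms[0]], prior.target), rng)
                for arm in arms:
                    _write(drawn[arm], prior.target, v)
        else:
            for arm in arms:
                bv = _read(base[arm], prior.target)
                _write(drawn[arm], prior.target, _draw_prior(prior, bv, rng))
    for p in drawn.values():
        p.validate()
    return drawn


@dataclass
class PsaResult:
    """(delta cost, delta QALY) pairs across parameter draws, a vs b."""

    arm_a: str
    arm_b: str
    delta_costs: list[float]
    delta_qalys: list[float]
    seeds: list[int]

    def __len__(self):
        return len(self.delta_costs)


def run_psa(
    priors: PriorSet,
    base: dict[str, ModelParameters],
    n_sets: int,
    n_individuals: int,
    base_seed: int,
    arm_a: str = "NNRTI",
    arm_b: str = "PIr",
) -> PsaResult:
    """For each parameter set, simulate both arms with common random numbers
    (shared individual substreams) and record the incremental pair."""
    if n_sets < 1 or n_individuals < 1:
        raise ValueError("n_sets and n_individuals must be >= 1")
    dc, dq, seeds = [], [], []
    for k in range(n_sets):
        prior_rng = np.random.default_rng([base_seed, 1_000_000 + k])
        drawn = sample_parameter_set(priors, base, prior_rng)
        inner_seed = int(
            np.random.default_rng([base_seed, k]).integers(0, 2**31 - 1)
        )
        sa = simulate_cohort(drawn[arm_a], n_individuals, inner_seed)
        sb = simulate_cohort(drawn[arm_b], n_individuals, inner_seed)
        dc.append(sa.means["total_cost"] - sb.means["total_cost"])
        dq.append(sa.means["qalys"] - sb.means["qalys"])
        seeds.append(inner_seed)
    return PsaResult(arm_a=arm_a, arm_b=arm_b, delta_costs=dc,
                     delta_qalys=dq, seeds=seeds)


def proportion_dominant(psa: PsaResult) -> float:
    """Fraction of draws where a costs less and yields more QALYs than b."""
    if len(psa) == 0:
        raise ValueError("empty PSA result")
    hits = sum(1 for c, q in zip(psa.delta_costs, psa.delta_qalys)
               if c < 0 and q > 0)
    return hits / len(psa)


def ceac(psa: PsaResult, lambda_grid) -> list[float]:
    """P(net monetary benefit > 0) at each willingness-to-pay value."""
    out = []
    n = len(psa)
    for lam in lambda_grid:
        if lam < 0:
            raise ValueError("willingness-to-pay must be >= 0")
        hits = sum(1 for c, q in zip(psa.delta_costs, psa.delta_qalys)
                   if lam * q - c > 0)
        out.append(hits / n)
    return out


# ---------------------------------------------------------------------------
# table rendering

def render_tables(
    summaries: dict[str, CohortSummary],
    incremental: IncrementalResult,
    out_dir,
    psa: PsaResult | None = None,
    lambda_grid=None,
) -> list[str]:
    """Write the clinical-outcomes table, the cost/effectiveness table with
    incremental statistics, and optionally the CEAC, as CSV/JSON files."""
    import pandas as pd

    os.makedirs(out_dir, exist_ok=True)
    written = []
    arms = list(summaries)
    a, b = arms[0], summaries[arms[1]] if len(arms) > 1 else None

    rows = []
    for f in (
        "regimen_switches", "hospitalizations", "virological_failures",
        "failures_after_suppression", "failures_no_suppression",
        "lifetime_months", "months_line1", "months_line2", "months_line3",
        "months_ns",
    ):
        row = {"quantity": f}
        for arm in arms:
            row[arm] = summaries[arm].means[f]
        if len(arms) == 2 and summaries[arms[1]].means[f]:
            row["percent_difference"] = 100.0 * (
                summaries[arms[0]].means[f] - summaries[arms[1]].means[f]
            ) / summaries[arms[1]].means[f]
        rows.append(row)
    for line in (1, 2, 3):
        row = {"quantity": f"pct_attaining_suppression_line{line}"}
        for arm in arms:
            row[arm] = summaries[arm].pct_attaining_suppression[line]
        rows.append(row)
    for key in (2, 3, "ns"):
        row = {"quantity": f"pct_reaching_{key}"}
        for arm in arms:
            row[arm] = summaries[arm].pct_reaching_line[key]
        rows.append(row)
    path = os.path.join(out_dir, "clinical_outcomes.csv")
    pd.DataFrame(rows).to_csv(path, index=False)
    written.append(path)

    econ_rows = []
    for f, label in (
        ("art_cost", "ART costs (disc)"), ("nonart_cost", "Non-ART costs (disc)"),
        ("event_cost", "Event costs (disc)"), ("total_cost", "Total costs (disc)"),
        ("life_years", "Life years (disc)"), ("qalys", "QALYs (disc)"),
        ("total_cost_undisc", "Total costs (undisc)"),
        ("life_years_undisc", "Life years (undisc)"),
        ("qalys_undisc", "QALYs (undisc)"),
    ):
        row = {"quantity": label}
        for arm in arms:
            row[arm] = summaries[arm].means[f]
        econ_rows.append(row)
    path = os.path.join(out_dir, "cost_effectiveness.csv")
    pd.DataFrame(econ_rows).to_csv(path, index=False)
    written.append(path)

    inc = {
        "delta_cost": incremental.delta_cost,
        "delta_life_years": incremental.delta_life_years,
        "delta_qalys": incremental.delta_qalys,
        "classification": incremental.classification,
        "icer_per_qaly": incremental.icer_per_qaly,
        "icer_per_ly": incremental.icer_per_ly,
    }
    path = os.path.join(out_dir, "incremental.json")
    with open(path, "w") as fh:
        json.dump(inc, fh, indent=2)
    written.append(path)

    if psa is not None:
        grid = list(lambda_grid) if lambda_grid is not None else list(
            range(0, 101_000, 1000))
        fracs = ceac(psa, grid)
        path = os.path.join(out_dir, "ceac.csv")
        pd.DataFrame(
            {"willingness_to_pay": grid, "p_cost_effective": fracs}
        ).to_csv(path, index=False)
        written.append(path)
        path = os.path.join(out_dir, "psa_pairs.csv")
        pd.DataFrame(
            {"delta_cost": psa.delta_costs, "delta_qaly": psa.delta_qalys,
             "seed": psa.seeds}
        ).to_csv(path, index=False)
        written.append(path)
    return written
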