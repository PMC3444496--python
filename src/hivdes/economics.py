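"""Costs, discounting, and quality-adjusted life-year accounting.

All monetary values are 2009 euros from the payer (NHS) perspective, direct
medical costs only.  Continuously accruing quantities (monthly costs,
life-years, QALYs) are discounted at the midpoint of each accrual interval
with discrete annual compounding; one-off event costs are discounted at the
event time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .params import CostParameters, ModelParameters, UtilityTable


@dataclass
class CostLedger:
    """Per-individual accumulators, discounted and undiscounted."""

    art_cost: float = 0.0
    nonart_cost: float = 0.0
    event_cost: float = 0.0
    life_years: float = 0.0
    qalys: float = 0.0
    art_cost_undisc: float = 0.0
    nonart_cost_undisc: float = 0.0
    event_cost_undisc: float = 0.0
    life_years_undisc: float = 0.0
    qalys_undisc: float = 0.0

    @property
    def total_cost(self) -> float:
        return self.art_cost + self.nonart_cost + self.event_cost

    @property
    def total_cost_undisc(self) -> float:
        return self.art_cost_undisc + self.nonart_cost_undisc + self.event_cost_undisc

    def add(self, other: "CostLedger") -> None:
        for f in self.__dataclass_fields__:
            setattr(self, f, getattr(self, f) + getattr(other, f))


def discount(amount: float, time_years: float, rate: float) -> float:
    """Present value with discrete annual compounding: amount / (1+r)^t."""
    if time_years < 0:
        raise ValueError("time_years must be >= 0")
    if rate <= -1.0:
        raise ValueError("rate must be > -1")
    return amount * (1.0 + rate) ** (-time_years)


def _glm_cost(intercept: float, effects: dict[str, float],
              deviations: dict[str, float]) -> float:
    eta = intercept
    for name, beta in effects.items():
        eta += beta * deviations.get(name, 0.0)
    return math.exp(eta)


def monthly_art_cost(deviations: dict[str, float], costs: CostParameters) -> float:
    """Gamma-family log-link GLM prediction of the monthly ART cost (euros)."""
    return _glm_cost(costs.art_glm_intercept, costs.art_glm_effects, deviations)


def monthly_nonart_cost(deviations: dict[str, float], costs: CostParameters) -> float:
    """Monthly non-ART outpatient cost (euros) from the companion GLM."""
    return _glm_cost(costs.nonart_glm_intercept, costs.nonart_glm_effects, deviations)


def adverse_event_cost(costs: CostParameters) -> float:
    """2005 intolerance-episode cost inflated to 2009 prices."""
    return costs.adverse_event_cost_2005 * costs.inflation_factor_2005_to_2009


def event_cost(event: str, cause: str | None, costs: CostParameters) -> float:
    """One-off cost attached to an event occurrence (euros)."""
    if event == "line_switch":
        return costs.line_switch_cost
    if event == "regimen_switch":
        c = costs.regimen_switch_cost
        if cause == "toxicity":
            c += adverse_event_cost(costs)
        return c
    if event == "aids_event":
        return costs.aids_event_cost
    if event == "hospitalization":
        return costs.hospitalization_cost
    if event in (
        "viral_suppression", "virological_failure", "deadline",
        "first_resistance", "resistance_class_switch",
        "hiv_death", "nonhiv_death", "enter_nonsuppressive", "stay",
    ):
        return 0.0
    raise ValueError(f"unrecognised event {event!r}")


def nonsuppressive_daily_art_cost(costs: CostParameters, rng) -> float:
    """Daily ART cost on non-suppressive therapy: one lognormal draw per
    individual, fixed on entry."""
    z = rng.standard_normal()
    return math.exp(
        costs.nonsuppressive_daily_cost_location
        + costs.nonsuppressive_daily_cost_scale * z
    )


def utility_weight(cd4: float, suppressed: bool, table: UtilityTable) -> float:
    """Utility in [0, 1] by CD4 stratum and virological suppression."""
    if cd4 < 0:
        raise ValueError("cd4 must be >= 0")
    i = table.stratum(cd4)
    return table.suppressed[i] if suppressed else table.unsuppressed[i]


def accrue_interval(
    ledger: CostLedger,
    t0_months: float,
    t1_months: float,
    art_per_month: float,
    nonart_per_month: float,
    utility: float,
    rate: float,
) -> None:
    """Accrue costs, life-years and QALYs over [t0, t1) months since ART
    initiation, discounting at the interval midpoint."""
    dt = t1_months - t0_months
    if dt < 0:
        raise ValueError("interval must have t1 >= t0")
    if dt == 0:
        return
    years = dt / 12.0
    mid_years = (t0_months + t1_months) / 2.0 / 12.0
    df = (1.0 + rate) ** (-mid_years)
    art = art_per_month * dt
    nonart = nonart_per_month * dt
    ledger.art_cost_undisc += art
    ledger.nonart_cost_undisc += nonart
    ledger.life_years_undisc += years
    ledger.qalys_undisc += years * utility
    ledger.art_cost += art * df
    ledger.nonart_cost += nonart * df
    ledger.life_years += years * df
    ledger.qalys += years * utility * df


def accrue_event(ledger: CostLedger, cost: float, t_months: float, rate: float) -> None:
    ledger.event_cost_undisc += cost
    ledger.event_cost += discount(cost, t_months / 12.0, rate)


def accumulate_qalys(intervals, table: UtilityTable, rate: float) -> float:
    """Discounted QALYs for (t0_months, t1_months, cd4, suppressed) intervals."""
    total = 0.0
    for t0, t1, cd4, suppressed in intervals:
        w = utility_weight(cd4, suppressed, table)
        mid_years = (t0 + t1) / 2.0 / 12.0
        total += (t1 - t0) / 12.0 * w * (1.0 + rate) ** (-mid_years)
    return total


def replay_ledger(trace, params: ModelParameters) -> CostLedger:
    """Recompute a ledger from an event/interval trace (audit path).

    ``trace`` rows are dicts: kind="interval" rows carry the covariate
    deviations and state snapshot the simulator used; kind="event" rows carry
    the event name and cause.  The replay re-derives every euro and QALY from
    those snapshots through the same economics functions.
    """
    ledger = CostLedger()
    rate = params.costs.discount_rate
    for row in trace:
        if row["kind"] == "interval":
            if row.get("nonsuppressive"):
                art = row["daily_art_cost"] * 365.25 / 12.0
            else:
                art = monthly_art_cost(row["deviations"], params.costs)
            nonart = monthly_nonart_cost(row["deviations"], params.costs)
            w = utility_weight(row["cd4"], row["suppressed"], params.utilities)
            accrue_interval(ledger, row["t0"], row["t1"], art, nonart, w, rate)
        elif row["kind"] == "event":
            c = event_cost(row["event"], row.get("cause"), params.costs)
            accrue_event(ledger, c, row["t"], rate)
        else:
            raise ValueError(f"unknown trace row kind {row['kind']!r}")
    return ledger
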