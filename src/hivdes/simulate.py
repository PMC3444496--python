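"""Individual-level discrete-event simulation and cohort aggregation.

One individual is driven from ART initiation to death: at every decision
point the times of all admissible clinical events are sampled from their
conditional Weibull distributions given the time already survived on the
relevant clock, the earliest fires, markers and ledgers are updated, and the
line rules are re-evaluated.  Cohorts run one RNG substream per individual
derived from (seed, index), so results are order-independent and two arms
can share substreams for common-random-numbers comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .cohort import PatientState, sample_baseline
from .economics import (
    CostLedger,
    accrue_event,
    accrue_interval,
    event_cost,
    monthly_art_cost,
    monthly_nonart_cost,
    nonsuppressive_daily_art_cost,
    utility_weight,
)
from .params import ModelParameters, calibrate_weibull_scale, shifted_median
from .progression import (
    NONSUPPRESSIVE,
    advance_resistance,
    apply_rebound,
    apply_suppression,
    assign_switch_cause,
    cd4_change,
    classify_aids,
    draw_regimen_characteristics,
    evaluate_line_rules,
    update_adherence,
    vl_change,
)
from .survival import conditional_weibull_time, next_event

MONTHS_PER_YEAR = 12.0
_MAX_EVENTS = 200_000

_TRANSMISSION_DUMMY = {"IDU": "idu", "Homosexual": "homosexual", "Other": "other_transmission"}


def covariate_deviations(state: PatientState, params: ModelParameters,
                         t_months: float) -> dict[str, float]:
    """Deviations of the current covariates from the arm's reference profile."""
    ref = params.covariate_reference
    nfail = state.n_failures_after_suppression + state.n_failures_no_suppression
    dev = {
        "female": float(state.female),
        "age": state.age + t_months / MONTHS_PER_YEAR - ref["age"],
        "log10vl": state.log10vl - ref["log10vl"],
        "cd4": state.cd4 - ref["cd4"],
        "hcv": float(state.hcv),
        "adherence_pct": state.adherence * 100.0 - ref["adherence_pct"],
        "year_art": state.year_art - ref["year_art"],
        "n_pis": state.n_pis - ref["n_pis"],
        "resistance_level": state.resistance_level - ref["resistance_level"],
        "regimen_number": state.regimen_number - ref["regimen_number"],
        "line2": 1.0 if (state.line == 2 and not state.nonsuppressive) else 0.0,
        "line3": 1.0 if (state.line == 3 or state.nonsuppressive) else 0.0,
        "resclass_2": 1.0 if state.resistance_class == 2 else 0.0,
        "resclass_3": 1.0 if state.resistance_class == 3 else 0.0,
        "resclass_4": 1.0 if state.resistance_class == 4 else 0.0,
        "employed": float(state.employed),
        "doses_1": 1.0 if state.doses_per_day == 1 else 0.0,
        "doses_3": 1.0 if state.doses_per_day >= 3 else 0.0,
        "pills_per_day": state.pills_per_day - ref["pills_per_day"],
        "art_duration_years": t_months / MONTHS_PER_YEAR,
        "prev_vf_1": 1.0 if nfail == 1 else 0.0,
        "prev_vf_gt1": 1.0 if nfail > 1 else 0.0,
    }
    d = _TRANSMISSION_DUMMY.get(state.transmission)
    dev["idu"] = dev["homosexual"] = dev["other_transmission"] = 0.0
    if d:
        dev[d] = 1.0
    return dev


@dataclass
class IndividualOutcome:
    ledger: CostLedger
    lifetime_months: float
    death_cause: str  # "hiv" | "other"
    regimen_switches: int = 0
    line_switches: int = 0
    hospitalizations: int = 0
    aids_events: int = 0
    failures_after_suppression: int = 0
    failures_no_suppression: int = 0
    resistance_events: int = 0
    months_per_line: dict = field(default_factory=dict)
    suppression_attained: dict = field(default_factory=dict)
    lines_reached: dict = field(default_factory=dict)

    @property
    def virological_failures(self) -> int:
        return self.failures_after_suppression + self.failures_no_suppression


def _cd4_stratum_key(cd4: float) -> str:
    if cd4 < 100.0:
        return "cd4_lt100"
    if cd4 < 200.0:
        return "cd4_100_200"
    return "cd4_gt200"


def _sample(spec, dev, elapsed, rng, floor):
    m = shifted_median(spec, dev, floor=floor[0], rel_floor=floor[1])
    scale = calibrate_weibull_scale(spec.shape_p, m)
    u = rng.random()
    while u <= 0.0:
        u = rng.random()
    return conditional_weibull_time(spec.shape_p, scale, elapsed, u)


def simulate_individual(
    params: ModelParameters,
    baseline: PatientState,
    rng,
    collect_trace: bool = False,
):
    """Run one individual from ART initiation to death.

    Returns an :class:`IndividualOutcome`, or ``(outcome, trace)`` when
    ``collect_trace`` is set.
    """
    state = baseline
    surv = params.survival
    strata = params.survival_strata
    floor = (params.median_floor, params.median_rel_floor)
    rate = params.costs.discount_rate
    deadline = params.suppression_deadline

    t = 0.0
    line_start = 0.0  # marker / line clock
    regimen_start = 0.0
    supp_clock_start = 0.0
    suppression_start = 0.0
    # renewal clocks: recurring events restart at their last occurrence
    last_hosp = 0.0
    last_aids = 0.0
    last_resist = 0.0
    daily_ns_cost = 0.0
    failed_in_line = False
    nonhiv_death_t = max(
        (state.nonhiv_death_age - state.age) * MONTHS_PER_YEAR, 0.0
    )

    ledger = CostLedger()
    out = IndividualOutcome(ledger=ledger, lifetime_months=0.0, death_cause="other")
    out.months_per_line = {1: 0.0, 2: 0.0, 3: 0.0, "ns": 0.0}
    out.suppression_attained = {1: False, 2: False, 3: False}
    out.lines_reached = {1: True, 2: False, 3: False, "ns": False}
    trace: list[dict] = []

    baseline_dev = covariate_deviations(state, params, 0.0)
    baseline_dev["monthly_art_cost"] = 0.0
    baseline_dev["art_duration_years"] = 0.0

    for _ in range(_MAX_EVENTS):
        dev = covariate_deviations(state, params, t)
        if state.nonsuppressive:
            art_month = daily_ns_cost * 365.25 / MONTHS_PER_YEAR
        else:
            art_month = monthly_art_cost(dev, params.costs)
        dev["monthly_art_cost"] = art_month - params.covariate_reference["monthly_art_cost"]
        update_adherence(state, params, dev, baseline_dev)
        dev["adherence_pct"] = (
            state.adherence * 100.0 - params.covariate_reference["adherence_pct"]
        )
        nonart_month = monthly_nonart_cost(dev, params.costs)

        # --- candidate events ----------------------------------------------
        candidates = [("nonhiv_death", nonhiv_death_t)]
        death_spec = strata["hiv_death"]["aids" if state.aids else "non_aids"]
        candidates.append(("hiv_death", _sample(death_spec, dev, t, rng, floor)))
        aids_spec = strata["aids_event"][_cd4_stratum_key(state.cd4)]
        candidates.append(
            ("aids_event",
             last_aids + _sample(aids_spec, dev, t - last_aids, rng, floor)))
        candidates.append(
            ("hospitalization",
             last_hosp + _sample(surv["hospitalization"], dev, t - last_hosp,
                                 rng, floor)))
        # resistance ladder: classes 2-3 can step up anywhere on therapy;
        # within-class-4 level increases belong to non-suppressive therapy
        if state.resistance_class == 1:
            candidates.append(("first_resistance",
                               _sample(surv["first_resistance"], dev, t, rng, floor)))
        elif state.resistance_class < 4 or state.nonsuppressive:
            candidates.append(
                ("resistance_class_switch",
                 last_resist + _sample(surv["resistance_class_switch"], dev,
                                       t - last_resist, rng, floor)))
        if not state.nonsuppressive:
            candidates.append(
                ("regimen_switch",
                 regimen_start + _sample(surv["regimen_switch"], dev,
                                         t - regimen_start, rng, floor))
            )
            if state.suppressed:
                vf = surv["virological_failure_l3" if state.line == 3
                          else "virological_failure_l12"]
                candidates.append(
                    ("virological_failure",
                     suppression_start + _sample(vf, dev, t - suppression_start,
                                                 rng, floor))
                )
            else:
                supp = surv["viral_suppression_l3" if state.line == 3
                            else "viral_suppression_l12"]
                candidates.append(
                    ("viral_suppression",
                     supp_clock_start + _sample(supp, dev, t - supp_clock_start,
                                                rng, floor))
                )
                candidates.append(("deadline", supp_clock_start + deadline))

        event, t_next = next_event(candidates)
        t_next = max(t_next, t)

        # --- accrue the interval [t, t_next) -------------------------------
        w = utility_weight(state.cd4, state.suppressed, params.utilities)
        accrue_interval(ledger, t, t_next, art_month, nonart_month, w, rate)
        line_key = "ns" if state.nonsuppressive else state.line
        out.months_per_line[line_key] += t_next - t
        if collect_trace:
            trace.append({
                "kind": "interval", "t0": t, "t1": t_next,
                "deviations": dict(dev), "cd4": state.cd4,
                "suppressed": state.suppressed,
                "nonsuppressive": state.nonsuppressive,
                "daily_art_cost": daily_ns_cost,
                "line": state.line,
                "resistance_class": state.resistance_class,
                "aids": state.aids,
            })

        # --- advance markers over the interval -----------------------------
        dt0 = t - line_start
        dt1 = t_next - line_start
        marker_line = NONSUPPRESSIVE if state.nonsuppressive else state.line
        state.cd4 = max(
            state.cd4
            + cd4_change(marker_line, dt1, params.trajectory)
            - cd4_change(marker_line, dt0, params.trajectory),
            0.0,
        )
        if not state.suppressed and not state.nonsuppressive:
            state.log10vl += (
                vl_change(marker_line, dt1, params.trajectory)
                - vl_change(marker_line, dt0, params.trajectory)
            )
        classify_aids(state)
        t = t_next

        # --- apply the event ------------------------------------------------
        cause = None
        if event in ("nonhiv_death", "hiv_death"):
            out.death_cause = "hiv" if event == "hiv_death" else "other"
            if collect_trace:
                trace.append({"kind": "event", "event": event, "t": t, "cause": None})
            break

        if event == "viral_suppression":
            apply_suppression(state, params.vl_floor)
            suppression_start = t
            # attainment is scored on the line's first regimen attempt, the
            # definition that is comparable across lines (lines 1-2 exit the
            # line at their first failure; line 3 retries indefinitely)
            if not failed_in_line:
                out.suppression_attained[state.line] = True
        elif event in ("deadline", "virological_failure"):
            if event == "virological_failure":
                apply_rebound(state, rng, params.rebound_bounds)
                state.n_failures_after_suppression += 1
                out.failures_after_suppression += 1
            else:
                state.n_failures_no_suppression += 1
                out.failures_no_suppression += 1
            action = evaluate_line_rules(state, event, params)
            cause = action.cause
            failed_in_line = True
            if action.action == "line_switch":
                state.line += 1
                out.line_switches += 1
                out.lines_reached[state.line] = True
                state.regimen_number += 1
                (state.n_pis, state.doses_per_day,
                 state.pills_per_day) = draw_regimen_characteristics(
                     state.line, params, rng)
                state.suppressed = False
                failed_in_line = False
                line_start = regimen_start = supp_clock_start = t
                accrue_event(ledger, params.costs.line_switch_cost, t, rate)
                ledger_event = "line_switch"
            elif action.action == "enter_nonsuppressive":
                state.nonsuppressive = True
                out.lines_reached["ns"] = True
                state.suppressed = False
                daily_ns_cost = nonsuppressive_daily_art_cost(params.costs, rng)
                line_start = regimen_start = t
                accrue_event(ledger, params.costs.line_switch_cost, t, rate)
                ledger_event = "line_switch"
            else:  # stay: line-3 regimen reshuffle after failure
                state.regimen_number += 1
                (state.n_pis, state.doses_per_day,
                 state.pills_per_day) = draw_regimen_characteristics(
                     state.line, params, rng)
                regimen_start = supp_clock_start = t
                accrue_event(ledger, params.costs.line_switch_cost, t, rate)
                ledger_event = "line_switch"
            if collect_trace:
                trace.append({"kind": "event", "event": ledger_event, "t": t,
                              "cause": cause})
            continue
        elif event == "regimen_switch":
            cause = assign_switch_cause(rng, params.toxicity_switch_prob)
            out.regimen_switches += 1
            state.regimen_number += 1
            (state.n_pis, state.doses_per_day,
             state.pills_per_day) = draw_regimen_characteristics(
                 state.line, params, rng)
            regimen_start = t
            accrue_event(ledger, event_cost("regimen_switch", cause, params.costs),
                         t, rate)
        elif event in ("first_resistance", "resistance_class_switch"):
            advance_resistance(state, rng, params)
            out.resistance_events += 1
            last_resist = t
        elif event == "hospitalization":
            out.hospitalizations += 1
            last_hosp = t
            accrue_event(ledger, params.costs.hospitalization_cost, t, rate)
        elif event == "aids_event":
            classify_aids(state, aids_event_fired=True)
            out.aids_events += 1
            last_aids = t
            accrue_event(ledger, params.costs.aids_event_cost, t, rate)
        if collect_trace:
            trace.append({"kind": "event", "event": event, "t": t, "cause": cause})
    else:
        raise RuntimeError("event cap reached without death; check parameters")

    out.lifetime_months = t
    return (out, trace) if collect_trace else out


# ---------------------------------------------------------------------------
# cohort level

_SCALAR_FIELDS = (
    "total_cost", "art_cost", "nonart_cost", "event_cost",
    "life_years", "qalys",
    "total_cost_undisc", "art_cost_undisc", "nonart_cost_undisc",
    "event_cost_undisc", "life_years_undisc", "qalys_undisc",
    "regimen_switches", "line_switches", "hospitalizations", "aids_events",
    "failures_after_suppression", "failures_no_suppression",
    "virological_failures", "lifetime_months",
    "months_line1", "months_line2", "months_line3", "months_ns",
)


@dataclass
class CohortSummary:
    arm: str
    n: int
    means: dict[str, float]
    ses: dict[str, float]
    pct_attaining_suppression: dict[int, float]  # of those entering the line
    pct_reaching_line: dict[str, float]  # of the whole cohort

    def validate(self) -> None:
        for d in (self.pct_attaining_suppression, self.pct_reaching_line):
            for v in d.values():
                assert 0.0 <= v <= 100.0
        seq = [self.pct_reaching_line[k] for k in (2, 3, "ns")]
        assert all(a >= b for a, b in zip(seq, seq[1:])), seq


def _outcome_row(o: IndividualOutcome) -> dict[str, float]:
    L = o.ledger
    return {
        "total_cost": L.total_cost, "art_cost": L.art_cost,
        "nonart_cost": L.nonart_cost, "event_cost": L.event_cost,
        "life_years": L.life_years, "qalys": L.qalys,
        "total_cost_undisc": L.total_cost_undisc,
        "art_cost_undisc": L.art_cost_undisc,
        "nonart_cost_undisc": L.nonart_cost_undisc,
        "event_cost_undisc": L.event_cost_undisc,
        "life_years_undisc": L.life_years_undisc,
        "qalys_undisc": L.qalys_undisc,
        "regimen_switches": o.regimen_switches,
        "line_switches": o.line_switches,
        "hospitalizations": o.hospitalizations,
        "aids_events": o.aids_events,
        "failures_after_suppression": o.failures_after_suppression,
        "failures_no_suppression": o.failures_no_suppression,
        "virological_failures": o.virological_failures,
        "lifetime_months": o.lifetime_months,
        "months_line1": o.months_per_line[1],
        "months_line2": o.months_per_line[2],
        "months_line3": o.months_per_line[3],
        "months_ns": o.months_per_line["ns"],
    }


def simulate_cohort(
    params: ModelParameters,
    n: int,
    seed: int,
    return_outcomes: bool = False,
):
    """Simulate ``n`` independent individuals on substreams (seed, index)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cols = {f: np.empty(n) for f in _SCALAR_FIELDS}
    attained = {1: 0, 2: 0, 3: 0}
    entered = {1: 0, 2: 0, 3: 0}
    reached = {2: 0, 3: 0, "ns": 0}
    outcomes = [] if return_outcomes else None
    for i in range(n):
        rng = np.random.default_rng([seed, i])
        state = sample_baseline(params, rng)
        o = simulate_individual(params, state, rng)
        row = _outcome_row(o)
        for f in _SCALAR_FIELDS:
            cols[f][i] = row[f]
        for line in (1, 2, 3):
            if line == 1 or o.lines_reached[line]:
                entered[line] += 1
                if o.suppression_attained[line]:
                    attained[line] += 1
        for key in (2, 3, "ns"):
            if o.lines_reached[key]:
                reached[key] += 1
        if return_outcomes:
            outcomes.append(o)
    means = {f: float(np.mean(cols[f])) for f in _SCALAR_FIELDS}
    ses = {f: float(np.std(cols[f], ddof=1) / math.sqrt(n)) if n > 1 else 0.0
           for f in _SCALAR_FIELDS}
    summary = CohortSummary(
        arm=params.arm,
        n=n,
        means=means,
        ses=ses,
        pct_attaining_suppression={
            line: 100.0 * attained[line] / entered[line] if entered[line] else 0.0
            for line in (1, 2, 3)
        },
        pct_reaching_line={key: 100.0 * reached[key] / n for key in (2, 3, "ns")},
    )
    summary.validate()
    return (summary, outcomes) if return_outcomes else summary


# ---------------------------------------------------------------------------
# strategy comparison

@dataclass
class IncrementalResult:
    """Incremental statistics of strategy a versus comparator b."""

    delta_cost: float
    delta_life_years: float
    delta_qalys: float
    icer_per_qaly: float | None  # None when dominant/dominated/undefined
    icer_per_ly: float | None
    classification: str  # "dominant" | "dominated" | "icer" | "undefined"
    percent_differences: dict[str, float] = field(default_factory=dict)


def _classify(delta_c: float, delta_e: float):
    if delta_c < 0 and delta_e > 0:
        return "dominant", None
    if delta_c > 0 and delta_e < 0:
        return "dominated", None
    if delta_e == 0:
        return ("undefined", None) if delta_c != 0 else ("undefined", None)
    return "icer", delta_c / delta_e


def compare_strategies(a: CohortSummary, b: CohortSummary) -> IncrementalResult:
    """Incremental cost-effectiveness of ``a`` against comparator ``b``.

    Percent differences use the comparator as the denominator.
    """
    dc = a.means["total_cost"] - b.means["total_cost"]
    dly = a.means["life_years"] - b.means["life_years"]
    dq = a.means["qalys"] - b.means["qalys"]
    cls, icer_q = _classify(dc, dq)
    _, icer_ly = _classify(dc, dly)
    pct = {}
    for f in _SCALAR_FIELDS:
        denom = b.means.get(f)
        if denom:
            pct[f] = 100.0 * (a.means[f] - denom) / denom
    return IncrementalResult(
        delta_cost=dc,
        delta_life_years=dly,
        delta_qalys=dq,
        icer_per_qaly=icer_q,
        icer_per_ly=icer_ly,
        classification=cls,
        percent_differences=pct,
    )


def summary_from_values(arm: str, n: int, total_cost: float, life_years: float,
                        qalys: float, **extra_means) -> CohortSummary:
    """Build a CohortSummary from externally supplied per-arm means (e.g. a
    published results table) for incremental-statistics computation."""
    means = {f: math.nan for f in _SCALAR_FIELDS}
    means.update(total_cost=total_cost, life_years=life_years, qalys=qalys)
    means.update(extra_means)
    return CohortSummary(
        arm=arm, n=n, means=means, ses={f: math.nan for f in _SCALAR_FIELDS},
        pct_attaining_suppression={}, pct_reaching_line={},
    )
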