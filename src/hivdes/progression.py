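"""State-update rules applied when events fire.

Covers marker trajectories (logarithmic CD4/log10VL paths per line),
instantaneous suppression and uniform rebound of viral load, the adherence
GLM, the four-class resistance ladder, permanent AIDS classification, the
line-switch rules, and regimen-characteristic redraws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .cohort import PatientState, resistance_class_of
from .params import ModelParameters, TrajectorySpec

NONSUPPRESSIVE = "nonsuppressive"


@dataclass(frozen=True)
class ProgressionAction:
    action: str  # stay | regimen_switch | line_switch | enter_nonsuppressive
    cause: str | None = None  # toxicity | other | failure_no_suppression | failure_after_suppression


def cd4_change(line, dt: float, traj: TrajectorySpec) -> float:
    """Accumulated CD4 change (cells/uL) after ``dt`` months in a line.

    Therapy lines follow a * ln(1 + b * dt); non-suppressive therapy declines
    linearly at the configured yearly rate.
    """
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if line == NONSUPPRESSIVE:
        return -traj.nonsuppressive_cd4_decline * dt / 12.0
    return traj.cd4_a[line] * math.log1p(traj.cd4_b[line] * dt)


def vl_change(line, dt: float, traj: TrajectorySpec) -> float:
    """Accumulated unsuppressed log10VL drift after ``dt`` months in a line."""
    if dt < 0:
        raise ValueError("dt must be >= 0")
    if line == NONSUPPRESSIVE:
        return 0.0
    return traj.vl_a[line] * math.log1p(traj.vl_b[line] * dt)


def apply_suppression(state: PatientState, vl_floor: float = 1.69) -> PatientState:
    """Viral suppression: log10VL drops instantaneously to the detectability
    floor and stays there until a rebound."""
    if state.nonsuppressive:
        raise ValueError("suppression cannot occur on non-suppressive therapy")
    state.suppressed = True
    state.log10vl = vl_floor
    return state


def apply_rebound(state: PatientState, rng, bounds) -> PatientState:
    """Virological rebound: log10VL jumps to a uniform draw within bounds."""
    if not state.suppressed:
        raise ValueError("rebound requires prior viral suppression")
    lo, hi = bounds
    state.suppressed = False
    state.log10vl = lo + (hi - lo) * rng.random()
    return state


def adherence_logit_coefficient(pp_effect: float, reference_mean: float = 0.88) -> float:
    """Convert a percentage-point marginal effect to a logit-scale slope
    at the reference adherence: beta = (dp/100) / (p * (1 - p))."""
    return (pp_effect / 100.0) / (reference_mean * (1.0 - reference_mean))


def update_adherence(
    state: PatientState,
    params: ModelParameters,
    deviations: dict[str, float],
    baseline_deviations: dict[str, float],
) -> float:
    """Adherence from a binomial-family logit GLM.

    Each patient is anchored at their own sampled baseline adherence; the
    linear predictor moves with covariate changes since ART initiation,
    using the percentage-point effects converted to logit slopes at the
    reference mean adherence.
    """
    p0 = min(max(state.baseline_adherence, 1e-9), 1.0 - 1e-9)
    eta = math.log(p0 / (1.0 - p0))
    pbar = params.adherence_reference_mean
    for name, pp in params.adherence_effects.items():
        delta = deviations.get(name, 0.0) - baseline_deviations.get(name, 0.0)
        if delta:
            eta += adherence_logit_coefficient(pp, pbar) * delta
    eta = min(max(eta, -500.0), 500.0)
    p = 1.0 / (1.0 + math.exp(-eta))
    p = min(max(p, 1e-12), 1.0 - 1e-12)  # strictly inside (0, 1)
    state.adherence = p
    return p


def advance_resistance(state: PatientState, rng, params: ModelParameters) -> PatientState:
    """Move one resistance class up (capped at 4) with a uniform level within
    the new class; within class 4 the level is max(current, triangular draw)."""
    b = params.resistance_bounds
    if state.resistance_class >= 4:
        lo, mode, hi = params.class4_triangular
        draw = rng.triangular(lo, mode, hi)
        state.resistance_level = max(state.resistance_level, draw)
    else:
        new_class = state.resistance_class + 1
        class_edges = {2: (b[0], b[1]), 3: (b[1], b[2]), 4: (b[2], b[3])}
        lo, hi = class_edges[new_class]
        state.resistance_level = lo + (hi - lo) * rng.random()
        state.resistance_class = new_class
    state.resistance_class = resistance_class_of(state.resistance_level, b)
    return state


def classify_aids(state: PatientState, aids_event_fired: bool = False) -> PatientState:
    """Permanent AIDS classification: first AIDS-defining event or CD4 < 200."""
    if state.aids or aids_event_fired or state.cd4 < 200.0:
        state.aids = True
    return state


def evaluate_line_rules(
    state: PatientState, event: str, params: ModelParameters
) -> ProgressionAction:
    """Line-switch logic at a virological-failure event.

    ``event`` is ``"deadline"`` (suppression not reached within the deadline)
    or ``"virological_failure"`` (confirmed failure after suppression).
    Lines 1-2 switch to the next line; line 3 stays (reshuffling the regimen)
    unless resistance has reached the highest class, which starts
    non-suppressive therapy.
    """
    if state.nonsuppressive:
        raise ValueError("no line rules on non-suppressive therapy")
    if event not in ("deadline", "virological_failure"):
        raise ValueError(f"unrecognised failure event {event!r}")
    cause = (
        "failure_no_suppression" if event == "deadline"
        else "failure_after_suppression"
    )
    if state.line < params.max_suppressive_lines:
        return ProgressionAction("line_switch", cause)
    if state.resistance_class >= 4:
        return ProgressionAction("enter_nonsuppressive", cause)
    return ProgressionAction("stay", cause)


def draw_regimen_characteristics(line, params: ModelParameters, rng):
    """Draw (n_PIs, doses/day, pills/day) from the line-specific tables."""
    try:
        tables = params.regimen_tables[line]
    except KeyError:
        raise KeyError(f"no regimen table for line {line!r}") from None
    out = []
    for var in ("n_pis", "doses_per_day", "pills_per_day"):
        table = tables[var]
        u = rng.random()
        acc = 0.0
        for key, p in table.items():
            acc += p
            if u < acc:
                break
        out.append(int(key))
    return tuple(out)


def assign_switch_cause(rng, p_toxicity: float) -> str:
    """Cause of a regimen switch without virological failure."""
    if not 0.0 <= p_toxicity <= 1.0:
        raise ValueError("p_toxicity must be in [0, 1]")
    return "toxicity" if rng.random() < p_toxicity else "other"
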