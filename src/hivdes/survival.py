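"""Weibull survival evaluation, conditional event-time sampling, and
Kaplan-Meier utilities.

Candidate times for all admissible events are drawn independently at each
decision point from their *conditional* distributions given the time already
survived, and the earliest candidate fires (next-event scheduling with the
minimum rule; exact ties resolved by a fixed clinical priority).
"""

from __future__ import annotations

import math

import numpy as np

from .params import SurvivalSpec, calibrate_weibull_scale, shifted_median

# Tie-break priority: death preempts everything; earlier entries win.
EVENT_PRIORITY = (
    "nonhiv_death",
    "hiv_death",
    "aids_event",
    "line_switch",
    "first_resistance",
    "resistance_class_switch",
    "regimen_switch",
    "hospitalization",
    "viral_suppression",
    "virological_failure",
    "deadline",
)
_PRIORITY_RANK = {name: i for i, name in enumerate(EVENT_PRIORITY)}


def weibull_survival(t, shape_p, scale):
    """S(t) = exp(-(t/scale)^shape_p)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if not shape_p > 0 or not scale > 0:
        raise ValueError("shape_p and scale must be > 0")
    return np.exp(-((t / scale) ** shape_p))[()]


def conditional_weibull_time(shape_p, scale, elapsed, u):
    """Solve S(t)/S(elapsed) = u for t (> elapsed).

    t = scale * ((elapsed/scale)^p - ln u)^(1/p); vectorised over ``u``.
    """
    if elapsed < 0:
        raise ValueError("elapsed must be >= 0")
    if isinstance(u, (float, int)):  # scalar fast path (simulation hot loop)
        if not 0.0 < u < 1.0:
            raise ValueError("u must lie strictly inside (0, 1)")
        return scale * ((elapsed / scale) ** shape_p - math.log(u)) ** (1.0 / shape_p)
    u = np.asarray(u, dtype=float)
    if np.any((u <= 0.0) | (u >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    return (scale * ((elapsed / scale) ** shape_p - np.log(u)) ** (1.0 / shape_p))[()]


def sample_conditional_time(
    spec: SurvivalSpec,
    covariates: dict[str, float],
    elapsed: float,
    u,
    floor: float = 3.0,
    rel_floor: float = 0.25,
):
    """Event time (months from the clock origin) given ``elapsed`` months
    already survived, using the covariate-shifted median to set the scale."""
    median = shifted_median(spec, covariates, floor=floor, rel_floor=rel_floor)
    scale = calibrate_weibull_scale(spec.shape_p, median)
    return conditional_weibull_time(spec.shape_p, scale, elapsed, u)


def next_event(candidates):
    """Minimum-time candidate from (event_name, time) pairs.

    Exact ties are broken by :data:`EVENT_PRIORITY` so that death always
    preempts concurrent clinical events.
    """
    if not candidates:
        raise ValueError("next_event requires a non-empty candidate list")
    return min(candidates, key=lambda c: (c[1], _PRIORITY_RANK.get(c[0], len(_PRIORITY_RANK))))


def km_median(times, event_flags):
    """Kaplan-Meier median: first time the product-limit curve falls to <= 0.5.

    Returns ``None`` when the curve never reaches 0.5.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    flags = np.asarray(event_flags, dtype=bool)
    if times.shape != flags.shape:
        raise ValueError("times and event_flags must have equal length")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=flags)
    med = kmf.median_survival_time_
    return None if np.isinf(med) else float(med)
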