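"""Synthetic baseline cohort generation.

The source tables print only marginal summaries (Bernoulli fractions,
categorical tables, median [IQR] for continuous markers), so continuous
characteristics are sampled from a piecewise-linear quantile function fitted
to the three quartile anchors, and all fields are drawn independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import BaselineProfile, ModelParameters

# Map third agent at initiation -> (n_PIs, doses/day, pills/day)
THIRD_AGENT_REGIMEN = {
    "EFV": (0, 1, 3),
    "NVP": (0, 2, 4),
    "LPVr": (1, 2, 6),
    "OtherPI": (1, 2, 5),
}


class QuantileDistribution:
    """Continuous distribution defined by its quartiles.

    The quantile function interpolates linearly through
    (0.25, q1), (0.5, median), (0.75, q3); each tail extrapolates the
    adjacent segment's slope scaled by ``tail_stretch``, truncated at the
    support bounds.  Degenerate anchors give a point mass.
    """

    def __init__(self, median, q1, q3, support=(-math.inf, math.inf), tail_stretch=1.0):
        if not (q1 <= median <= q3):
            raise ValueError(f"anchors not ordered: q1={q1}, median={median}, q3={q3}")
        lo, hi = support
        if not (lo <= q1 and q3 <= hi):
            raise ValueError("anchors outside support bounds")
        self.q1, self.median, self.q3 = float(q1), float(median), float(q3)
        self.lo, self.hi = float(lo), float(hi)
        self.tail_stretch = float(tail_stretch)

    def ppf(self, u):
        """Quantile function; accepts scalars or arrays."""
        u = np.asarray(u, dtype=float)
        s_lo = (self.median - self.q1) / 0.25 * self.tail_stretch
        s_hi = (self.q3 - self.median) / 0.25 * self.tail_stretch
        x = np.where(
            u < 0.25,
            self.q1 - s_lo * (0.25 - u),
            np.where(
                u < 0.5,
                self.q1 + (self.median - self.q1) * (u - 0.25) / 0.25,
                np.where(
                    u < 0.75,
                    self.median + (self.q3 - self.median) * (u - 0.5) / 0.25,
                    self.q3 + s_hi * (u - 0.75),
                ),
            ),
        )
        return np.clip(x, self.lo, self.hi)[()]

    def sample(self, rng, size=None):
        return self.ppf(rng.random(size))

    def mean_inverse(self, n_grid: int = 200_001) -> float:
        """E[1/X] by midpoint quadrature over the quantile function."""
        u = (np.arange(n_grid) + 0.5) / n_grid
        return float(np.mean(1.0 / self.ppf(u)))


def fit_quantile_distribution(median, q1, q3, support=(-math.inf, math.inf),
                              tail_stretch=1.0) -> QuantileDistribution:
    """Distribution whose quartiles match the three printed anchors."""
    return QuantileDistribution(median, q1, q3, support, tail_stretch)


@dataclass
class PatientState:
    """Evolving description of one simulated individual."""

    female: int
    age: float  # years, at ART initiation (kept fixed; time tracks ageing)
    employed: int
    hcv: int
    transmission: str
    aids: bool
    cd4: float
    log10vl: float
    adherence: float  # fraction in (0, 1)
    resistance_level: float  # inverted GSS, 0-25
    resistance_class: int  # 1..4
    line: int  # 1, 2, 3; non-suppressive flagged separately
    nonsuppressive: bool
    regimen_number: int
    n_pis: int
    doses_per_day: int
    pills_per_day: int
    year_art: int
    nrti_pair: str
    suppressed: bool
    n_failures_after_suppression: int
    n_failures_no_suppression: int
    nonhiv_death_age: float  # years
    baseline_log10vl: float = 0.0
    baseline_adherence: float = 0.0
    baseline_cd4: float = 0.0

    def check_invariants(self) -> None:
        assert 0.0 <= self.adherence <= 1.0, self.adherence
        assert self.cd4 >= 0.0, self.cd4
        assert 0.0 <= self.resistance_level <= 25.0, self.resistance_level
        assert self.resistance_class == resistance_class_of(
            self.resistance_level
        ), (self.resistance_level, self.resistance_class)
        assert self.line in (1, 2, 3)


def resistance_class_of(level: float, bounds=(1.0, 5.0, 10.0, 25.0)) -> int:
    """Class 1..4 for an inverted-GSS level (R<1, 1<=R<5, 5<=R<10, 10<R<=25)."""
    b1, b2, b3, _ = bounds
    if level < b1:
        return 1
    if level < b2:
        return 2
    if level <= b3:
        return 3
    return 4


def _draw_table(table: dict[str, float], rng) -> str:
    u = rng.random()
    acc = 0.0
    for key, p in table.items():
        acc += p
        if u < acc:
            return key
    return key  # numerical slack: last category


def sample_baseline(params: ModelParameters, rng) -> PatientState:
    """Draw one patient at ART initiation from the arm's marginal profile."""
    prof = params.baseline
    female = int(rng.random() < prof.p_female)
    age = float(
        fit_quantile_distribution(
            prof.age_anchors[1], prof.age_anchors[0], prof.age_anchors[2],
            support=prof.age_bounds,
        ).ppf(rng.random())
    )
    employed = int(rng.random() < prof.p_employed)
    log10vl = float(
        fit_quantile_distribution(
            prof.log10vl_anchors[1], prof.log10vl_anchors[0], prof.log10vl_anchors[2],
            support=prof.log10vl_bounds,
        ).ppf(rng.random())
    )
    cd4 = float(
        fit_quantile_distribution(
            prof.cd4_anchors[1], prof.cd4_anchors[0], prof.cd4_anchors[2],
            support=prof.cd4_bounds,
        ).ppf(rng.random())
    )
    hcv = int(rng.random() < prof.p_hcv)
    adherence = float(
        fit_quantile_distribution(
            prof.adherence_anchors[1], prof.adherence_anchors[0],
            prof.adherence_anchors[2], support=prof.adherence_bounds,
        ).ppf(rng.random())
    )
    adherence = min(max(adherence, 1e-6), 1.0 - 1e-6)
    nrti_pair = _draw_table(prof.nrti_pair_table, rng)
    third = _draw_table(prof.third_agent_table, rng)
    n_pis, doses, pills = THIRD_AGENT_REGIMEN[third]
    if rng.random() < prof.p_resistance_gt1:
        level = 1.0 + 4.0 * rng.random()  # uniform on [1, 5)
    else:
        level = rng.random()  # uniform on [0, 1)
    transmission = _draw_table(prof.transmission_table, rng)
    aids = rng.random() < prof.p_aids
    cd4 = max(cd4, 0.0)
    state = PatientState(
        female=female,
        age=age,
        employed=employed,
        hcv=hcv,
        transmission=transmission,
        aids=bool(aids or cd4 < 200.0),
        cd4=cd4,
        log10vl=log10vl,
        adherence=adherence,
        resistance_level=level,
        resistance_class=resistance_class_of(level, params.resistance_bounds),
        line=1,
        nonsuppressive=False,
        regimen_number=1,
        n_pis=n_pis,
        doses_per_day=doses,
        pills_per_day=pills,
        year_art=prof.year_art,
        nrti_pair=nrti_pair,
        suppressed=False,
        n_failures_after_suppression=0,
        n_failures_no_suppression=0,
        nonhiv_death_age=math.nan,
        baseline_log10vl=log10vl,
        baseline_adherence=adherence,
        baseline_cd4=cd4,
    )
    state.nonhiv_death_age = sample_nonhiv_death_age(
        age, "F" if female else "M", params.life_table, rng,
        cap_age=params.max_age,
    )
    return state


def sample_nonhiv_death_age(current_age, sex, life_table, rng, cap_age=105.0):
    """Age at death from non-HIV causes, by sequential annual mortality draws.

    ``life_table`` rows are (age, q_male, q_female) with q the annual death
    probability.  Death in the year starting at integer age a is recorded at
    a + 1; reaching the end of the table returns ``cap_age``.
    """
    ages = [row[0] for row in life_table]
    if current_age < ages[0] or current_age > ages[-1]:
        raise ValueError(
            f"current_age {current_age} outside life table range "
            f"[{ages[0]}, {ages[-1]}]"
        )
    col = 2 if sex == "F" else 1
    start = int(math.floor(current_age))
    for row in life_table:
        a = row[0]
        if a < start:
            continue
        if rng.random() < row[col]:
            return min(float(a) + 1.0, cap_age)
    return float(cap_age)


def make_gompertz_makeham_life_table(
    a: float = 2.0e-4, b: float = 2.7e-5, c: float = 1.113,
    max_age: int = 105, sex_ratio: float = 1.6,
) -> list[tuple[float, float, float]]:
    """SYNTHETIC stand-in life table (annual death probabilities by age/sex).

    Gompertz-Makeham hazard q(x) ~ a + b*c^x; male mortality is
    ``sex_ratio`` times female.  This is a documented synthetic default for
    the national life table the study used, which is not reproduced here.
    """
    rows = []
    for x in range(0, max_age + 1):
        qf = min(a + b * c**x, 1.0)
        qm = min(sex_ratio * qf, 1.0)
        rows.append((float(x), qm, qf))
    return rows
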