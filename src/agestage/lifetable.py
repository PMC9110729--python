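"""Age-stage schedules and demographic parameters of the two-sex life table.

The age-stage, two-sex life table tracks every developmental stage of both
sexes by age, so that variable development rates and pre-adult mortality enter
the population parameters.  The central object is the age-stage survival
matrix ``s_xj`` — the probability that a fresh egg is alive and in stage *j*
at age *x* — with its companions

* ``l_x   = sum_j s_xj``                    (age-specific survival),
* ``f_xj``: mean eggs laid at age *x* per individual in stage *j*
  (non-zero only for adult females),
* ``m_x  = sum_j s_xj f_xj / sum_j s_xj``   (age-specific fecundity).

From these, the scalar parameters:

* net reproductive rate      ``R0 = sum_x l_x m_x``,
* intrinsic rate of increase ``r`` solving the Euler–Lotka equation
  ``sum_x exp(-r (x+1)) l_x m_x = 1``  (age indexed from 0, hence the x+1),
* finite rate of increase    ``lambda = exp(r)``,
* mean generation time       ``T = ln(R0) / r``,

and the age-stage matrices of life expectancy ``e_xj`` and reproductive value
``v_xj``, both computed from the empirical per-individual trajectories.

The ``x+1`` exponent convention matters: an off-by-one in the discount age
moves ``r`` in the third decimal for schedules on this time scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .cohort import CohortDataset

__all__ = [
    "AgeStageSchedule",
    "DemographicParameters",
    "UndefinedRateError",
    "build_schedule",
    "net_reproductive_rate",
    "intrinsic_rate",
    "finite_rate",
    "mean_generation_time",
    "life_expectancy",
    "reproductive_value",
    "demographic_parameters",
    "curves_frame",
    "solve_euler_lotka",
]

ADULT_FEMALE = "adult_female"
ADULT_MALE = "adult_male"


class UndefinedRateError(ValueError):
    """Raised when r (and hence lambda, T, v_xj) is undefined (R0 = 0)."""


@dataclass
class AgeStageSchedule:
    """Empirical age-stage schedule of one cohort.

    The ``adult`` ontology stage is split into ``adult_female`` and
    ``adult_male`` columns, as the two-sex method plots it.  Every entry of
    ``s`` is a multiple of 1/N.  Private per-individual arrays (occupancy,
    daily eggs, death ages) are retained because the e_xj and v_xj
    recursions condition on empirical trajectories.
    """

    stages: tuple[str, ...]
    s: np.ndarray            # (X, J) occupancy probabilities
    f: np.ndarray            # (X, J) eggs per individual in (x, j)
    l_x: np.ndarray          # (X,)
    m_x: np.ndarray          # (X,)
    N: int
    _occupancy: np.ndarray   # (N, X) stage index, -1 = dead
    _eggs: np.ndarray        # (N, X) eggs laid
    _death_age: np.ndarray   # (N,)

    @property
    def ages(self) -> np.ndarray:
        return np.arange(self.s.shape[0])

    @property
    def n_ages(self) -> int:
        return self.s.shape[0]

    def stage_index(self, stage: str) -> int:
        return self.stages.index(stage)


def build_schedule(cohort: CohortDataset) -> AgeStageSchedule:
    """Census the cohort day by day into the age-stage matrices.

    ``s[x, j]`` = (# individuals alive in stage j on day x) / N;
    ``f[x, adult_female]`` = (eggs laid on day x) / (# adult females alive
    on day x), 0 when none is alive.
    """
    records = cohort.active
    if not records:
        raise ValueError("cohort has no non-excluded individuals")
    cohort.validate()
    n = len(records)
    immature = [s for s in cohort.stage_ontology if s != "adult"]
    stages = tuple(immature) + (ADULT_FEMALE, ADULT_MALE)
    x_max = max(r.death_age for r in records) + 1  # one trailing all-dead age

    occupancy = np.full((n, x_max), -1, dtype=np.int16)
    eggs = np.zeros((n, x_max))
    death_age = np.zeros(n, dtype=np.int64)
    for i, rec in enumerate(records):
        death_age[i] = rec.death_age
        cum = 0
        for stage, dur in rec.stage_durations.items():
            if stage == "adult":
                j = stages.index(ADULT_FEMALE if rec.sex == "female" else ADULT_MALE)
            else:
                j = stages.index(stage)
            occupancy[i, cum:cum + dur] = j
            cum += dur
        for age, count in rec.daily_fecundity.items():
            eggs[i, age] += count

    j_count = len(stages)
    s = np.zeros((x_max, j_count))
    for j in range(j_count):
        s[:, j] = (occupancy == j).sum(axis=0) / n
    l_x = s.sum(axis=1)

    f = np.zeros((x_max, j_count))
    jf = stages.index(ADULT_FEMALE)
    females_alive = (occupancy == jf).sum(axis=0)
    total_eggs = eggs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f[:, jf] = np.where(females_alive > 0, total_eggs / np.maximum(females_alive, 1), 0.0)

    alive = (occupancy >= 0).sum(axis=0)
    m_x = np.where(alive > 0, total_eggs / np.maximum(alive, 1), 0.0)

    return AgeStageSchedule(
        stages=stages, s=s, f=f, l_x=l_x, m_x=m_x, N=n,
        _occupancy=occupancy, _eggs=eggs, _death_age=death_age,
    )


# ---------------------------------------------------------------------------
# scalar parameters
# ---------------------------------------------------------------------------

def net_reproductive_rate(sched: AgeStageSchedule) -> float:
    """R0 = sum_x l_x m_x — expected lifetime eggs per initial individual."""
    return float(np.sum(sched.l_x * sched.m_x))


def solve_euler_lotka(b: np.ndarray, tol: float = 1e-12, max_iter: int = 200) -> float:
    """Solve ``sum_x exp(-r (x+1)) b_x = 1`` for r given ``b_x = l_x m_x``.

    Log-space bracketed bisection on r in [-5, 5] followed by Newton
    polishing; monotone, deterministic, overflow-safe for any schedule
    length.  Raises UndefinedRateError when ``b`` has no mass.
    """
    b = np.asarray(b, dtype=float)
    mask = b > 0
    if not mask.any():
        raise UndefinedRateError("R0 = 0: intrinsic rate of increase is undefined")
    ages = np.nonzero(mask)[0] + 1.0  # discount exponent uses x+1
    logb = np.log(b[mask])

    def g(r: float) -> float:
        return float(logsumexp(logb - r * ages))

    lo, hi = -5.0, 5.0
    glo, ghi = g(lo), g(hi)
    if glo < 0 or ghi > 0:  # growth rate outside any biological range
        raise UndefinedRateError("Euler-Lotka root outside [-5, 5] per day")
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < 1e-9:
            break
    r = 0.5 * (lo + hi)
    # Newton polish: g'(r) = -sum(w * ages) with w the softmax weights
    for _ in range(50):
        log_terms = logb - r * ages
        gval = float(logsumexp(log_terms))
        w = np.exp(log_terms - gval)
        step = gval / float(np.sum(w * ages))  # -g/g'
        r += step
        if abs(step) < 1e-15:
            break
    residual = abs(math.exp(g(r)) - 1.0)
    if residual >= tol:
        raise RuntimeError(f"Euler-Lotka solver did not converge: residual {residual}")
    return r


def intrinsic_rate(sched: AgeStageSchedule, tol: float = 1e-12, max_iter: int = 200) -> float:
    """Intrinsic rate of increase r (per day) from the Euler–Lotka equation."""
    return solve_euler_lotka(sched.l_x * sched.m_x, tol=tol, max_iter=max_iter)


def finite_rate(r: float) -> float:
    """Finite rate of increase lambda = exp(r) (per day)."""
    return math.exp(r)


def mean_generation_time(r0: float, r: float) -> float:
    """Mean generation time T = ln(R0)/r, in days.

    Returns NaN for the degenerate stationary case R0 = 1 (r = 0), where T
    is undefined.
    """
    if r0 <= 0:
        raise UndefinedRateError("T is undefined when R0 <= 0")
    if r == 0.0:
        return math.nan
    return math.log(r0) / r


@dataclass
class DemographicParameters:
    """Scalar demographic parameters; NaN marks the undefined ones.

    On a cohort with no reproduction (R0 = 0) only R0 is defined — the prey
    diet that kills every larva still has a life table, just no growth rate.
    """

    R0: float
    r: float
    lam: float
    T: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


def demographic_parameters(sched: AgeStageSchedule) -> DemographicParameters:
    r0 = net_reproductive_rate(sched)
    if r0 <= 0:
        return DemographicParameters(R0=r0, r=math.nan, lam=math.nan, T=math.nan)
    r = intrinsic_rate(sched)
    return DemographicParameters(
        R0=r0, r=r, lam=finite_rate(r),
        T=mean_generation_time(r0, r),
    )


# ---------------------------------------------------------------------------
# age-stage matrices
# ---------------------------------------------------------------------------

def life_expectancy(sched: AgeStageSchedule) -> np.ndarray:
    """Expected remaining days of life of an individual in stage j at age x.

    Conditioned on the empirical trajectories: e_xj averages
    ``death_age - x`` over the individuals observed alive in (x, j).
    Unoccupied (x, j) cells are NaN.  At age 0 in the first stage this is
    the cohort mean lifespan, deaths included.
    """
    x_max, j_count = sched.s.shape
    e = np.full((x_max, j_count), np.nan)
    occ = sched._occupancy
    remaining = sched._death_age[:, None] - np.arange(x_max)[None, :]
    for j in range(j_count):
        members = occ == j
        counts = members.sum(axis=0)
        with np.errstate(invalid="ignore"):
            sums = np.where(members, remaining, 0).sum(axis=0)
        e[counts > 0, j] = sums[counts > 0] / counts[counts > 0]
    return e


def reproductive_value(sched: AgeStageSchedule, r: float) -> np.ndarray:
    """Age-stage reproductive value v_xj at intrinsic rate ``r``.

    v_xj discounts the expected future egg stream of an individual currently
    in (x, j) back to its present value under exponential growth at rate r:

        v_xj = exp(r (x+1)) * mean over individuals in (x,j) of
               sum_{i >= x} exp(-r (i+1)) * eggs_i

    The Euler–Lotka equation makes ``v`` at age 0 in the first stage exactly
    lambda.  Unoccupied cells are NaN.
    """
    if math.isnan(r):
        raise UndefinedRateError("v_xj is undefined when r is undefined")
    x_max, j_count = sched.s.shape
    weights = np.exp(-r * (np.arange(x_max) + 1.0))
    discounted = sched._eggs * weights[None, :]
    # tail sums G[i, x] = sum_{a >= x} discounted[i, a]
    tails = np.cumsum(discounted[:, ::-1], axis=1)[:, ::-1]
    v = np.full((x_max, j_count), np.nan)
    occ = sched._occupancy
    growth = np.exp(r * (np.arange(x_max) + 1.0))
    for j in range(j_count):
        members = occ == j
        counts = members.sum(axis=0)
        sums = np.where(members, tails, 0).sum(axis=0)
        idx = counts > 0
        v[idx, j] = growth[idx] * sums[idx] / counts[idx]
    return v


# ---------------------------------------------------------------------------
# tidy export (the data behind the survival / fecundity / expectancy figures)
# ---------------------------------------------------------------------------

def curves_frame(
    sched: AgeStageSchedule,
    e_xj: np.ndarray | None = None,
    v_xj: np.ndarray | None = None,
) -> pd.DataFrame:
    """Long-format (quantity, age, stage, value) table of all curves.

    Age-stage matrices contribute one row per occupied (x, j) cell; the age
    vectors l_x and m_x carry an empty stage field.
    """
    rows: list[tuple[str, int, str, float]] = []
    matrices: list[tuple[str, np.ndarray]] = [("s_xj", sched.s), ("f_xj", sched.f)]
    if e_xj is not None:
        matrices.append(("e_xj", e_xj))
    if v_xj is not None:
        matrices.append(("v_xj", v_xj))
    for name, mat in matrices:
        for j, stage in enumerate(sched.stages):
            col = mat[:, j]
            for x in range(sched.n_ages):
                val = col[x]
                if not np.isnan(val) and (name in ("e_xj", "v_xj") or val != 0.0):
                    rows.append((name, x, stage, float(val)))
    for name, vec in (("l_x", sched.l_x), ("m_x", sched.m_x)):
        for x in range(sched.n_ages):
            rows.append((name, x, "", float(vec[x])))
    return pd.DataFrame(rows, columns=["quantity", "age", "stage", "value"])
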