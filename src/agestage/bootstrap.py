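"""Bootstrap standard errors, percentile CIs, and paired treatment tests.

The resampling unit is the individual: each replicate draws N individuals
with replacement from the cohort and recomputes the statistic — including
the full life-table parameters (R0, r, lambda, T), whose Euler–Lotka solution
is re-run on every replicate schedule.  Percentile 95% intervals are used
throughout (no bias correction), and two treatments differ when the 95%
percentile interval of the bootstrapped difference excludes zero.

Replicates on which a statistic is undefined (e.g. an all-male resample has
no fecundity) are skipped and counted, never silently dropped; a warning is
emitted when more than 1% of replicates degenerate.

The study-scale default is B = 100,000 resamples; tests and desk-scale runs
use far fewer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .cohort import CohortDataset
from .lifetable import UndefinedRateError, solve_euler_lotka

__all__ = [
    "STATISTICS",
    "CohortArrays",
    "BootstrapResult",
    "PairedTestResult",
    "bootstrap",
    "paired_bootstrap_test",
    "compare_treatments",
    "letter_display",
]

DEFAULT_B = 100_000

_FEMALE, _MALE = 1, 2


class CohortArrays:
    """Per-individual arrays for fast resampling of a fixed cohort."""

    def __init__(self, cohort: CohortDataset):
        records = cohort.active
        if not records:
            raise ValueError("cohort has no non-excluded individuals")
        self.treatment = cohort.treatment
        n = len(records)
        self.n = n
        self.death_age = np.zeros(n, dtype=np.int64)
        self.sex = np.zeros(n, dtype=np.int8)
        self.is_adult = np.zeros(n, dtype=bool)
        self.emergence = np.full(n, -1, dtype=np.int64)
        self.first_egg = np.full(n, -1, dtype=np.int64)
        self.total_eggs = np.zeros(n)
        self.ovi_days = np.zeros(n, dtype=np.int64)
        x_max = max(r.death_age for r in records)
        self.eggs = np.zeros((n, x_max))
        for i, rec in enumerate(records):
            self.death_age[i] = rec.death_age
            self.sex[i] = {"female": _FEMALE, "male": _MALE}.get(rec.sex, 0)
            self.is_adult[i] = rec.is_adult
            if rec.is_adult:
                self.emergence[i] = rec.emergence_age
            laying = [a for a, e in rec.daily_fecundity.items() if e > 0]
            if laying:
                self.first_egg[i] = min(laying)
            self.ovi_days[i] = len(laying)
            for age, count in rec.daily_fecundity.items():
                self.eggs[i, age] += count
        self.total_eggs = self.eggs.sum(axis=1)
        self.all_idx = np.arange(n)


# -- named statistics -------------------------------------------------------
# Each statistic maps (arrays, index vector) -> float, NaN when undefined on
# that resample.

def _females(a: CohortArrays, idx: np.ndarray) -> np.ndarray:
    return idx[(a.sex[idx] == _FEMALE) & a.is_adult[idx]]


def _stat_fecundity(a, idx):
    f = _females(a, idx)
    return float(a.total_eggs[f].mean()) if f.size else math.nan


def _stat_apop(a, idx):
    f = idx[a.first_egg[idx] >= 0]
    return float((a.first_egg[f] - a.emergence[f]).mean()) if f.size else math.nan


def _stat_tpop(a, idx):
    f = idx[a.first_egg[idx] >= 0]
    return float(a.first_egg[f].mean()) if f.size else math.nan


def _stat_ovi_days(a, idx):
    f = _females(a, idx)
    return float(a.ovi_days[f].mean()) if f.size else math.nan


def _stat_sex_ratio(a, idx):
    adults = idx[a.is_adult[idx]]
    if not adults.size:
        return math.nan
    return float((a.sex[adults] == _FEMALE).mean())


def _stat_preadult_survival(a, idx):
    return float(a.is_adult[idx].mean())


def _stat_immature(sex_code):
    def stat(a, idx):
        g = idx[(a.sex[idx] == sex_code) & a.is_adult[idx]]
        return float(a.emergence[g].mean()) if g.size else math.nan
    return stat


def _stat_adult_longevity(sex_code):
    def stat(a, idx):
        g = idx[(a.sex[idx] == sex_code) & a.is_adult[idx]]
        return float((a.death_age[g] - a.emergence[g]).mean()) if g.size else math.nan
    return stat


def _stat_total_longevity(a, idx):
    return float(a.death_age[idx].mean())


def _stat_r0(a, idx):
    return float(a.total_eggs[idx].sum() / idx.size)


def _stat_r(a, idx):
    b = a.eggs[idx].sum(axis=0) / idx.size
    try:
        return solve_euler_lotka(b)
    except UndefinedRateError:
        return math.nan


def _stat_lambda(a, idx):
    r = _stat_r(a, idx)
    return math.exp(r) if not math.isnan(r) else math.nan


def _stat_t(a, idx):
    r = _stat_r(a, idx)
    if math.isnan(r) or r == 0.0:
        return math.nan
    return math.log(_stat_r0(a, idx)) / r


STATISTICS = {
    "fecundity": _stat_fecundity,
    "apop": _stat_apop,
    "tpop": _stat_tpop,
    "oviposition_days": _stat_ovi_days,
    "sex_ratio": _stat_sex_ratio,
    "preadult_survival": _stat_preadult_survival,
    "female_immature": _stat_immature(_FEMALE),
    "male_immature": _stat_immature(_MALE),
    "female_adult_longevity": _stat_adult_longevity(_FEMALE),
    "male_adult_longevity": _stat_adult_longevity(_MALE),
    "total_longevity": _stat_total_longevity,
    "R0": _stat_r0,
    "r": _stat_r,
    "lambda": _stat_lambda,
    "T": _stat_t,
}


@dataclass
class BootstrapResult:
    statistic: str
    treatment: str
    B: int
    seed: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    degenerate_count: int
    replicates: np.ndarray  # valid replicate values


@dataclass
class PairedTestResult:
    statistic: str
    treatment_a: str
    treatment_b: str
    B: int
    seed: int
    estimate_a: float
    estimate_b: float
    difference: float          # estimate_a - estimate_b on the full cohorts
    ci_low: float
    ci_high: float
    significant: bool
    degenerate_count: int


def _as_arrays(cohort: CohortDataset | CohortArrays) -> CohortArrays:
    return cohort if isinstance(cohort, CohortArrays) else CohortArrays(cohort)


def _resolve_stat(statistic):
    if callable(statistic):
        return getattr(statistic, "__name__", "custom"), statistic
    try:
        return statistic, STATISTICS[statistic]
    except KeyError:
        raise KeyError(
            f"unknown statistic {statistic!r}; available: {sorted(STATISTICS)}"
        ) from None


def _replicates(arrays, fn, B, rng):
    vals = np.empty(B)
    n = arrays.n
    for b in range(B):
        idx = rng.integers(0, n, n)
        vals[b] = fn(arrays, idx)
    return vals


def bootstrap(
    cohort: CohortDataset | CohortArrays,
    statistic,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> BootstrapResult:
    """Bootstrap SE and percentile 95% CI of a named statistic.

    ``statistic`` is a key of :data:`STATISTICS` or a callable
    ``(CohortArrays, idx) -> float``.  Deterministic given (cohort, B, seed).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    arrays = _as_arrays(cohort)
    name, fn = _resolve_stat(statistic)
    point = fn(arrays, arrays.all_idx)
    if math.isnan(point):
        raise ValueError(f"statistic {name!r} is undefined on the full cohort")
    rng = np.random.default_rng(seed)
    vals = _replicates(arrays, fn, B, rng)
    valid = vals[~np.isnan(vals)]
    degenerate = B - valid.size
    if degenerate > 0.01 * B:
        warnings.warn(
            f"{degenerate}/{B} bootstrap replicates were degenerate for {name!r}",
            stacklevel=2,
        )
    se = float(np.std(valid, ddof=1)) if valid.size > 1 else 0.0
    lo, hi = (np.percentile(valid, [2.5, 97.5]) if valid.size else (math.nan, math.nan))
    return BootstrapResult(
        statistic=name, treatment=arrays.treatment, B=B, seed=seed,
        estimate=point, se=se, ci_low=float(lo), ci_high=float(hi),
        degenerate_count=int(degenerate), replicates=valid,
    )


def paired_bootstrap_test(
    cohort_a: CohortDataset | CohortArrays,
    cohort_b: CohortDataset | CohortArrays,
    statistic,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> PairedTestResult:
    """Paired bootstrap test of one statistic between two treatments.

    Each arm is resampled independently (independent seed substreams); the
    treatments differ when the 95% percentile interval of the replicate
    differences excludes zero.  Symmetric in its arguments up to sign.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    a, b = _as_arrays(cohort_a), _as_arrays(cohort_b)
    name, fn = _resolve_stat(statistic)
    est_a, est_b = fn(a, a.all_idx), fn(b, b.all_idx)
    if math.isnan(est_a) or math.isnan(est_b):
        raise ValueError(f"statistic {name!r} is undefined on a full cohort")
    ss_a, ss_b = np.random.SeedSequence(seed).spawn(2)
    vals_a = _replicates(a, fn, B, np.random.default_rng(ss_a))
    vals_b = _replicates(b, fn, B, np.random.default_rng(ss_b))
    diffs = vals_a - vals_b
    valid = diffs[~np.isnan(diffs)]
    degenerate = B - valid.size
    if degenerate > 0.01 * B:
        warnings.warn(
            f"{degenerate}/{B} paired replicates were degenerate for {name!r}",
            stacklevel=2,
        )
    lo, hi = np.percentile(valid, [2.5, 97.5]) if valid.size else (math.nan, math.nan)
    significant = bool(valid.size) and not (lo <= 0.0 <= hi)
    return PairedTestResult(
        statistic=name, treatment_a=a.treatment, treatment_b=b.treatment,
        B=B, seed=seed, estimate_a=est_a, estimate_b=est_b,
        difference=est_a - est_b, ci_low=float(lo), ci_high=float(hi),
        significant=significant, degenerate_count=int(degenerate),
    )


def letter_display(names: list[str], significant: dict[frozenset, bool]) -> dict[str, str]:
    """Compact letter display from a pairwise significance matrix.

    Treatments sharing a letter do not differ.  Letters are the maximal
    cliques of the "not significantly different" graph, lettered in order of
    their earliest member, so a single clique collapses to everyone sharing
    'a' and any differing pair gets disjoint letters.
    """
    k = len(names)
    adj = [
        {
            j for j in range(k)
            if j != i and not significant.get(frozenset((names[i], names[j])), False)
        }
        for i in range(k)
    ]
    cliques: list[frozenset] = []
    # brute-force maximal cliques; k (number of treatments) is tiny
    from itertools import combinations

    for size in range(k, 0, -1):
        for combo in combinations(range(k), size):
            cset = set(combo)
            if all(cset - {i} <= adj[i] for i in combo):
                if not any(cset <= c for c in cliques):
                    cliques.append(frozenset(cset))
    cliques.sort(key=lambda c: (min(c), sorted(c)))
    letters: dict[str, list[str]] = {name: [] for name in names}
    for pos, clique in enumerate(cliques):
        letter = chr(ord("a") + pos)
        for i in clique:
            letters[names[i]].append(letter)
    return {name: "".join(sorted(ls)) for name, ls in letters.items()}


def compare_treatments(
    cohorts: list[CohortDataset | CohortArrays],
    statistic,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> tuple[list[PairedTestResult], dict[str, str]]:
    """All pairwise paired bootstrap tests plus the compact letter display.

    Each pair gets an independent seed substream derived from ``seed``.
    """
    arrays = [_as_arrays(c) for c in cohorts]
    if len(arrays) < 2:
        raise ValueError("need at least two cohorts to compare")
    names = [a.treatment for a in arrays]
    if len(set(names)) != len(names):
        names = [f"{name}#{i}" for i, name in enumerate(names)]
    pairs = [(i, j) for i in range(len(arrays)) for j in range(i + 1, len(arrays))]
    children = np.random.SeedSequence(seed).spawn(len(pairs))
    results = []
    sig: dict[frozenset, bool] = {}
    for (i, j), child in zip(pairs, children):
        pair_seed = int(child.generate_state(1)[0] % (2**31))
        res = paired_bootstrap_test(arrays[i], arrays[j], statistic, B=B, seed=pair_seed)
        results.append(res)
        sig[frozenset((names[i], names[j]))] = res.significant
    return results, letter_display(names, sig)
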