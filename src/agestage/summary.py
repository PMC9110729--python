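"""Cohort-level developmental and reproductive statistics.

Descriptive means and plain standard errors (SD/sqrt(n)) of the quantities a
two-sex life-table study reports per treatment: stage durations, immature
development time by sex, preadult survival, sex ratio, the pre-oviposition
periods (APOP: adult emergence to first egg; TPOP: oviposition to first egg),
oviposition days, per-female fecundity, and longevity.  Bootstrap standard
errors live in :mod:`agestage.bootstrap`.

Longevity is reported under both conventions — adult lifespan (emergence to
death) and total lifespan (egg to death) — because published tables do not
always state which is meant; the two differ by the immature duration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .cohort import CohortDataset, IndividualRecord

__all__ = ["MeanSE", "LifeTableSummary", "summarize", "stage_duration_table"]


@dataclass(frozen=True)
class MeanSE:
    """A sample mean with its descriptive standard error and sample size."""

    mean: float
    se: float
    n: int

    @classmethod
    def of(cls, values: list[float] | np.ndarray) -> "MeanSE":
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            return cls(math.nan, math.nan, 0)
        se = float(np.std(arr, ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else math.nan
        return cls(float(arr.mean()), se, int(arr.size))


@dataclass
class LifeTableSummary:
    """Scalar cohort statistics; undefined entries carry NaN means, n = 0."""

    treatment: str
    n: int                       # non-excluded cohort size
    n_adults: int
    n_females: int
    n_males: int
    preadult_survival: float     # adults / N
    sex_ratio: float             # females / (females + males), NaN if no adults
    immature_female: MeanSE      # egg-to-emergence days, eventual females
    immature_male: MeanSE
    apop: MeanSE                 # emergence to first egg, laying females
    tpop: MeanSE                 # oviposition to first egg, laying females
    oviposition_days: MeanSE     # census days with >= 1 egg, all adult females
    fecundity: MeanSE            # lifetime eggs per adult female
    adult_longevity_female: MeanSE   # emergence to death
    adult_longevity_male: MeanSE
    total_longevity_female: MeanSE   # egg to death
    total_longevity_male: MeanSE
    total_longevity: MeanSE      # egg to death, all N individuals

    DEFINITIONS = {
        "preadult_survival": "fraction of the initial cohort reaching adulthood",
        "sex_ratio": "females / (females + males) among emerged adults",
        "immature_female": "egg-to-emergence duration (days), eventual females",
        "immature_male": "egg-to-emergence duration (days), eventual males",
        "apop": "adult pre-oviposition period (days), females that laid",
        "tpop": "total pre-oviposition period, oviposition to first egg (days)",
        "oviposition_days": "census days with >= 1 egg, per adult female",
        "fecundity": "lifetime eggs per adult female",
        "adult_longevity_female": "adult lifespan (days), emergence to death",
        "adult_longevity_male": "adult lifespan (days), emergence to death",
        "total_longevity_female": "total lifespan (days), egg to death",
        "total_longevity_male": "total lifespan (days), egg to death",
        "total_longevity": "total lifespan (days), all individuals incl. immature deaths",
    }

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for f in fields(self):
            val = getattr(self, f.name)
            if isinstance(val, MeanSE):
                rows.append((f.name, val.mean, val.se, val.n,
                             self.DEFINITIONS.get(f.name, "")))
            elif f.name in ("preadult_survival", "sex_ratio"):
                rows.append((f.name, val, math.nan, self.n_adults if f.name == "sex_ratio" else self.n,
                             self.DEFINITIONS.get(f.name, "")))
        return pd.DataFrame(rows, columns=["statistic", "mean", "se", "n", "definition"])


def _first_egg_age(rec: IndividualRecord) -> int | None:
    laying = [a for a, eggs in rec.daily_fecundity.items() if eggs > 0]
    return min(laying) if laying else None


def summarize(cohort: CohortDataset) -> LifeTableSummary:
    """Compute all scalar statistics of one cohort.

    Reproductive statistics are undefined (NaN, n = 0) rather than zero when
    no female ever laid — the all-larvae-die treatment must summarize
    gracefully.
    """
    cohort.validate()
    records = cohort.active
    if not records:
        raise ValueError("cohort has no non-excluded individuals")
    n = len(records)
    adults = [r for r in records if r.is_adult]
    females = [r for r in adults if r.sex == "female"]
    males = [r for r in adults if r.sex == "male"]
    layers = [r for r in females if _first_egg_age(r) is not None]

    apop = [_first_egg_age(r) - r.emergence_age for r in layers]
    tpop = [_first_egg_age(r) for r in layers]
    ovi_days = [sum(1 for e in r.daily_fecundity.values() if e > 0) for r in females]
    eggs = [sum(r.daily_fecundity.values()) for r in females]

    return LifeTableSummary(
        treatment=cohort.treatment,
        n=n,
        n_adults=len(adults),
        n_females=len(females),
        n_males=len(males),
        preadult_survival=len(adults) / n,
        sex_ratio=(len(females) / len(adults)) if adults else math.nan,
        immature_female=MeanSE.of([r.emergence_age for r in females]),
        immature_male=MeanSE.of([r.emergence_age for r in males]),
        apop=MeanSE.of(apop),
        tpop=MeanSE.of(tpop),
        oviposition_days=MeanSE.of(ovi_days),
        fecundity=MeanSE.of(eggs),
        adult_longevity_female=MeanSE.of([r.death_age - r.emergence_age for r in females]),
        adult_longevity_male=MeanSE.of([r.death_age - r.emergence_age for r in males]),
        total_longevity_female=MeanSE.of([r.death_age for r in females]),
        total_longevity_male=MeanSE.of([r.death_age for r in males]),
        total_longevity=MeanSE.of([r.death_age for r in records]),
    )


def stage_duration_table(cohort: CohortDataset) -> pd.DataFrame:
    """Per-stage duration means over completers, plus the larva-adult composite.

    A stage is completed when a later stage was entered; the final, truncated
    stage occupancy of an individual never enters a duration mean (it still
    counts in the survival schedule).  The composite sums every stage between
    the first and the adult stage (L1 through pupa under the default
    ontology) for individuals reaching adulthood.
    """
    cohort.validate()
    records = cohort.active
    ontology = list(cohort.stage_ontology)
    immature = [s for s in ontology if s != "adult"]
    rows = []
    for stage in immature:
        pos = ontology.index(stage)
        durations = [
            r.stage_durations[stage]
            for r in records
            if stage in r.stage_durations and ontology.index(r.death_stage) > pos
        ]
        m = MeanSE.of(durations)
        rows.append((stage, m.mean, m.se, m.n))
    composite_stages = immature[1:]
    comp = [
        sum(r.stage_durations[s] for s in composite_stages)
        for r in records
        if r.is_adult
    ]
    m = MeanSE.of(comp)
    rows.append(("larva_adult", m.mean, m.se, m.n))
    return pd.DataFrame(rows, columns=["stage", "mean", "se", "n"])
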