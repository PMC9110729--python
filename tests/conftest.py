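"""Shared cohort builders for the test suite.

All fixtures are generated programmatically: deterministic count-structured
cohorts mirroring the published survivor tables, and seeded random cohorts
for brute-force oracle comparisons.
"""

from __future__ import annotations

import numpy as np
import pytest

from agestage.cohort import CohortDataset, IndividualRecord
from agestage.simulate import count_cohort


def make_record(
    rid: str,
    durations: dict[str, int],
    sex: str = "undetermined",
    fecundity: dict[int, int] | None = None,
    treatment: str = "toy",
    excluded: bool = False,
) -> IndividualRecord:
    """Record with death_age/death_stage derived from the durations."""
    stages = list(durations)
    return IndividualRecord(
        id=rid,
        treatment=treatment,
        stage_durations=dict(durations),
        death_stage=stages[-1],
        death_age=sum(durations.values()),
        sex=sex,
        daily_fecundity=dict(fecundity or {}),
        excluded=excluded,
    )


def random_cohort(rng: np.random.Generator, n_max: int = 10) -> CohortDataset:
    """Small random but valid cohort, for oracle-equivalence checks."""
    stages = ("egg", "L1", "L2", "L3", "L4", "prepupa", "pupa", "adult")
    n = int(rng.integers(2, n_max + 1))
    individuals = []
    for i in range(n):
        durations: dict[str, int] = {}
        died = False
        for stage in stages[:-1]:
            dur = int(rng.integers(1, 5))
            if rng.random() < 0.15:  # dies inside this stage
                durations[stage] = int(rng.integers(1, dur + 1))
                died = True
                break
            durations[stage] = dur
        if died:
            individuals.append(make_record(f"r{i:02d}", durations, treatment="rand"))
            continue
        sex = "female" if rng.random() < 0.5 else "male"
        adult_days = int(rng.integers(1, 16))
        durations["adult"] = adult_days
        emergence = sum(d for s, d in durations.items() if s != "adult")
        fec = {}
        if sex == "female":
            for age in range(emergence, emergence + adult_days):
                eggs = int(rng.poisson(2.0))
                if eggs:
                    fec[age] = eggs
        individuals.append(make_record(f"r{i:02d}", durations, sex=sex, fecundity=fec,
                                       treatment="rand"))
    cohort = CohortDataset(treatment="rand", individuals=individuals, stage_ontology=stages)
    cohort.validate()
    return cohort


@pytest.fixture
def urticae_counts_cohort() -> CohortDataset:
    """50-egg cohort with the spider-mite-diet survivor structure:

    48 of 50 reach adulthood (25 females, 23 males), the 2 losses dying in
    the pupal stage.
    """
    return count_cohort(
        "t_urticae",
        n_female=25,
        n_male=23,
        n_immature_deaths=2,
        death_stage="pupa",
        stage_days={"egg": 3, "L1": 2, "L2": 2, "L3": 3, "L4": 4, "prepupa": 1, "pupa": 4},
        adult_days_female=89,
        adult_days_male=85,
        eggs_per_female={8: 5, 9: 7, 10: 6},
    )


@pytest.fixture
def ogmophallos_counts_cohort() -> CohortDataset:
    """50-egg cohort with the peanut-mite-diet survivor structure:

    37 adults (17 females, 20 males), 13 dying as second instars.
    """
    return count_cohort(
        "t_ogmophallos",
        n_female=17,
        n_male=20,
        n_immature_deaths=13,
        death_stage="L2",
        stage_days={"egg": 3, "L1": 3, "L2": 3, "L3": 3, "L4": 5, "prepupa": 1, "pupa": 4},
        adult_days_female=28,
        adult_days_male=27,
        eggs_per_female={13: 4, 14: 5},
    )


def table2_cohort() -> CohortDataset:
    """Diet-switch cohort of 20 larvae, 18 completing development.

    Integer durations chosen so the per-stage means over completers round to
    2.3, 3.1, 3.4, 4.2, 1.0 and 3.8 days (L1..pupa) and the larva-adult
    composite to 17.8 days.
    """
    l1 = [3] * 6 + [2] * 12          # sum 42 over the 18 completers
    l2 = [4] * 2 + [3] * 16          # sum 56
    l3 = [4] * 7 + [3] * 11          # sum 61
    l4 = [5] * 4 + [4] * 14          # sum 76
    pupa = [3] * 4 + [4] * 14        # sum 68
    individuals = []
    for i in range(18):
        durations = {
            "egg": 3, "L1": l1[i], "L2": l2[i], "L3": l3[i], "L4": l4[i],
            "prepupa": 1, "pupa": pupa[i], "adult": 5,
        }
        sex = "female" if i % 2 == 0 else "male"
        individuals.append(make_record(f"d{i:02d}", durations, sex=sex,
                                       treatment="evansi_switch"))
    for i in (18, 19):  # the two larvae dying as third instars
        durations = {"egg": 3, "L1": 2, "L2": 3, "L3": 2}
        individuals.append(make_record(f"d{i:02d}", durations, treatment="evansi_switch"))
    cohort = CohortDataset(treatment="evansi_switch", individuals=individuals)
    cohort.validate()
    return cohort
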