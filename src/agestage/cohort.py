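"""Cohort data model and CSV input/output.

A cohort is the unit of an age-stage, two-sex life-table experiment: a set of
same-aged individuals (here: freshly laid ladybird eggs) followed by daily
census until the last death.  Each individual carries its stage-transition
history, sex (assigned at adult emergence), death age, and — for females — the
daily egg counts recorded at each census.

Age convention: age 0 is the day of oviposition; all ages are integer days
(the experimental unit is a 24-h census interval).  An individual with
``death_age = d`` is observed alive on days ``0 .. d-1``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "DEFAULT_STAGES",
    "IndividualRecord",
    "CohortDataset",
    "CohortValidationError",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "fecundity_path",
]

#: Default developmental stage ontology, oviposition to death.
DEFAULT_STAGES = ("egg", "L1", "L2", "L3", "L4", "prepupa", "pupa", "adult")

SEXES = ("female", "male", "undetermined")


class CohortValidationError(ValueError):
    """A record violates the cohort data-model invariants."""


class CohortFormatError(ValueError):
    """An input file does not match the documented CSV dialect."""


@dataclass
class IndividualRecord:
    """Life history of one individual, from oviposition to death.

    ``stage_durations`` holds one entry per stage *entered*, in ontology
    order; the last entry is the stage the individual died in, valued with
    the days it survived there.  Hence ``death_age`` always equals the sum
    of the recorded durations.  A stage is *completed* only if a later
    stage was entered, so duration means over completers exclude the final,
    truncated stage occupancy.
    """

    id: str
    treatment: str
    stage_durations: dict[str, int]
    death_stage: str
    death_age: int
    sex: str = "undetermined"
    daily_fecundity: dict[int, int] = field(default_factory=dict)
    excluded: bool = False

    # -- derived accessors -------------------------------------------------

    @property
    def is_adult(self) -> bool:
        return "adult" in self.stage_durations

    @property
    def emergence_age(self) -> int | None:
        """Age (days) at adult emergence, i.e. total immature duration."""
        if not self.is_adult:
            return None
        return sum(d for s, d in self.stage_durations.items() if s != "adult")

    def stage_at(self, age: int) -> str | None:
        """Stage occupied on census day ``age``; None if dead."""
        cum = 0
        for stage, dur in self.stage_durations.items():
            cum += dur
            if age < cum:
                return stage
        return None

    def completed_stages(self) -> list[str]:
        stages = list(self.stage_durations)
        return stages[:-1]

    def validate(self, stage_ontology: Iterable[str]) -> None:
        ontology = list(stage_ontology)
        stages = list(self.stage_durations)
        if not stages:
            raise CohortValidationError(f"{self.id}: no stages entered")
        if stages != ontology[: len(stages)]:
            raise CohortValidationError(
                f"{self.id}: stages {stages} are not a prefix of the ontology {ontology}"
            )
        if self.death_stage != stages[-1]:
            raise CohortValidationError(
                f"{self.id}: death_stage {self.death_stage!r} is not the last entered "
                f"stage {stages[-1]!r}"
            )
        if any(not isinstance(d, int) or d < 1 for d in self.stage_durations.values()):
            raise CohortValidationError(f"{self.id}: stage durations must be integers >= 1")
        if self.death_age != sum(self.stage_durations.values()):
            raise CohortValidationError(
                f"{self.id}: death_age {self.death_age} != sum of stage durations "
                f"{sum(self.stage_durations.values())}"
            )
        if self.sex not in SEXES:
            raise CohortValidationError(f"{self.id}: unknown sex {self.sex!r}")
        if self.is_adult and self.sex == "undetermined":
            raise CohortValidationError(
                f"{self.id}: adults are sexed at emergence; sex cannot be undetermined"
            )
        if self.daily_fecundity:
            if self.sex != "female":
                raise CohortValidationError(
                    f"{self.id}: fecundity recorded for a non-female individual"
                )
            emergence = self.emergence_age
            for age, eggs in self.daily_fecundity.items():
                if not isinstance(eggs, int) or eggs < 0:
                    raise CohortValidationError(
                        f"{self.id}: egg counts must be non-negative integers"
                    )
                if emergence is None or age < emergence or age >= self.death_age:
                    raise CohortValidationError(
                        f"{self.id}: egg count at age {age} outside the adult lifespan"
                    )


@dataclass
class CohortDataset:
    """One treatment's set of individuals plus its stage ontology."""

    treatment: str
    individuals: list[IndividualRecord] = field(default_factory=list)
    stage_ontology: tuple[str, ...] = DEFAULT_STAGES
    census_step: int = 1

    @property
    def active(self) -> list[IndividualRecord]:
        """Individuals contributing to analysis (excluded flags dropped)."""
        return [r for r in self.individuals if not r.excluded]

    @property
    def n(self) -> int:
        return len(self.active)

    def validate(self) -> None:
        seen: set[str] = set()
        for rec in self.individuals:
            if rec.id in seen:
                raise CohortValidationError(f"duplicate individual id {rec.id!r}")
            seen.add(rec.id)
            rec.validate(self.stage_ontology)

    def survivors_of(self, stage: str) -> int:
        """Number of non-excluded individuals that entered ``stage``."""
        return sum(1 for r in self.active if stage in r.stage_durations)


# ---------------------------------------------------------------------------
# CSV dialect
#
# individuals file: id, treatment, excluded, sex, death_stage, death_age,
#                   dur_<stage> ... (one column per ontology stage; empty =
#                   stage never entered).
# fecundity file (<stem>.fecundity.csv): id, age_day, eggs  (long format).
# UTF-8, comma separated, "." decimal, rows sorted by id (and age_day).
# ---------------------------------------------------------------------------

FIXED_COLUMNS = ("id", "treatment", "excluded", "sex", "death_stage", "death_age")


def fecundity_path(path: Path | str) -> Path:
    path = Path(path)
    return path.with_name(path.stem + ".fecundity.csv")


def write_cohort(cohort: CohortDataset, path: Path | str) -> None:
    """Write a cohort to the documented two-file CSV dialect (lossless).

    Deterministic: fixed column order, rows sorted by individual id, so
    write→read→write is byte-identical.
    """
    cohort.validate()
    path = Path(path)
    stages = cohort.stage_ontology
    header = list(FIXED_COLUMNS) + [f"dur_{s}" for s in stages]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(header)
        for rec in sorted(cohort.individuals, key=lambda r: r.id):
            row = [
                rec.id,
                rec.treatment,
                "1" if rec.excluded else "0",
                rec.sex,
                rec.death_stage,
                str(rec.death_age),
            ]
            row += [str(rec.stage_durations.get(s, "")) for s in stages]
            writer.writerow(row)
    with open(fecundity_path(path), "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["id", "age_day", "eggs"])
        for rec in sorted(cohort.individuals, key=lambda r: r.id):
            for age in sorted(rec.daily_fecundity):
                writer.writerow([rec.id, str(age), str(rec.daily_fecundity[age])])


def read_cohort(
    path: Path | str,
    format: str = "individual_csv",
    stage_ontology: tuple[str, ...] = DEFAULT_STAGES,
) -> CohortDataset:
    """Read and validate a cohort written in the ``individual_csv`` dialect.

    Malformed rows are reported with their line number; the companion
    fecundity file is read when present.
    """
    if format != "individual_csv":
        raise CohortFormatError(f"unknown format {format!r}")
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFormatError(f"{path}: empty file") from None
        if header[: len(FIXED_COLUMNS)] != list(FIXED_COLUMNS):
            raise CohortFormatError(
                f"{path}: header {header[:len(FIXED_COLUMNS)]} does not start with the "
                f"required columns {list(FIXED_COLUMNS)}"
            )
        stage_cols = header[len(FIXED_COLUMNS):]
        if not stage_cols or any(not c.startswith("dur_") for c in stage_cols):
            raise CohortFormatError(f"{path}: stage columns must be named dur_<stage>")
        # the file spells out its own ontology through the dur_ columns
        stage_ontology = tuple(c[4:] for c in stage_cols)

        records: dict[str, IndividualRecord] = {}
        treatment = ""
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise CohortFormatError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(row)}"
                )
            rid, treat, excl, sex, death_stage, death_age = row[: len(FIXED_COLUMNS)]
            durations: dict[str, int] = {}
            for stage, cell in zip(stage_ontology, row[len(FIXED_COLUMNS):]):
                if cell != "":
                    try:
                        durations[stage] = int(cell)
                    except ValueError:
                        raise CohortFormatError(
                            f"{path}:{lineno}: non-integer duration {cell!r} for {stage}"
                        ) from None
            try:
                rec = IndividualRecord(
                    id=rid,
                    treatment=treat,
                    stage_durations=durations,
                    death_stage=death_stage,
                    death_age=int(death_age),
                    sex=sex,
                    excluded=excl in ("1", "true", "True"),
                )
            except ValueError:
                raise CohortFormatError(
                    f"{path}:{lineno}: non-integer death_age {death_age!r}"
                ) from None
            if rid in records:
                raise CohortValidationError(f"{path}:{lineno}: duplicate id {rid!r}")
            records[rid] = rec
            treatment = treatment or treat

    fec = fecundity_path(path)
    if fec.exists():
        with open(fec, newline="", encoding="utf-8") as fh:
            reader = csv.reader(fh)
            fheader = next(reader, None)
            if fheader != ["id", "age_day", "eggs"]:
                raise CohortFormatError(f"{fec}: malformed header {fheader}")
            for lineno, row in enumerate(reader, start=2):
                if not row:
                    continue
                rid, age, eggs = row
                if rid not in records:
                    raise CohortValidationError(
                        f"{fec}:{lineno}: fecundity for unknown individual {rid!r}"
                    )
                records[rid].daily_fecundity[int(age)] = int(eggs)

    cohort = CohortDataset(
        treatment=treatment, individuals=list(records.values()), stage_ontology=stage_ontology
    )
    errors = []
    for lineno, rec in enumerate(cohort.individuals, start=2):
        try:
            rec.validate(stage_ontology)
        except CohortValidationError as exc:
            errors.append(f"{path}:{lineno}: {exc}")
    if errors:
        raise CohortValidationError("; ".join(errors))
    cohort.validate()
    return cohort
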