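"""Survey-record schema and CSV I/O.

The unit of observation is one captured adult damselfly: where and when it
was caught (population and year, which jointly define the grouping level for
all random effects), its phenotype (one of three heritable female colour
morphs or male), its water-mite count, whether it was caught in copula, and
— for mated females only — the number of eggs laid over 72 h in captivity.

The exchange format is a UTF-8 comma-separated long table with columns
``population, year, phenotype, mites, mated, eggs``.  A missing egg count is
an empty field; zero eggs is a legitimate observation and is written as
``0``.
"""

from __future__ import annotations

import csv
import enum
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Phenotype",
    "SurveyRecord",
    "GroupKey",
    "SurveySummary",
    "SurveyValidationError",
    "read_survey_csv",
    "write_survey_csv",
    "summarize_survey",
    "records_to_frame",
    "frame_to_records",
]

CSV_COLUMNS = ("population", "year", "phenotype", "mites", "mated", "eggs")


class Phenotype(enum.Enum):
    """The four phenotype classes scored in the field.

    ``A`` androchrome (male-coloured) female, ``I`` *Infuscans* female,
    ``O`` *Infuscans-obsoleta* female, ``M`` male.
    """

    A = "A"
    I = "I"  # noqa: E741
    O = "O"  # noqa: E741
    M = "M"

    @property
    def is_female(self) -> bool:
        return self is not Phenotype.M


#: Female morphs for which fecundity tolerance is modelled.  The O morph is
#: too rare for stable random-effect estimation and is excluded by default.
TOLERANCE_MORPHS = (Phenotype.A, Phenotype.I)


class GroupKey(tuple):
    """A (population, year) pair — the random-effect level of every model."""

    __slots__ = ()

    def __new__(cls, population: str, year: int):
        return super().__new__(cls, (str(population), int(year)))

    @property
    def population(self) -> str:
        return self[0]

    @property
    def year(self) -> int:
        return self[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GroupKey({self[0]!r}, {self[1]})"


class SurveyValidationError(ValueError):
    """A survey record violates the schema invariants."""


@dataclass(frozen=True)
class SurveyRecord:
    """One captured damselfly."""

    population: str
    year: int
    phenotype: Phenotype
    mites: int
    mated: bool
    eggs: Optional[int] = None

    @property
    def group(self) -> GroupKey:
        return GroupKey(self.population, self.year)

    def validate(self) -> None:
        if self.mites < 0:
            raise SurveyValidationError(f"negative mite count {self.mites}")
        if self.eggs is not None:
            if self.eggs < 0:
                raise SurveyValidationError(f"negative egg count {self.eggs}")
            if not self.mated:
                raise SurveyValidationError("eggs recorded on an unmated individual")
            if not self.phenotype.is_female:
                raise SurveyValidationError("eggs recorded on a male")


def _parse_row(row: dict, line: int) -> SurveyRecord:
    try:
        phenotype = Phenotype(row["phenotype"].strip())
    except ValueError:
        raise SurveyValidationError(
            f"line {line}: unknown phenotype code {row['phenotype']!r}"
        ) from None
    eggs_field = (row.get("eggs") or "").strip()
    mated_field = row["mated"].strip().lower()
    if mated_field not in {"true", "false", "0", "1"}:
        raise SurveyValidationError(f"line {line}: bad mated flag {row['mated']!r}")
    try:
        rec = SurveyRecord(
            population=row["population"].strip(),
            year=int(row["year"]),
            phenotype=phenotype,
            mites=int(row["mites"]),
            mated=mated_field in {"true", "1"},
            eggs=int(eggs_field) if eggs_field else None,
        )
    except ValueError as exc:
        raise SurveyValidationError(f"line {line}: {exc}") from None
    try:
        rec.validate()
    except SurveyValidationError as exc:
        raise SurveyValidationError(f"line {line}: {exc}") from None
    return rec


def read_survey_csv(path, strict: bool = True) -> list[SurveyRecord]:
    """Read survey records from ``path``.

    In strict mode (default) any invariant violation aborts with a
    :class:`SurveyValidationError` naming the offending line.  In lenient
    mode offending rows are dropped and the number dropped is logged.
    """
    path = Path(path)
    records: list[SurveyRecord] = []
    dropped = 0
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        missing = set(CSV_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise SurveyValidationError(f"missing columns: {sorted(missing)}")
        for line, row in enumerate(reader, start=2):
            try:
                records.append(_parse_row(row, line))
            except SurveyValidationError:
                if strict:
                    raise
                dropped += 1
    if dropped:
        logger.warning("dropped %d invalid rows from %s", dropped, path)
    return records


def write_survey_csv(records: Iterable[SurveyRecord], path) -> int:
    """Write ``records`` to ``path``; returns the number of rows written."""
    path = Path(path)
    n = 0
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for rec in records:
            rec.validate()
            writer.writerow(
                [
                    rec.population,
                    rec.year,
                    rec.phenotype.value,
                    rec.mites,
                    str(rec.mated).lower(),
                    "" if rec.eggs is None else rec.eggs,
                ]
            )
            n += 1
    return n


@dataclass(frozen=True)
class SurveySummary:
    """Descriptive counts for a survey."""

    total: int
    counts: dict  # Phenotype -> int
    zero_fraction: float
    n_groups: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"phenotype": [p.value for p in self.counts], "n": list(self.counts.values())}
        )


def summarize_survey(records: Sequence[SurveyRecord]) -> SurveySummary:
    """Counts per phenotype, fraction of uninfected hosts, distinct groups."""
    records = list(records)
    if not records:
        raise ValueError("empty survey")
    counts = Counter(r.phenotype for r in records)
    zeros = sum(1 for r in records if r.mites == 0)
    groups = {r.group for r in records}
    return SurveySummary(
        total=len(records),
        counts={p: counts.get(p, 0) for p in Phenotype if p in counts},
        zero_fraction=zeros / len(records),
        n_groups=len(groups),
    )


def records_to_frame(records: Sequence[SurveyRecord]) -> pd.DataFrame:
    """Long-format DataFrame view used internally by the model fitters."""
    return pd.DataFrame(
        {
            "population": [r.population for r in records],
            "year": [r.year for r in records],
            "phenotype": [r.phenotype.value for r in records],
            "mites": [r.mites for r in records],
            "mated": [r.mated for r in records],
            "eggs": [float("nan") if r.eggs is None else r.eggs for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[SurveyRecord]:
    records = []
    for row in frame.itertuples(index=False):
        eggs = getattr(row, "eggs", None)
        if eggs is not None and pd.isna(eggs):
            eggs = None
        rec = SurveyRecord(
            population=str(row.population),
            year=int(row.year),
            phenotype=Phenotype(row.phenotype),
            mites=int(row.mites),
            mated=bool(row.mated),
            eggs=None if eggs is None else int(eggs),
        )
        rec.validate()
        records.append(rec)
    return records
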