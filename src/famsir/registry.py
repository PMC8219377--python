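"""Domain types and file I/O for a linked family/cancer registry.

The registry consists of two tables: persons (children and their mothers,
grouped into families) and cancer events (primary diagnoses carrying an
ICCC-3 main group).  Everything downstream — proband designation, at-risk
windows, person-time — consumes the validated output of :func:`read_registry`.

Dates are carried as calendar years only: the analysis collapses every event
to the middle of its calendar year, so finer resolution never changes a
result.  Full ISO dates are accepted on input and truncated to the year with
a logged note.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Role",
    "Sex",
    "RaceEthnicity",
    "ICCC3Group",
    "Category",
    "PersonRecord",
    "CancerEvent",
    "RegistryConfig",
    "RegistryError",
    "SchemaError",
    "IntegrityError",
    "ParseError",
    "classify_hema_solid",
    "group_abbreviation",
    "read_registry",
    "write_registry",
    "validate_registry",
    "records_to_persons",
    "records_to_events",
    "persons_to_records",
    "events_to_records",
]


class Role(str, enum.Enum):
    child = "child"
    mother = "mother"


class Sex(str, enum.Enum):
    male = "male"
    female = "female"


class RaceEthnicity(str, enum.Enum):
    """Self-identified race/ethnicity strata (the mother's group stands for
    the whole family)."""

    latino = "latino"
    nl_white = "nl_white"
    nl_black = "nl_black"
    nl_api = "nl_api"
    other = "other"


class ICCC3Group(str, enum.Enum):
    """The 12 main diagnostic groups of the International Classification of
    Childhood Cancer, third edition."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    VII = "VII"
    VIII = "VIII"
    IX = "IX"
    X = "X"
    XI = "XI"
    XII = "XII"


class Category(str, enum.Enum):
    hematologic = "hematologic"
    solid = "solid"


#: Conventional short labels for the 12 ICCC-3 main groups.
GROUP_ABBREVIATIONS: dict[ICCC3Group, str] = {
    ICCC3Group.I: "Leukemias",
    ICCC3Group.II: "Lymphomas",
    ICCC3Group.III: "CNS tumors",
    ICCC3Group.IV: "Neuroblastomas",
    ICCC3Group.V: "Retinoblastoma",
    ICCC3Group.VI: "Renal tumors",
    ICCC3Group.VII: "Hepatic tumors",
    ICCC3Group.VIII: "Bone tumors",
    ICCC3Group.IX: "Sarcomas",
    ICCC3Group.X: "GCT",
    ICCC3Group.XI: "Epithelial neoplasms",
    ICCC3Group.XII: "Other",
}

#: Leukemias (I) and lymphomas (II) form the hematologic category; the
#: remaining ten groups are solid.
HEMATOLOGIC_GROUPS = frozenset({ICCC3Group.I, ICCC3Group.II})


class RegistryError(Exception):
    """Base class for registry validation failures."""


class SchemaError(RegistryError):
    """A required column is missing from an input file."""


class IntegrityError(RegistryError):
    """Referential integrity or uniqueness violated."""


class ParseError(RegistryError):
    """A cell could not be parsed into its domain type."""


@dataclass(frozen=True)
class PersonRecord:
    person_id: str
    family_id: str
    role: Role
    sex: Sex
    race_ethnicity: RaceEthnicity
    birth_year: int


@dataclass(frozen=True)
class CancerEvent:
    person_id: str
    diagnosis_year: int
    iccc3_group: ICCC3Group
    subtype_label: Optional[str] = None
    sequence: int = 1


@dataclass(frozen=True)
class RegistryConfig:
    """Study-design parameters shared across the pipeline.

    Parameters
    ----------
    study_start_year, study_end_year
        Calendar bounds of registry capture; diagnoses outside them are not
        observable.
    proband_age_max
        Upper age (years, inclusive) for diagnosis intake of probands.
    follow_up_age_max
        Follow-up ceiling for relatives and second-primary windows; the
        default 30 is the upper edge of the last reference age interval
        (25-29 years).
    paper_mode
        When true, mothers (or same-year siblings) already diagnosed at the
        start of the at-risk window contribute a degenerate event window, so
        observed counts match a convention that counts every affected mother.
        The principled default excludes them: follow-up starts only at the
        proband's diagnosis.
    censor_at_other_cancer
        In type-specific analyses, whether a relative's non-qualifying cancer
        ends their window (default) or follow-up continues to censoring.
    relapse_min_gap_years
        If positive, a same-group second event within this many years of the
        first primary is adjudicated a relapse regardless of subtype.
    """

    study_start_year: int = 1989
    study_end_year: int = 2015
    proband_age_max: int = 26
    follow_up_age_max: float = 30.0
    paper_mode: bool = False
    censor_at_other_cancer: bool = True
    relapse_min_gap_years: float = 0.0
    age_breaks: tuple = (0, 1, 5, 10, 15, 20, 25, 30)

    def __post_init__(self) -> None:
        if self.study_start_year >= self.study_end_year:
            raise ValueError("study_start_year must precede study_end_year")
        if self.proband_age_max <= 0:
            raise ValueError("proband_age_max must be positive")

    def scheme(self):
        from .exposure import AgeIntervalScheme

        return AgeIntervalScheme(tuple(self.age_breaks))


def classify_hema_solid(group: ICCC3Group | str) -> Category:
    """Dichotomize an ICCC-3 main group into hematologic vs solid.

    Leukemias (I) and lymphomas (II) are hematologic; CNS tumors,
    neuroblastomas, retinoblastoma, renal, hepatic and bone tumors, sarcomas,
    germ cell tumors, epithelial neoplasms and the unspecified remainder
    (III-XII) are solid.
    """
    group = _coerce_group(group)
    return Category.hematologic if group in HEMATOLOGIC_GROUPS else Category.solid


def group_abbreviation(group: ICCC3Group | str) -> str:
    """Return the conventional short label for an ICCC-3 main group."""
    return GROUP_ABBREVIATIONS[_coerce_group(group)]


def _coerce_group(group: ICCC3Group | str) -> ICCC3Group:
    if isinstance(group, ICCC3Group):
        return group
    try:
        return ICCC3Group(str(group).strip().upper())
    except ValueError:
        raise RegistryError(f"unknown ICCC-3 group: {group!r}") from None


# ---------------------------------------------------------------------------
# File I/O

PERSON_COLUMNS = ["person_id", "family_id", "role", "sex", "race_ethnicity", "birth_year"]
EVENT_COLUMNS = ["person_id", "diagnosis_year", "iccc3_group"]
OPTIONAL_EVENT_COLUMNS = ["subtype_label", "sequence"]


def _read_delimited(path: str | Path) -> pd.DataFrame:
    # sep=None sniffs comma vs tab
    return pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)


def _parse_year(series: pd.Series, column: str, path) -> pd.Series:
    """Accept plain years or full ISO dates (truncated to year with a note)."""
    s = series.str.strip()
    datelike = s.str.contains("-", regex=False)
    if datelike.any():
        logger.info(
            "%s: %d %s values carry full dates; truncating to calendar year",
            path, int(datelike.sum()), column,
        )
        s = s.where(~datelike, s.str.slice(0, 4))
    try:
        return s.astype(int)
    except ValueError:
        bad = s[~s.str.fullmatch(r"-?\d+")]
        row = int(bad.index[0])
        raise ParseError(f"{path}: row {row}: cannot parse {column}={series.iloc[row]!r}")


def _parse_enum(series: pd.Series, enum_cls, column: str, path) -> pd.Series:
    valid = {e.value for e in enum_cls}
    s = series.str.strip()
    if enum_cls is ICCC3Group:
        s = s.str.upper()
    else:
        s = s.str.lower()
    bad = ~s.isin(valid)
    if bad.any():
        row = int(s.index[bad][0])
        raise ParseError(f"{path}: row {row}: invalid {column} value {series.iloc[row]!r}")
    return s


def read_registry(
    persons_path: str | Path,
    events_path: str | Path,
    config: RegistryConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate a persons/events file pair.

    Both files are delimited text (comma or tab, sniffed).  Returns the two
    validated tables; the events table always carries ``subtype_label``
    (nullable) and ``sequence`` (derived from diagnosis order when absent).

    Raises
    ------
    SchemaError
        if a required column is missing (the message names it).
    IntegrityError
        for duplicate person ids, orphan events, or families with more than
        one mother.
    ParseError
        for a cell outside its enum vocabulary or a malformed year.
    """
    persons_raw = _read_delimited(persons_path)
    events_raw = _read_delimited(events_path)

    for col in PERSON_COLUMNS:
        if col not in persons_raw.columns:
            raise SchemaError(f"{persons_path}: missing required column {col!r}")
    for col in EVENT_COLUMNS:
        if col not in events_raw.columns:
            raise SchemaError(f"{events_path}: missing required column {col!r}")

    persons = pd.DataFrame(
        {
            "person_id": persons_raw["person_id"].str.strip(),
            "family_id": persons_raw["family_id"].str.strip(),
            "role": _parse_enum(persons_raw["role"], Role, "role", persons_path),
            "sex": _parse_enum(persons_raw["sex"], Sex, "sex", persons_path),
            "race_ethnicity": _parse_enum(
                persons_raw["race_ethnicity"], RaceEthnicity, "race_ethnicity", persons_path
            ),
            "birth_year": _parse_year(persons_raw["birth_year"], "birth_year", persons_path),
        }
    )

    events = pd.DataFrame(
        {
            "person_id": events_raw["person_id"].str.strip(),
            "diagnosis_year": _parse_year(
                events_raw["diagnosis_year"], "diagnosis_year", events_path
            ),
            "iccc3_group": _parse_enum(
                events_raw["iccc3_group"], ICCC3Group, "iccc3_group", events_path
            ),
        }
    )
    if "subtype_label" in events_raw.columns:
        sub = events_raw["subtype_label"].str.strip()
        events["subtype_label"] = sub.where(sub != "", None)
    else:
        events["subtype_label"] = None
    if "sequence" in events_raw.columns and (events_raw["sequence"].str.strip() != "").all():
        events["sequence"] = _parse_year(events_raw["sequence"], "sequence", events_path)
    else:
        events["sequence"] = 0  # derived below

    events = derive_sequence(events)
    validate_registry(persons, events, config)
    return persons, events


def derive_sequence(events: pd.DataFrame) -> pd.DataFrame:
    """Ensure per-person sequence numbers are consecutive from 1 in diagnosis
    order; derive them when absent or inconsistent with that ordering."""
    events = events.sort_values(
        ["person_id", "diagnosis_year", "sequence"], kind="stable"
    ).reset_index(drop=True)
    derived = events.groupby("person_id", sort=False).cumcount() + 1
    if (events["sequence"] > 0).all():
        if not (events["sequence"].to_numpy() == derived.to_numpy()).all():
            raise IntegrityError(
                "event sequence numbers are not consecutive from 1 in diagnosis order"
            )
    events["sequence"] = derived
    return events


def validate_registry(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    config: RegistryConfig | None = None,
) -> None:
    """Check registry invariants; raise :class:`IntegrityError` on violation."""
    dup = persons["person_id"][persons["person_id"].duplicated()]
    if len(dup):
        raise IntegrityError(f"duplicated person_id values: {sorted(set(dup))[:10]}")
    mothers = persons[persons["role"] == Role.mother.value]
    extra = mothers.groupby("family_id").size()
    extra = extra[extra > 1]
    if len(extra):
        raise IntegrityError(f"families with more than one mother: {list(extra.index[:10])}")
    orphan = set(events["person_id"]) - set(persons["person_id"])
    if orphan:
        raise IntegrityError(f"events reference unknown person ids: {sorted(orphan)[:10]}")
    if config is not None:
        kids = persons[persons["role"] == Role.child.value]
        out = kids[
            (kids["birth_year"] < config.study_start_year)
            | (kids["birth_year"] > config.study_end_year)
        ]
        if len(out):
            raise IntegrityError(
                "child birth years outside the registry period: "
                f"{sorted(out['person_id'])[:10]}"
            )


def write_registry(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    persons_path: str | Path,
    events_path: str | Path,
    sep: str = ",",
) -> None:
    """Write the two registry tables as delimited text (round-trips with
    :func:`read_registry`)."""
    persons[PERSON_COLUMNS].to_csv(persons_path, sep=sep, index=False)
    cols = EVENT_COLUMNS + OPTIONAL_EVENT_COLUMNS
    events[cols].to_csv(events_path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Record <-> frame converters

def records_to_persons(records: Iterable[PersonRecord]) -> pd.DataFrame:
    rows = [
        (p.person_id, p.family_id, p.role.value, p.sex.value, p.race_ethnicity.value, p.birth_year)
        for p in records
    ]
    return pd.DataFrame(rows, columns=PERSON_COLUMNS)


def records_to_events(records: Iterable[CancerEvent]) -> pd.DataFrame:
    rows = [
        (e.person_id, e.diagnosis_year, e.iccc3_group.value, e.subtype_label, e.sequence)
        for e in records
    ]
    return pd.DataFrame(rows, columns=EVENT_COLUMNS + OPTIONAL_EVENT_COLUMNS)


def persons_to_records(persons: pd.DataFrame) -> list[PersonRecord]:
    return [
        PersonRecord(
            r.person_id,
            r.family_id,
            Role(r.role),
            Sex(r.sex),
            RaceEthnicity(r.race_ethnicity),
            int(r.birth_year),
        )
        for r in persons.itertuples(index=False)
    ]


def events_to_records(events: pd.DataFrame) -> list[CancerEvent]:
    return [
        CancerEvent(
            r.person_id,
            int(r.diagnosis_year),
            ICCC3Group(r.iccc3_group),
            None if pd.isna(r.subtype_label) else r.subtype_label,
            int(r.sequence),
        )
        for r in events.itertuples(index=False)
    ]
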