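"""Proband designation and left-truncated at-risk windows.

A family's proband is its earliest-diagnosed affected child within the intake
bounds.  Relatives (siblings and the mother) enter follow-up at their age
when the proband is diagnosed and leave at their own qualifying diagnosis or
at censoring (study end or the follow-up age ceiling, whichever comes first).
Second-primary follow-up starts instead at a patient's own first primary.

Under the mid-year convention every event sits at the middle of its calendar
year, so a window that starts at the proband's diagnosis covers the calendar
years strictly after it: an in-window event must satisfy
``start_age < age_at_diagnosis <= end_age``.  A relative diagnosed in the
proband's own diagnosis year (or a mother diagnosed earlier) was never
cancer-free inside the window and contributes neither person-time nor, by
default, an event; ``paper_mode`` counts such relatives through a degenerate
zero-length event window instead.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .registry import (
    CancerEvent,
    ICCC3Group,
    RegistryConfig,
    Role,
    classify_hema_solid,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyCohort",
    "AtRiskWindow",
    "SPMRecord",
    "assign_probands",
    "build_relative_windows",
    "build_spm_windows",
    "flag_relapse",
    "spm_enrichment_table",
    "family_race_map",
]

MODES = ("any_cancer", "same_category", "same_group")


@dataclass(frozen=True)
class FamilyCohort:
    family_id: str
    proband_id: str
    proband_dx_year: int
    proband_group: str
    proband_sex: str
    race_ethnicity: str  # the mother's self-identified group
    relatives: tuple  # of (person_id, role token)


@dataclass(frozen=True)
class AtRiskWindow:
    person_id: str
    stratum: tuple  # (race_ethnicity, sex)
    start_age: float
    end_age: float
    event: int
    event_group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.end_age < self.start_age:
            raise ValueError("window end precedes start")


@dataclass(frozen=True)
class SPMRecord:
    person_id: str
    first_dx_year: int
    second_dx_year: int
    first_group: str
    second_group: str
    relapse_flag: bool


def family_race_map(persons: pd.DataFrame) -> dict[str, str]:
    """Family race/ethnicity := the mother's self-identified group.

    Families without a mother record fall back to the first listed member's
    group (children's own codes are otherwise ignored for stratification).
    """
    mothers = persons[persons["role"] == Role.mother.value]
    out = dict(zip(mothers["family_id"], mothers["race_ethnicity"]))
    for fam, race in zip(persons["family_id"], persons["race_ethnicity"]):
        out.setdefault(fam, race)
    return out


def assign_probands(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    config: RegistryConfig,
) -> list[FamilyCohort]:
    """Designate one proband per family with at least one affected child.

    The proband is the affected child (diagnosis age <= ``proband_age_max``,
    diagnosis year inside the study window) with the earliest diagnosis year;
    ties break on the smaller person id, which cannot change observed or
    expected counts because same-year diagnoses coincide in time under the
    mid-year convention.  Families whose only affected member is the mother
    yield no cohort (logged).
    """
    firsts = events[events["sequence"] == 1].merge(
        persons[["person_id", "family_id", "role", "sex", "birth_year"]], on="person_id"
    )
    kids = firsts[firsts["role"] == Role.child.value].copy()
    kids["dx_age"] = kids["diagnosis_year"] - kids["birth_year"]
    kids = kids[
        (kids["dx_age"] >= 0)
        & (kids["dx_age"] <= config.proband_age_max)
        & (kids["diagnosis_year"] >= config.study_start_year)
        & (kids["diagnosis_year"] <= config.study_end_year)
    ]
    probands = (
        kids.sort_values(["family_id", "diagnosis_year", "person_id"], kind="stable")
        .groupby("family_id", sort=False)
        .head(1)
    )

    affected_mother_only = (
        set(firsts.loc[firsts["role"] == Role.mother.value, "family_id"])
        - set(probands["family_id"])
    )
    if affected_mother_only:
        logger.info(
            "%d families have an affected mother but no affected child; no cohort emitted",
            len(affected_mother_only),
        )

    races = family_race_map(persons)
    by_fam = persons.sort_values("family_id", kind="stable")
    members: dict[str, list] = {}
    for fid, pid, role in zip(by_fam["family_id"], by_fam["person_id"], by_fam["role"]):
        members.setdefault(fid, []).append((pid, role))
    cohorts = []
    for row in probands.itertuples(index=False):
        relatives = tuple(
            (pid, role) for pid, role in members[row.family_id] if pid != row.person_id
        )
        cohorts.append(
            FamilyCohort(
                family_id=row.family_id,
                proband_id=row.person_id,
                proband_dx_year=int(row.diagnosis_year),
                proband_group=row.iccc3_group,
                proband_sex=row.sex,
                race_ethnicity=races[row.family_id],
                relatives=relatives,
            )
        )
    return cohorts


def _qualifies(event_group: str, proband_group: str, mode: str) -> bool:
    if mode == "any_cancer":
        return True
    if mode == "same_category":
        return classify_hema_solid(event_group) == classify_hema_solid(proband_group)
    if mode == "same_group":
        return event_group == proband_group
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def build_relative_windows(
    cohort: FamilyCohort,
    persons: pd.DataFrame,
    events: pd.DataFrame,
    config: RegistryConfig,
    mode: str = "any_cancer",
    log: Counter | None = None,
) -> list[AtRiskWindow]:
    """At-risk windows for one cohort's siblings and mother.

    Follow-up starts at the member's age when the proband is diagnosed
    (at birth for siblings born later) and ends at the earliest of: the
    member's qualifying diagnosis, a non-qualifying cancer (when
    ``censor_at_other_cancer``, the default), study end, or the follow-up
    age ceiling.  When censoring at other cancers is disabled, follow-up
    instead continues through non-qualifying diagnoses to the member's
    first qualifying one.  The proband never contributes a window.
    """
    log = log if log is not None else Counter()
    fam = persons[persons["family_id"] == cohort.family_id].set_index("person_id")
    by_person = dict(
        tuple(events.sort_values(["person_id", "sequence"]).groupby("person_id", sort=False))
    )
    windows = []
    for pid, role in cohort.relatives:
        member = fam.loc[pid]
        birth = int(member["birth_year"])
        if birth > config.study_end_year:
            log["born_after_study_end"] += 1
            continue
        start = max(0.0, float(cohort.proband_dx_year - birth))
        ceiling = min(
            config.follow_up_age_max, float(config.study_end_year - birth)
        )
        stratum = (cohort.race_ethnicity, member["sex"])

        own = by_person.get(pid)
        dx_age = dx_group = None
        if own is not None:
            first = own.iloc[0]
            dx_age = float(first["diagnosis_year"] - birth)
            dx_group = first["iccc3_group"]

        if dx_age is not None and dx_age <= start:
            # already affected at (or in the same year as) window start;
            # paper_mode counts the event through a degenerate zero-length
            # window placed at the diagnosis age
            if (
                config.paper_mode
                and dx_age <= min(ceiling, config.follow_up_age_max)
                and _qualifies(dx_group, cohort.proband_group, mode)
            ):
                windows.append(
                    AtRiskWindow(pid, stratum, dx_age, dx_age, 1, dx_group)
                )
                log["paper_mode_pre_window_events"] += 1
            else:
                log["affected_at_window_start"] += 1
            continue

        if ceiling <= start:
            log["beyond_follow_up_ceiling"] += 1
            continue

        end, event, event_group = ceiling, 0, None
        if config.censor_at_other_cancer:
            if dx_age is not None and dx_age <= ceiling:
                if _qualifies(dx_group, cohort.proband_group, mode):
                    end, event, event_group = dx_age, 1, dx_group
                else:
                    end = dx_age
                    log["censored_at_other_cancer"] += 1
        elif own is not None:
            # follow through other cancers to the first qualifying one
            for row in own.itertuples(index=False):
                age = float(row.diagnosis_year - birth)
                if age <= ceiling and _qualifies(
                    row.iccc3_group, cohort.proband_group, mode
                ):
                    end, event, event_group = age, 1, row.iccc3_group
                    break
        windows.append(AtRiskWindow(pid, stratum, start, end, event, event_group))
    return windows


def flag_relapse(
    first: CancerEvent, second: CancerEvent, config: RegistryConfig | None = None
) -> bool:
    """Rule-based relapse adjudication for a putative second primary.

    A second event is flagged as a relapse of the first (and excluded from
    second-primary analyses) when it shares both the ICCC-3 main group and
    the subtype label of the first primary.  With
    ``relapse_min_gap_years > 0``, a same-group second event closer than the
    gap is flagged regardless of subtype.  This rule stands in for a manual
    chart review of post-first-primary diagnosis codes.
    """
    if second.person_id != first.person_id:
        raise ValueError("relapse adjudication requires events of the same person")
    if second.diagnosis_year < first.diagnosis_year:
        raise ValueError("second event precedes the first")
    same_group = first.iccc3_group == second.iccc3_group
    if same_group and first.subtype_label == second.subtype_label:
        return True
    gap = config.relapse_min_gap_years if config is not None else 0.0
    if gap > 0 and same_group and (second.diagnosis_year - first.diagnosis_year) < gap:
        return True
    return False


def _event_from_row(row) -> CancerEvent:
    sub = row.subtype_label
    return CancerEvent(
        person_id=row.person_id,
        diagnosis_year=int(row.diagnosis_year),
        iccc3_group=ICCC3Group(row.iccc3_group),
        subtype_label=None if pd.isna(sub) else sub,
        sequence=int(row.sequence),
    )


def adjudicate_spms(events: pd.DataFrame, config: RegistryConfig) -> list[SPMRecord]:
    """Classify every post-first-primary event as relapse or distinct SPM."""
    records = []
    multi = events[events["person_id"].isin(
        events.loc[events["sequence"] >= 2, "person_id"]
    )].sort_values(["person_id", "sequence"])
    for pid, grp in multi.groupby("person_id", sort=False):
        rows = list(grp.itertuples(index=False))
        first = _event_from_row(rows[0])
        for row in rows[1:]:
            second = _event_from_row(row)
            records.append(
                SPMRecord(
                    person_id=pid,
                    first_dx_year=first.diagnosis_year,
                    second_dx_year=second.diagnosis_year,
                    first_group=first.iccc3_group.value,
                    second_group=second.iccc3_group.value,
                    relapse_flag=flag_relapse(first, second, config),
                )
            )
    return records


def build_spm_windows(
    events: pd.DataFrame,
    persons: pd.DataFrame,
    config: RegistryConfig,
    log: Counter | None = None,
) -> list[AtRiskWindow]:
    """Second-primary at-risk windows for every first-primary child patient.

    Follow-up runs from the first primary diagnosis to the first non-relapse
    second primary or to censoring.  Mothers are excluded; relapses (per
    :func:`flag_relapse`) do not end follow-up and do not count as events.
    Strata use the family's (mother's) race/ethnicity.
    """
    log = log if log is not None else Counter()
    races = family_race_map(persons)
    pinfo = persons.set_index("person_id")
    spm_by_person: dict[str, SPMRecord] = {}
    for rec in adjudicate_spms(events, config):
        if rec.relapse_flag:
            log["relapse_flagged"] += 1
            continue
        cur = spm_by_person.get(rec.person_id)
        if cur is None or rec.second_dx_year < cur.second_dx_year:
            spm_by_person[rec.person_id] = rec

    windows = []
    firsts = events[events["sequence"] == 1]
    for row in firsts.itertuples(index=False):
        person = pinfo.loc[row.person_id]
        if person["role"] != Role.child.value:
            continue
        birth = int(person["birth_year"])
        dx_age = float(row.diagnosis_year - birth)
        if not (
            0 <= dx_age <= config.proband_age_max
            and config.study_start_year <= row.diagnosis_year <= config.study_end_year
        ):
            log["first_primary_outside_intake"] += 1
            continue
        start = dx_age
        ceiling = min(config.follow_up_age_max, float(config.study_end_year - birth))
        if ceiling < start:
            log["beyond_follow_up_ceiling"] += 1
            continue
        stratum = (races[person["family_id"]], person["sex"])
        end, event, event_group = ceiling, 0, None
        spm = spm_by_person.get(row.person_id)
        if spm is not None:
            spm_age = float(spm.second_dx_year - birth)
            if start < spm_age <= ceiling:
                end, event, event_group = spm_age, 1, spm.second_group
        windows.append(AtRiskWindow(row.person_id, stratum, start, end, event, event_group))
    return windows


def spm_enrichment_table(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    config: RegistryConfig,
) -> tuple[int, int, int, int]:
    """2x2 counts of members with an SPM by family-risk status.

    A family "exhibits familial risk" when two or more of its members have a
    primary cancer.  Returns ``(x1, n1, x2, n2)``: SPM carriers and total
    members in familial-risk families, then in all other families.  An empty
    registry yields an all-zero table.
    """
    if len(persons) == 0:
        logger.warning("empty registry: SPM enrichment table is all zero")
        return (0, 0, 0, 0)
    firsts = events[events["sequence"] == 1].merge(
        persons[["person_id", "family_id"]], on="person_id"
    )
    affected_per_family = firsts.groupby("family_id")["person_id"].nunique()
    risk_families = set(affected_per_family[affected_per_family >= 2].index)

    spm_people = {
        rec.person_id for rec in adjudicate_spms(events, config) if not rec.relapse_flag
    }
    fam_of = dict(zip(persons["person_id"], persons["family_id"]))
    fam_sizes = persons.groupby("family_id").size()

    n1 = int(fam_sizes[fam_sizes.index.isin(risk_families)].sum())
    n2 = int(fam_sizes.sum()) - n1
    x1 = sum(1 for pid in spm_people if fam_of[pid] in risk_families)
    x2 = len(spm_people) - x1
    return (x1, n1, x2, n2)
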