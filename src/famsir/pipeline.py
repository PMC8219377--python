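"""Orchestration of the full familial-risk study.

Given a validated registry and a reference rate table, runs the configured
grid of analyses — familial SIRs for siblings and mothers by proband cancer
type, outcome mode and race/ethnicity; second-primary SIRs; the
SPM-by-familial-risk enrichment test — plus a demographic summary, and
collects every exclusion into a run manifest.

Observed and expected counts for the relative analyses are computed by a
vectorized sweep over all cohorts that is exactly equivalent, window by
window, to :func:`famsir.cohort.build_relative_windows` (the per-cohort
reference implementation; the equivalence is covered by tests).
"""

from __future__ import annotations

import hashlib
import json
from collections import Counter
from dataclasses import dataclass, asdict
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    FamilyCohort,
    MODES,
    adjudicate_spms,
    assign_probands,
    build_spm_windows,
    spm_enrichment_table,
)
from .exposure import AgeIntervalScheme, RateTable, accrue_matrix
from .registry import ICCC3Group, RaceEthnicity, RegistryConfig, Role, classify_hema_solid
from .stats import ComparisonResult, SIRResult, compare_sirs, two_proportion_test

__all__ = [
    "AnalysisSpec",
    "default_grid",
    "run_familial",
    "run_spm",
    "enrichment_summary",
    "compare_across_groups",
    "demographic_summary",
    "results_to_frame",
    "comparisons_to_frame",
    "run_manifest",
]

PROBAND_FILTERS = ("any", "hematologic", "solid") + tuple(g.value for g in ICCC3Group)
POPULATIONS = ("all",) + tuple(r.value for r in RaceEthnicity)

_CATEGORY = {g.value: classify_hema_solid(g).value for g in ICCC3Group}


@dataclass(frozen=True)
class AnalysisSpec:
    """One cell of the analysis grid.

    ``proband_filter`` restricts which families enter by the proband's (or,
    for second-primary analyses, the patient's first-primary) cancer type;
    ``outcome_mode`` defines which relative diagnoses count as events;
    ``population`` restricts to one race/ethnicity stratum;
    ``proband_age_band`` optionally restricts to probands diagnosed within a
    half-open age band ``[lo, hi)``.
    """

    proband_filter: str = "any"
    outcome_mode: str = "any_cancer"
    population: str = "all"
    family: str = "relatives"  # or "spm"
    proband_age_band: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.proband_filter not in PROBAND_FILTERS:
            raise ValueError(f"unknown proband filter {self.proband_filter!r}")
        if self.outcome_mode not in MODES:
            raise ValueError(f"unknown outcome mode {self.outcome_mode!r}")
        if self.population not in POPULATIONS:
            raise ValueError(f"unknown population {self.population!r}")
        if self.family not in ("relatives", "spm"):
            raise ValueError(f"unknown analysis family {self.family!r}")

    @property
    def label(self) -> str:
        band = (
            "" if self.proband_age_band is None
            else f"|age{self.proband_age_band[0]:g}-{self.proband_age_band[1]:g}"
        )
        return f"{self.family}|{self.proband_filter}|{self.outcome_mode}|{self.population}{band}"


def default_grid(family: str = "relatives", modes: Sequence[str] = MODES) -> list[AnalysisSpec]:
    """The standard enumeration: every proband type (pooled, hematologic,
    solid, and each ICCC-3 group) crossed with outcome modes and
    race/ethnicity strata."""
    return [
        AnalysisSpec(pf, mode, pop, family)
        for pf in PROBAND_FILTERS
        for mode in modes
        for pop in POPULATIONS
    ]


def _matches_proband(group: str, proband_filter: str) -> bool:
    if proband_filter == "any":
        return True
    if proband_filter in ("hematologic", "solid"):
        return _CATEGORY[group] == proband_filter
    return group == proband_filter


def _outcome_layer(mode: str, proband_group: str) -> str:
    if mode == "any_cancer":
        return "any"
    if mode == "same_category":
        return _CATEGORY[proband_group]
    return proband_group


def _relative_contributions(
    cohorts: Sequence[FamilyCohort],
    persons: pd.DataFrame,
    events: pd.DataFrame,
    config: RegistryConfig,
    mode: str,
    rates: RateTable,
    scheme: AgeIntervalScheme,
    log: Counter,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-cohort observed and expected counts over relative windows."""
    n_c = len(cohorts)
    O = np.zeros(n_c, dtype=int)
    E = np.zeros(n_c, dtype=float)
    if n_c == 0:
        return O, E

    coh = pd.DataFrame(
        {
            "family_id": [c.family_id for c in cohorts],
            "cidx": np.arange(n_c),
            "proband_id": [c.proband_id for c in cohorts],
            "t": [c.proband_dx_year for c in cohorts],
            "proband_group": [c.proband_group for c in cohorts],
            "race": [c.race_ethnicity for c in cohorts],
        }
    )
    rel = persons.merge(coh, on="family_id")
    rel = rel[rel["person_id"] != rel["proband_id"]].reset_index(drop=True)

    firsts = events.loc[events["sequence"] == 1, ["person_id", "diagnosis_year", "iccc3_group"]]
    rel = rel.merge(firsts, on="person_id", how="left")

    birth = rel["birth_year"].to_numpy()
    born_late = birth > config.study_end_year
    log["born_after_study_end"] += int(born_late.sum())
    rel = rel[~born_late].reset_index(drop=True)
    birth = birth[~born_late]

    cidx = rel["cidx"].to_numpy()
    t = rel["t"].to_numpy()
    start = np.maximum(0.0, (t - birth).astype(float))
    ceiling = np.minimum(
        config.follow_up_age_max, (config.study_end_year - birth).astype(float)
    )
    has_ev = rel["diagnosis_year"].notna().to_numpy()
    dx_age = np.where(has_ev, rel["diagnosis_year"].to_numpy(dtype=float) - birth, np.inf)
    ev_group = rel["iccc3_group"].to_numpy(dtype=object)
    pro_group = rel["proband_group"].to_numpy(dtype=object)

    if mode == "any_cancer":
        qual = has_ev
    elif mode == "same_category":
        qual = has_ev & np.array(
            [has and _CATEGORY[g] == _CATEGORY[p] for has, g, p in zip(has_ev, ev_group, pro_group)]
        )
    elif mode == "same_group":
        qual = has_ev & (ev_group == pro_group)
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")

    pre = has_ev & (dx_age <= start)
    if config.paper_mode:
        deg = pre & qual & (dx_age <= np.minimum(ceiling, config.follow_up_age_max))
        np.add.at(O, cidx[deg], 1)
        log["paper_mode_pre_window_events"] += int(deg.sum())
        log["affected_at_window_start"] += int((pre & ~deg).sum())
    else:
        log["affected_at_window_start"] += int(pre.sum())

    beyond = ~pre & (ceiling <= start)
    log["beyond_follow_up_ceiling"] += int(beyond.sum())
    alive = ~pre & ~beyond

    if config.censor_at_other_cancer:
        in_window_ev = alive & has_ev & (dx_age <= ceiling)
        event = in_window_ev & qual
        censored_other = in_window_ev & ~qual & config.censor_at_other_cancer
        log["censored_at_other_cancer"] += int(censored_other.sum())
        end = np.where(event | censored_other, np.minimum(dx_age, ceiling), ceiling)
    else:
        # follow through non-qualifying cancers to the first qualifying one
        me = events.merge(
            rel[["person_id", "proband_group"]].assign(row=np.arange(len(rel))),
            on="person_id",
        )
        if mode == "any_cancer":
            q = np.ones(len(me), dtype=bool)
        elif mode == "same_category":
            q = np.array(
                [_CATEGORY[g] == _CATEGORY[p]
                 for g, p in zip(me["iccc3_group"], me["proband_group"])]
            )
        else:
            q = (me["iccc3_group"] == me["proband_group"]).to_numpy()
        firstq = (
            me[q].sort_values(["row", "diagnosis_year"], kind="stable")
            .groupby("row", sort=False)
            .head(1)
            .set_index("row")
        )
        dxq_age = np.full(len(rel), np.inf)
        evq_group = np.empty(len(rel), dtype=object)
        idx = firstq.index.to_numpy()
        dxq_age[idx] = firstq["diagnosis_year"].to_numpy(dtype=float) - birth[idx]
        evq_group[idx] = firstq["iccc3_group"].to_numpy(dtype=object)
        event = alive & (dxq_age > start) & (dxq_age <= ceiling)
        end = np.where(event, np.minimum(dxq_age, ceiling), ceiling)

    np.add.at(O, cidx[event], 1)

    py = accrue_matrix(start[alive], end[alive], scheme)
    race = rel["race"].to_numpy(dtype=object)[alive]
    sex = rel["sex"].to_numpy(dtype=object)[alive]
    if mode == "any_cancer":
        outcome = np.full(alive.sum(), "any", dtype=object)
    elif mode == "same_category":
        outcome = np.array([_CATEGORY[p] for p in pro_group[alive]], dtype=object)
    else:
        outcome = pro_group[alive]
    cidx_alive = cidx[alive]
    combos = pd.DataFrame({"race": race, "sex": sex, "outcome": outcome})
    for (r, s, o), idx in combos.groupby(["race", "sex", "outcome"], sort=False).groups.items():
        idx = np.asarray(idx)
        vec = rates.rate_vector(r, s, o, scheme)
        np.add.at(E, cidx_alive[idx], py[idx] @ vec)
    return O, E


def run_familial(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    rates: RateTable,
    config: RegistryConfig,
    grid: Sequence[AnalysisSpec] | None = None,
    alpha: float = 0.05,
) -> tuple[list[SIRResult], dict]:
    """Familial (sibling + mother) SIRs over the analysis grid.

    For each grid cell, observed events are summed over the at-risk windows
    of relatives of the selected probands, expected events come from the
    rate table layer matching the outcome mode, and the interval follows the
    count-dependent method switch.  Cells with zero observed events are
    emitted with a ``not_calculable`` status.  Returns the results and a run
    manifest with exclusion counts.
    """
    if grid is None:
        grid = default_grid("relatives")
    scheme = config.scheme()
    log: Counter = Counter()
    cohorts = assign_probands(persons, events, config)

    modes_needed = sorted({spec.outcome_mode for spec in grid})
    contrib = {
        mode: _relative_contributions(
            cohorts, persons, events, config, mode, rates, scheme, log
        )
        for mode in modes_needed
    }

    birth_of = dict(zip(persons["person_id"], persons["birth_year"]))
    c_group = np.array([c.proband_group for c in cohorts], dtype=object)
    c_cat = np.array([_CATEGORY[c.proband_group] for c in cohorts], dtype=object)
    c_race = np.array([c.race_ethnicity for c in cohorts], dtype=object)
    c_age = np.array(
        [c.proband_dx_year - birth_of[c.proband_id] for c in cohorts], dtype=float
    )

    results = []
    for spec in grid:
        if spec.family != "relatives":
            raise ValueError("run_familial only handles 'relatives' grid cells")
        mask = np.ones(len(cohorts), dtype=bool)
        if spec.proband_filter in ("hematologic", "solid"):
            mask &= c_cat == spec.proband_filter
        elif spec.proband_filter != "any":
            mask &= c_group == spec.proband_filter
        if spec.population != "all":
            mask &= c_race == spec.population
        if spec.proband_age_band is not None:
            lo, hi = spec.proband_age_band
            mask &= (c_age >= lo) & (c_age < hi)
        O_arr, E_arr = contrib[spec.outcome_mode]
        results.append(
            SIRResult.from_counts(spec.label, int(O_arr[mask].sum()), float(E_arr[mask].sum()), alpha)
        )

    manifest = run_manifest(
        config, log, n_families=persons["family_id"].nunique(), n_cohorts=len(cohorts)
    )
    return results, manifest


def run_spm(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    rates: RateTable,
    config: RegistryConfig,
    grid: Sequence[AnalysisSpec] | None = None,
    alpha: float = 0.05,
) -> tuple[list[SIRResult], dict, dict]:
    """Second-primary SIRs plus the familial-risk enrichment test.

    Follow-up for every first-primary child patient starts at that first
    diagnosis; events are adjudicated non-relapse SPMs.  Under
    ``same_category`` mode only SPMs in the first primary's
    hematologic/solid category count as events (the window still closes at
    any SPM) and expected counts use that category's rate layer.  Also
    returns the 2x2 enrichment table with its two-proportion p-value, and
    the run manifest.
    """
    if grid is None:
        grid = default_grid("spm", modes=("any_cancer",))
    scheme = config.scheme()
    log: Counter = Counter()
    windows = build_spm_windows(events, persons, config, log)

    firsts = events[events["sequence"] == 1]
    first_group = dict(zip(firsts["person_id"], firsts["iccc3_group"]))

    # per-window attributes and exposures, computed once
    n_w = len(windows)
    w_group = np.array([first_group[w.person_id] for w in windows], dtype=object)
    w_cat = np.array([_CATEGORY[g] for g in w_group], dtype=object)
    w_race = np.array([w.stratum[0] for w in windows], dtype=object)
    w_sex = np.array([w.stratum[1] for w in windows], dtype=object)
    w_start = np.array([w.start_age for w in windows], dtype=float)
    w_event = np.array([w.event for w in windows], dtype=int)
    w_event_cat = np.array(
        [None if w.event_group is None else _CATEGORY[w.event_group] for w in windows],
        dtype=object,
    )
    py = (
        accrue_matrix(w_start, np.array([w.end_age for w in windows]), scheme)
        if n_w
        else np.zeros((0, scheme.k_max))
    )

    vec_cache: dict[tuple, np.ndarray] = {}

    def e_total(mask: np.ndarray, outcomes: np.ndarray) -> float:
        total = 0.0
        for i in np.flatnonzero(mask):
            key = (w_race[i], w_sex[i], outcomes[i])
            if key not in vec_cache:
                vec_cache[key] = rates.rate_vector(*key, scheme)
            total += float(vec_cache[key] @ py[i])
        return total

    results = []
    for spec in grid:
        if spec.family != "spm":
            raise ValueError("run_spm only handles 'spm' grid cells")
        if spec.outcome_mode == "same_group":
            raise ValueError("same_group outcome is not defined for the SPM analysis")
        mask = np.ones(n_w, dtype=bool)
        if spec.proband_filter in ("hematologic", "solid"):
            mask &= w_cat == spec.proband_filter
        elif spec.proband_filter != "any":
            mask &= w_group == spec.proband_filter
        if spec.population != "all":
            mask &= w_race == spec.population
        if spec.proband_age_band is not None:
            lo, hi = spec.proband_age_band
            mask &= (w_start >= lo) & (w_start < hi)
        if spec.outcome_mode == "same_category":
            ev = w_event & np.array(
                [c is not None and c == k for c, k in zip(w_event_cat, w_cat)], dtype=int
            )
            outcomes = w_cat
        else:
            ev = w_event
            outcomes = np.full(n_w, "any", dtype=object)
        O = int(ev[mask].sum())
        E = e_total(mask, outcomes)
        results.append(SIRResult.from_counts(spec.label, O, E, alpha))

    enrichment = enrichment_summary(*spm_enrichment_table(persons, events, config))
    manifest = run_manifest(config, log, n_first_primaries=n_w)
    return results, enrichment, manifest


def enrichment_summary(x1: int, n1: int, x2: int, n2: int) -> dict:
    """SPM proportions by family-risk status with the two-proportion test."""
    return {
        "spm_in_familial_risk_families": x1,
        "members_in_familial_risk_families": n1,
        "spm_in_other_families": x2,
        "members_in_other_families": n2,
        "percent_familial_risk": round(100 * x1 / n1, 2) if n1 else None,
        "percent_other": round(100 * x2 / n2, 2) if n2 else None,
        "p_value": two_proportion_test(x1, n1, x2, n2) if n1 and n2 and x1 + x2 > 0 else None,
    }


def compare_across_groups(
    results: Iterable[SIRResult],
    pairs: Sequence[tuple[str, str]],
    method: str = "chi_square_approx",
) -> list[ComparisonResult]:
    """Pairwise SIR comparisons between named result cells.

    Pairs with a non-calculable member are skipped.  Output order follows
    the input pairs.
    """
    by_label = {r.label: r for r in results}
    out = []
    for l1, l2 in pairs:
        r1, r2 = by_label[l1], by_label[l2]
        if r1.status != "ok" or r2.status != "ok":
            continue
        out.append(
            compare_sirs(r1.O, r1.E, r2.O, r2.E, method=method, label1=l1, label2=l2)
        )
    return out


#: Age bands used in the demographic summary (diagnosis age; 20+ open-ended).
SUMMARY_AGE_BANDS = ((0, 1), (1, 5), (5, 10), (10, 15), (15, 20), (20, np.inf))


def demographic_summary(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    config: RegistryConfig,
) -> pd.DataFrame:
    """Counts and percentages by diagnosis-age band, sex and race/ethnicity
    for probands, affected siblings, affected mothers and second primaries.

    Returns a tidy frame with columns ``column, section, category, count,
    percent``; within each (column, section) the counts partition the
    column total and the percentages sum to 100 up to rounding.
    """
    cohorts = assign_probands(persons, events, config)
    proband_ids = {c.proband_id for c in cohorts}
    pinfo = persons.set_index("person_id")

    firsts = events[events["sequence"] == 1].merge(
        persons[["person_id", "role", "sex", "family_id", "birth_year"]], on="person_id"
    )
    firsts["dx_age"] = firsts["diagnosis_year"] - firsts["birth_year"]

    from .cohort import family_race_map

    races = family_race_map(persons)
    firsts["race"] = firsts["family_id"].map(races)

    cols: dict[str, pd.DataFrame] = {}
    kids = firsts[firsts["role"] == Role.child.value]
    cols["probands"] = kids[kids["person_id"].isin(proband_ids)]
    cols["affected_siblings"] = kids[~kids["person_id"].isin(proband_ids)]
    cols["affected_mothers"] = firsts[firsts["role"] == Role.mother.value]

    spms = [r for r in adjudicate_spms(events, config) if not r.relapse_flag]
    if spms:
        spm_df = pd.DataFrame(
            {
                "person_id": [r.person_id for r in spms],
                "dx_age": [
                    r.second_dx_year - int(pinfo.loc[r.person_id, "birth_year"]) for r in spms
                ],
                "sex": [pinfo.loc[r.person_id, "sex"] for r in spms],
                "race": [races[pinfo.loc[r.person_id, "family_id"]] for r in spms],
            }
        )
    else:
        spm_df = pd.DataFrame(columns=["person_id", "dx_age", "sex", "race"])
    cols["second_primaries"] = spm_df

    rows = []
    for column, df in cols.items():
        total = len(df)

        def add(section: str, category: str, count: int) -> None:
            pct = round(100 * count / total, 2) if total else 0.0
            rows.append((column, section, category, count, pct))

        add("total", "all", total)
        for lo, hi in SUMMARY_AGE_BANDS:
            label = f"{lo:g}+" if not np.isfinite(hi) else (
                f"{lo:g}" if hi - lo == 1 else f"{lo:g}-{hi - 1:g}"
            )
            n = int(((df["dx_age"] >= lo) & (df["dx_age"] < hi)).sum()) if total else 0
            add("age_at_diagnosis", label, n)
        for sex in ("male", "female"):
            add("sex", sex, int((df["sex"] == sex).sum()) if total else 0)
        for race in (r.value for r in RaceEthnicity):
            add("race_ethnicity", race, int((df["race"] == race).sum()) if total else 0)

    return pd.DataFrame(rows, columns=["column", "section", "category", "count", "percent"])


# ---------------------------------------------------------------------------
# Serialization helpers


def results_to_frame(results: Iterable[SIRResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "label": r.label,
                "O": r.O,
                "E": r.E,
                "sir": r.sir,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "ci_method": r.ci_method.value if r.ci_method else None,
                "alpha": r.alpha,
                "status": r.status,
            }
            for r in results
        ]
    )


def comparisons_to_frame(comparisons: Iterable[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(c) for c in comparisons])


def run_manifest(config: RegistryConfig, log: Counter, **extra) -> dict:
    """Reproducibility record: package version, config hash, exclusions."""
    from . import __version__

    cfg = asdict(config)
    cfg["age_breaks"] = list(cfg["age_breaks"])
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()[:16]
    return {
        "famsir_version": __version__,
        "config": cfg,
        "config_hash": digest,
        "exclusions": dict(log),
        **extra,
    }
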