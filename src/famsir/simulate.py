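"""Synthetic linked-registry generator.

Emulates the structure the analysis assumes — families of one mother plus
one to four children, five race/ethnicity strata with a California-like
mixture, piecewise-constant baseline incidence, a familial hazard multiplier
switched on at the first diagnosis in a family, and a second-primary hazard
multiplier after a first primary — so that every pipeline stage is testable
without external data and the true parameters are recoverable.

Familial dependence is a conditional multiplier theta applied to surviving
relatives' hazards from the family's first diagnosis year onward.  Because
relatives' at-risk windows start exactly there, the true relative SIR equals
theta by construction, making it a clean recovery target.  Likewise the
distinct-second-primary hazard is exactly phi times baseline, so the true
SPM SIR is phi.  Planted relapses — events copying the first primary's
group and subtype — occur on top of that as a fraction ``relapse_rate`` of
all post-first-primary events; they neither remove the patient from
distinct-SPM risk nor alter the phi target, mirroring how the analysis
treats an adjudicated relapse.  A mean-one gamma frailty shared within the
family is available behind ``frailty_shape`` as a robustness alternative.

Two sampling frames are supported.  The default draws a general population
of families.  With ``ascertained=True`` the generator instead emulates a
proband-linked registry — the frame the analysis actually consumes, where
every family contains a cancer proband — by simulating population families
in batches and retaining the first ``n_families`` that acquire an affected
child.  Ascertainment conditions only on the proband's occurrence, so the
relatives' post-diagnosis relative risk is still exactly theta.

Event times are drawn year by year (one Bernoulli trial per person-year at
probability 1 - exp(-hazard)) and recorded as calendar years, matching the
registry dialect and the mid-year convention downstream.  The generator also
emits its exact baseline rate table so SIR analyses can standardize against
truth rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .exposure import AgeIntervalScheme, RateTable
from .registry import ICCC3Group, RaceEthnicity, RegistryConfig, classify_hema_solid

__all__ = ["SimulationParams", "SimulatedRegistry", "simulate", "expected_event_count"]

#: Approximate relative frequencies of the 12 ICCC-3 main groups among
#: early-onset cancers (leukemias most common, CNS tumors second).
DEFAULT_GROUP_WEIGHTS: dict[str, float] = {
    "I": 0.27, "II": 0.11, "III": 0.17, "IV": 0.05, "V": 0.02, "VI": 0.04,
    "VII": 0.01, "VIII": 0.05, "IX": 0.07, "X": 0.07, "XI": 0.12, "XII": 0.02,
}

#: California-like family race/ethnicity mixture.
DEFAULT_RACE_MIXTURE: dict[str, float] = {
    "latino": 0.45, "nl_white": 0.38, "nl_black": 0.06, "nl_api": 0.09, "other": 0.02,
}

#: Children per family (mean 2.0).
DEFAULT_CHILDREN_DIST: dict[int, float] = {1: 0.38, 2: 0.34, 3: 0.18, 4: 0.10}

_ASCERTAIN_BATCH = 250_000


@dataclass(frozen=True)
class SimulationParams:
    """Generator knobs; the defaults are the reference study conditions.

    ``baseline_rate`` is the flat "any first primary" hazard per person-year
    (default 20 per 100,000).  ``theta`` (familial multiplier, default 3.32)
    may be a single ratio or a mapping from race/ethnicity token to ratio;
    ``phi`` multiplies the baseline for distinct second primaries (default
    7.27).  ``relapse_rate`` is the fraction of post-first-primary events
    planted as relapses.  With ``ascertained=True``, ``n_families`` counts
    proband families.
    """

    n_families: int = 1000
    children_dist: dict = field(default_factory=lambda: dict(DEFAULT_CHILDREN_DIST))
    race_mixture: dict = field(default_factory=lambda: dict(DEFAULT_RACE_MIXTURE))
    birth_year_range: tuple = (1989, 2015)
    baseline_rate: float = 20e-5
    theta: float | dict = 3.32
    phi: float = 7.27
    relapse_rate: float = 0.15
    group_weights: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_WEIGHTS))
    frailty_shape: Optional[float] = None
    ascertained: bool = False
    seed: int = 0
    config: RegistryConfig = field(default_factory=RegistryConfig)

    def __post_init__(self) -> None:
        if self.n_families < 1:
            raise ValueError("n_families must be positive")
        for name, dist in (
            ("children_dist", self.children_dist),
            ("race_mixture", self.race_mixture),
            ("group_weights", self.group_weights),
        ):
            vals = np.asarray(list(dist.values()), float)
            if len(vals) == 0 or (vals < 0).any() or not np.isclose(vals.sum(), 1.0):
                raise ValueError(f"{name} must be non-negative and sum to 1")
        thetas = self.theta.values() if isinstance(self.theta, dict) else [self.theta]
        if any(t < 0 for t in thetas) or self.phi < 0 or self.baseline_rate < 0:
            raise ValueError("hazards and multipliers must be non-negative")
        if not 0 <= self.relapse_rate < 1:
            raise ValueError("relapse_rate must be in [0, 1)")

    def theta_for(self, race: str) -> float:
        if isinstance(self.theta, dict):
            return float(self.theta[race])
        return float(self.theta)


@dataclass
class SimulatedRegistry:
    persons: pd.DataFrame
    events: pd.DataFrame
    rates: RateTable
    params: SimulationParams


def _truth_rate_table(params: SimulationParams, scheme: AgeIntervalScheme) -> RateTable:
    """All outcome layers implied by the flat baseline and group mixture."""
    lam = params.baseline_rate
    w = params.group_weights
    layers = {"any": 1.0}
    layers.update({g: w.get(g, 0.0) for g in (x.value for x in ICCC3Group)})
    layers["hematologic"] = sum(
        w.get(g.value, 0.0) for g in ICCC3Group if classify_hema_solid(g).value == "hematologic"
    )
    layers["solid"] = sum(
        w.get(g.value, 0.0) for g in ICCC3Group if classify_hema_solid(g).value == "solid"
    )
    rows = []
    for race in RaceEthnicity:
        for sex in ("male", "female"):
            for lo, hi in zip(scheme.lowers, scheme.uppers):
                for outcome, frac in layers.items():
                    rows.append((race.value, sex, lo, hi, outcome, lam * frac))
    return RateTable(
        pd.DataFrame(rows, columns=["race_ethnicity", "sex", "age_lo", "age_hi", "outcome", "rate"])
    )


def _simulate_arrays(params: SimulationParams, rng: np.random.Generator, n_families: int) -> dict:
    """One vectorized population draw; returns raw per-person arrays."""
    cfg = params.config
    b0, b1 = params.birth_year_range

    kid_counts = rng.choice(
        list(params.children_dist), size=n_families, p=list(params.children_dist.values())
    )
    fam_race = rng.choice(
        list(params.race_mixture), size=n_families, p=list(params.race_mixture.values())
    )
    n_kids = int(kid_counts.sum())
    kid_fam = np.repeat(np.arange(n_families), kid_counts)
    kid_birth = rng.integers(b0, b1 + 1, size=n_kids)
    first_child_birth = np.full(n_families, b1, dtype=int)
    np.minimum.at(first_child_birth, kid_fam, kid_birth)
    # maternal age at first recorded birth uniform on 15..45
    mom_birth = first_child_birth - rng.integers(15, 46, size=n_families)

    n = n_kids + n_families
    fam_idx = np.concatenate([kid_fam, np.arange(n_families)])
    birth = np.concatenate([kid_birth, mom_birth])
    is_mother = np.concatenate([np.zeros(n_kids, bool), np.ones(n_families, bool)])
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    sex[is_mother] = "female"

    theta_p = np.array([params.theta_for(r) for r in fam_race])[fam_idx]
    if params.frailty_shape is not None:
        a = params.frailty_shape
        frailty = rng.gamma(a, 1.0 / a, size=n_families)[fam_idx]
    else:
        frailty = np.ones(n)

    lam = params.baseline_rate
    upper = min(cfg.follow_up_age_max, cfg.scheme().upper)
    affected = np.zeros(n, bool)
    dx_year = np.zeros(n, int)
    distinct = np.zeros(n, bool)
    distinct_year = np.zeros(n, int)
    relapse_person: list[int] = []
    relapse_year: list[int] = []
    fam_active = np.full(n_families, np.iinfo(np.int32).max, dtype=np.int64)

    # total post-first-primary event hazard, of which a relapse_rate share
    # are planted relapses, leaving the distinct-SPM hazard at exactly
    # phi * baseline (to first order in the yearly probability)
    h_second = lam * params.phi / (1.0 - params.relapse_rate)

    for year in range(cfg.study_start_year, cfg.study_end_year + 1):
        age = year - birth
        in_age = (age >= 0) & (age < upper)

        at_risk = ~affected & in_age
        mult = np.where(fam_active[fam_idx] < year, theta_p, 1.0) * frailty
        p_first = -np.expm1(-lam * mult)
        hit = at_risk & (rng.random(n) < p_first)
        if hit.any():
            dx_year[hit] = year
            affected[hit] = True
            np.minimum.at(fam_active, fam_idx[hit], year)

        spm_risk = affected & ~distinct & ~is_mother & (dx_year < year) & in_age
        p_spm = -np.expm1(-h_second * frailty)
        hit2 = np.flatnonzero(spm_risk & (rng.random(n) < p_spm))
        if len(hit2):
            is_rel = rng.random(len(hit2)) < params.relapse_rate
            relapse_person.extend(hit2[is_rel].tolist())
            relapse_year.extend([year] * int(is_rel.sum()))
            d = hit2[~is_rel]
            distinct[d] = True
            distinct_year[d] = year

    groups = np.array(list(params.group_weights))
    gw = np.asarray(list(params.group_weights.values()), float)
    first_group = rng.choice(groups, size=n, p=gw)
    first_sub = np.char.add(first_group.astype(str), np.where(rng.random(n) < 0.5, "_a", "_b"))

    # a distinct SPM draws its group from the mixture excluding the first
    # primary's group; planted relapses copy group and subtype exactly
    distinct_group = np.empty(n, dtype="<U4")
    distinct_sub = np.empty(n, dtype="<U8")
    for i in np.flatnonzero(distinct):
        keep = groups != first_group[i]
        wts = gw[keep] / gw[keep].sum()
        distinct_group[i] = rng.choice(groups[keep], p=wts)
        distinct_sub[i] = distinct_group[i] + ("_a" if rng.random() < 0.5 else "_b")

    return {
        "fam_idx": fam_idx,
        "fam_race": fam_race,
        "birth": birth,
        "is_mother": is_mother,
        "sex": sex,
        "affected": affected,
        "dx_year": dx_year,
        "first_group": first_group,
        "first_sub": first_sub,
        "distinct": distinct,
        "distinct_year": distinct_year,
        "distinct_group": distinct_group,
        "distinct_sub": distinct_sub,
        "relapse_person": np.asarray(relapse_person, dtype=int),
        "relapse_year": np.asarray(relapse_year, dtype=int),
        "n_families": n_families,
    }


def _assemble(arr: dict, fam_offset: int, person_offset: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    n = len(arr["birth"])
    person_id = np.array([f"p{i:08d}" for i in range(person_offset, person_offset + n)])
    family_label = np.array(
        [f"f{i:07d}" for i in range(fam_offset, fam_offset + arr["n_families"])]
    )
    persons = pd.DataFrame(
        {
            "person_id": person_id,
            "family_id": family_label[arr["fam_idx"]],
            "role": np.where(arr["is_mother"], "mother", "child"),
            "sex": arr["sex"],
            "race_ethnicity": arr["fam_race"][arr["fam_idx"]],
            "birth_year": arr["birth"],
        }
    )

    aff = arr["affected"]
    e1 = pd.DataFrame(
        {
            "person_id": person_id[aff],
            "diagnosis_year": arr["dx_year"][aff],
            "iccc3_group": arr["first_group"][aff],
            "subtype_label": arr["first_sub"][aff],
        }
    )
    dis = arr["distinct"]
    e2 = pd.DataFrame(
        {
            "person_id": person_id[dis],
            "diagnosis_year": arr["distinct_year"][dis],
            "iccc3_group": arr["distinct_group"][dis],
            "subtype_label": arr["distinct_sub"][dis],
        }
    )
    rp = arr["relapse_person"]
    e3 = pd.DataFrame(
        {
            "person_id": person_id[rp],
            "diagnosis_year": arr["relapse_year"],
            "iccc3_group": arr["first_group"][rp],
            "subtype_label": arr["first_sub"][rp],
        }
    )
    events = (
        pd.concat([e1, e2, e3], ignore_index=True)
        .sort_values(["person_id", "diagnosis_year"], kind="stable")
        .reset_index(drop=True)
    )
    events["sequence"] = events.groupby("person_id", sort=False).cumcount() + 1
    return persons, events


def _filter_families(arr: dict, keep_fams: np.ndarray) -> dict:
    """Restrict a raw draw to a subset of family indices (renumbered)."""
    mask = np.isin(arr["fam_idx"], keep_fams)
    remap = {old: new for new, old in enumerate(np.sort(keep_fams))}
    kept_persons = np.flatnonzero(mask)
    old_to_new_person = np.full(len(arr["birth"]), -1, dtype=int)
    old_to_new_person[kept_persons] = np.arange(len(kept_persons))

    out = {
        "fam_idx": np.array([remap[f] for f in arr["fam_idx"][mask]]),
        "fam_race": arr["fam_race"][np.sort(keep_fams)],
        "n_families": len(keep_fams),
    }
    for key in (
        "birth", "is_mother", "sex", "affected", "dx_year",
        "first_group", "first_sub", "distinct", "distinct_year",
        "distinct_group", "distinct_sub",
    ):
        out[key] = arr[key][mask]
    rel_keep = np.isin(arr["relapse_person"], kept_persons)
    out["relapse_person"] = old_to_new_person[arr["relapse_person"][rel_keep]]
    out["relapse_year"] = arr["relapse_year"][rel_keep]
    return out


def simulate(params: SimulationParams) -> SimulatedRegistry:
    """Draw a full registry (persons, events, truth rates) from the model.

    Identical parameters (including seed) give byte-identical tables.
    """
    rng = np.random.default_rng(params.seed)
    if not params.ascertained:
        arr = _simulate_arrays(params, rng, params.n_families)
        persons, events = _assemble(arr, 0, 0)
    else:
        frames, collected = [], 0
        fam_offset = person_offset = 0
        while collected < params.n_families:
            arr = _simulate_arrays(params, rng, _ASCERTAIN_BATCH)
            fam_has_proband = np.zeros(arr["n_families"], bool)
            kid_cases = arr["affected"] & ~arr["is_mother"]
            fam_has_proband[arr["fam_idx"][kid_cases]] = True
            fams = np.flatnonzero(fam_has_proband)[: params.n_families - collected]
            if len(fams):
                sub = _filter_families(arr, fams)
                frames.append(_assemble(sub, fam_offset, person_offset))
                fam_offset += sub["n_families"]
                person_offset += len(sub["birth"])
                collected += len(fams)
        persons = pd.concat([p for p, _ in frames], ignore_index=True)
        events = pd.concat([e for _, e in frames], ignore_index=True)

    return SimulatedRegistry(
        persons=persons,
        events=events,
        rates=_truth_rate_table(params, params.config.scheme()),
        params=params,
    )


def expected_event_count(params: SimulationParams) -> float:
    """Closed-form expectation of first-primary events in the population
    sampling frame, ignoring the familial feedback (valid in the
    rare-disease regime).

    Sums, over the discrete birth-year distributions of children and
    mothers, the number of at-risk person-year slots inside the study window
    and under the age ceiling, times the per-year event probability
    ``1 - exp(-baseline)``.  Not defined for ascertained sampling, whose
    event count is conditioned on by construction.
    """
    if params.ascertained:
        raise ValueError("expected_event_count applies to the population frame only")
    cfg = params.config
    upper = min(cfg.follow_up_age_max, cfg.scheme().upper)
    p_year = -np.expm1(-params.baseline_rate)

    def slots(birth_years: np.ndarray, probs: np.ndarray) -> float:
        lo = np.maximum(birth_years, cfg.study_start_year)
        hi = np.minimum(cfg.study_end_year, birth_years + int(upper) - 1)
        return float(probs @ np.maximum(0, hi - lo + 1))

    b0, b1 = params.birth_year_range
    births = np.arange(b0, b1 + 1)
    uniform = np.full(len(births), 1.0 / len(births))
    mean_children = sum(k * p for k, p in params.children_dist.items())
    e_children = params.n_families * mean_children * slots(births, uniform) * p_year

    # distribution of the earliest birth among c iid uniform children
    n_years = len(births)
    cdf = np.arange(1, n_years + 1) / n_years  # P(one child's birth <= b)
    pmin = np.zeros(n_years)
    for c, pc in params.children_dist.items():
        surv_hi = (1 - cdf) ** c
        surv_lo = np.concatenate([[1.0], surv_hi[:-1]])
        pmin += pc * (surv_lo - surv_hi)
    # mother birth = first birth - U{15..45}
    mom_births, mom_probs = [], []
    for b, pb in zip(births, pmin):
        for gap in range(15, 46):
            mom_births.append(b - gap)
            mom_probs.append(pb / 31.0)
    e_mothers = params.n_families * slots(np.array(mom_births), np.array(mom_probs)) * p_year

    return e_children + e_mothers
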