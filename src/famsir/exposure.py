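"""Stratified person-time accrual and expected event counts.

Indirect standardization needs, for every at-risk window, the person-years
spent in each reference age interval, and a reference rate table lambda_k
indexed by (race/ethnicity, sex, age interval, outcome).  The expected count
is then E = sum over persons and intervals of lambda_k * t_k, the denominator
of the standardized incidence ratio O/E.

All ages are derived under the mid-year convention: every event is placed at
the middle of its calendar year, so age at an event is exactly
``event_year - birth_year`` and all window endpoints are whole numbers of
years (fractional endpoints are still accepted and split exactly).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import RaceEthnicity, Sex, classify_hema_solid, ICCC3Group

__all__ = [
    "AgeIntervalScheme",
    "DEFAULT_SCHEME",
    "ExposureVector",
    "RateTable",
    "CoverageError",
    "mid_year_age",
    "accrue",
    "accrue_matrix",
    "expected_count",
    "rates_from_population",
]

#: Outcome layers understood by rate tables: any first primary, the
#: hematologic/solid dichotomy, or a single ICCC-3 main group.
VALID_OUTCOMES = frozenset({"any", "hematologic", "solid"} | {g.value for g in ICCC3Group})


class CoverageError(Exception):
    """A rate table does not cover a stratum/interval that a window touches."""


@dataclass(frozen=True)
class AgeIntervalScheme:
    """Ordered, contiguous, half-open age intervals ``[b_k, b_{k+1})``.

    The default reference scheme has seven intervals — an infant interval
    [0,1) followed by [1,5), [5,10), [10,15), [15,20), [20,25), [25,30) —
    mirroring the age strata 0, 1-4, 5-9, 10-14, 15-19, 20-24, 25-29.
    """

    breaks: tuple = (0, 1, 5, 10, 15, 20, 25, 30)

    def __post_init__(self) -> None:
        b = np.asarray(self.breaks, dtype=float)
        if len(b) < 2 or b[0] != 0:
            raise ValueError("age breaks must start at 0 and define >=1 interval")
        if not np.all(np.diff(b) > 0):
            raise ValueError("age breaks must be strictly increasing")

    @property
    def k_max(self) -> int:
        return len(self.breaks) - 1

    @property
    def upper(self) -> float:
        return float(self.breaks[-1])

    @property
    def lowers(self) -> np.ndarray:
        return np.asarray(self.breaks[:-1], dtype=float)

    @property
    def uppers(self) -> np.ndarray:
        return np.asarray(self.breaks[1:], dtype=float)

    def labels(self) -> list[str]:
        out = []
        for lo, hi in zip(self.lowers, self.uppers):
            if hi - lo == 1:
                out.append(f"{lo:g}")
            else:
                out.append(f"{lo:g}-{hi - 1:g}")
        return out

    def interval_of(self, age: float) -> int:
        """Index of the interval containing ``age`` (right-open convention)."""
        if age < 0 or age >= self.upper:
            raise ValueError(f"age {age} outside scheme coverage [0, {self.upper})")
        return int(np.searchsorted(np.asarray(self.breaks, float), age, side="right") - 1)


DEFAULT_SCHEME = AgeIntervalScheme()


@dataclass(frozen=True)
class ExposureVector:
    """Person-years by age interval for one at-risk window."""

    person_id: str
    t: np.ndarray
    stratum: tuple  # (race_ethnicity token, sex token)

    def total(self) -> float:
        return float(self.t.sum())


def mid_year_age(birth_year: int, event_year: int) -> float:
    """Age at an event under the mid-year convention.

    Both years collapse to July 1, so the age is exactly the difference of
    calendar years, a whole number.
    """
    if event_year < birth_year:
        raise ValueError(f"event year {event_year} precedes birth year {birth_year}")
    return float(event_year - birth_year)


def accrue_matrix(
    start: np.ndarray, end: np.ndarray, scheme: AgeIntervalScheme = DEFAULT_SCHEME
) -> np.ndarray:
    """Vectorized interval split: rows are windows, columns age intervals.

    Each window [start, end) is intersected with every scheme interval; row
    sums equal ``end - start`` exactly (a conservation property the tests
    check against a fine-step integrator).
    """
    start = np.asarray(start, dtype=float)[:, None]
    end = np.asarray(end, dtype=float)[:, None]
    lo = scheme.lowers[None, :]
    hi = scheme.uppers[None, :]
    return np.clip(np.minimum(end, hi) - np.maximum(start, lo), 0.0, None)


def accrue(window, scheme: AgeIntervalScheme = DEFAULT_SCHEME) -> ExposureVector:
    """Split one at-risk window's follow-up across the scheme's intervals."""
    if window.end_age < window.start_age:
        raise ValueError(f"window for {window.person_id} has end before start")
    if window.end_age > scheme.upper + 1e-9:
        raise CoverageError(
            f"window for person {window.person_id} ends at age {window.end_age}, "
            f"beyond scheme coverage [0, {scheme.upper})"
        )
    t = accrue_matrix(
        np.array([window.start_age]), np.array([window.end_age]), scheme
    )[0]
    return ExposureVector(person_id=window.person_id, t=t, stratum=window.stratum)


class RateTable:
    """Reference incidence rates per person-year by race, sex, age interval
    and outcome layer.

    The canonical frame has columns ``race_ethnicity, sex, age_lo, age_hi,
    outcome, rate`` with rates per person-year.  Files may instead declare
    ``unit = per_100k_py``; rates are converted on read.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"race_ethnicity", "sex", "age_lo", "age_hi", "outcome", "rate"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"rate table missing columns: {sorted(missing)}")
        frame = frame.copy()
        if (frame["rate"] < 0).any():
            raise ValueError("rates must be non-negative")
        bad = set(frame["outcome"]) - VALID_OUTCOMES
        if bad:
            raise ValueError(f"unknown outcome layers: {sorted(bad)}")
        self.frame = frame.reset_index(drop=True)
        self._index: dict[tuple, float] = {
            (r.race_ethnicity, r.sex, float(r.age_lo), float(r.age_hi), r.outcome): float(r.rate)
            for r in frame.itertuples(index=False)
        }

    @classmethod
    def from_file(cls, path: str | Path) -> "RateTable":
        frame = pd.read_csv(path, sep=None, engine="python")
        if "unit" in frame.columns:
            per100k = (frame["unit"] == "per_100k_py").to_numpy()
            frame["rate"] = np.where(per100k, frame["rate"] / 1e5, frame["rate"])
            frame = frame.drop(columns=["unit"])
        return cls(frame)

    def to_file(self, path: str | Path) -> None:
        out = self.frame.copy()
        out["unit"] = "per_person_year"
        out.to_csv(path, index=False)

    @classmethod
    def flat(
        cls,
        rate: float,
        scheme: AgeIntervalScheme = DEFAULT_SCHEME,
        outcomes: Sequence[str] = ("any",),
    ) -> "RateTable":
        """A rate table constant across race, sex and age (testing aid)."""
        rows = []
        for race in RaceEthnicity:
            for sex in Sex:
                for lo, hi in zip(scheme.lowers, scheme.uppers):
                    for outcome in outcomes:
                        rows.append((race.value, sex.value, lo, hi, outcome, rate))
        return cls(
            pd.DataFrame(
                rows,
                columns=["race_ethnicity", "sex", "age_lo", "age_hi", "outcome", "rate"],
            )
        )

    def rate_vector(
        self, race: str, sex: str, outcome: str, scheme: AgeIntervalScheme = DEFAULT_SCHEME
    ) -> np.ndarray:
        """Rates for one (race, sex, outcome) across the scheme's intervals.

        Raises :class:`CoverageError` when any interval is missing; a rate of
        zero must be stated explicitly, never implied by absence.
        """
        out = np.empty(scheme.k_max)
        for k, (lo, hi) in enumerate(zip(scheme.lowers, scheme.uppers)):
            key = (race, sex, float(lo), float(hi), outcome)
            if key not in self._index:
                raise CoverageError(
                    f"no reference rate for stratum ({race}, {sex}), "
                    f"age [{lo:g}, {hi:g}), outcome {outcome!r}"
                )
            out[k] = self._index[key]
        return out

    def scaled(self, factor: float) -> "RateTable":
        frame = self.frame.copy()
        frame["rate"] = frame["rate"] * factor
        return RateTable(frame)


def expected_count(
    exposures: Iterable[ExposureVector],
    rates: RateTable,
    outcome: str = "any",
    scheme: AgeIntervalScheme = DEFAULT_SCHEME,
) -> float:
    """Expected events E = sum over persons and intervals of rate * exposure.

    Linear in both the rates and the exposure; raises
    :class:`CoverageError` (never silently zero) when the table lacks a
    touched stratum.
    """
    total = 0.0
    cache: dict[tuple, np.ndarray] = {}
    for ev in exposures:
        key = (*ev.stratum, outcome)
        if key not in cache:
            cache[key] = rates.rate_vector(ev.stratum[0], ev.stratum[1], outcome, scheme)
        total += float(cache[key] @ ev.t)
    return total


def rates_from_population(
    persons: pd.DataFrame,
    events: pd.DataFrame,
    scheme: AgeIntervalScheme = DEFAULT_SCHEME,
    outcome: str = "any",
    *,
    study_start_year: int,
    study_end_year: int,
) -> RateTable:
    """Estimate reference rates from a whole registry population.

    Each person contributes one person-year per calendar year observed
    (birth or study start through study end) while under the scheme's age
    ceiling; first primaries matching ``outcome`` are the numerators.  Cells
    with zero person-time raise an error listing the offending cells.
    """
    birth = persons["birth_year"].to_numpy()
    start_age = np.maximum(0.0, float(study_start_year) - birth)
    end_age = np.minimum(scheme.upper, float(study_end_year) + 1.0 - birth)
    keep = end_age > start_age
    py = accrue_matrix(start_age[keep], end_age[keep], scheme)

    pt = pd.DataFrame(py, columns=range(scheme.k_max))
    pt["race_ethnicity"] = persons["race_ethnicity"].to_numpy()[keep]
    pt["sex"] = persons["sex"].to_numpy()[keep]
    denom = pt.groupby(["race_ethnicity", "sex"], sort=True).sum()

    firsts = events[events["sequence"] == 1].merge(
        persons[["person_id", "race_ethnicity", "sex", "birth_year"]], on="person_id"
    )
    if outcome == "any":
        sel = firsts
    elif outcome in ("hematologic", "solid"):
        cat = firsts["iccc3_group"].map(lambda g: classify_hema_solid(g).value)
        sel = firsts[cat == outcome]
    else:
        sel = firsts[firsts["iccc3_group"] == outcome]
    age = (sel["diagnosis_year"] - sel["birth_year"]).astype(float)
    in_range = (age >= 0) & (age < scheme.upper)
    sel = sel[in_range]
    kidx = np.searchsorted(np.asarray(scheme.breaks, float), age[in_range], side="right") - 1
    num = (
        pd.DataFrame(
            {
                "race_ethnicity": sel["race_ethnicity"].to_numpy(),
                "sex": sel["sex"].to_numpy(),
                "k": kidx,
            }
        )
        .groupby(["race_ethnicity", "sex", "k"])
        .size()
    )

    rows, empty = [], []
    for (race, sex), pys in denom.iterrows():
        for k in range(scheme.k_max):
            t = float(pys[k])
            if t <= 0:
                empty.append((race, sex, scheme.labels()[k]))
                continue
            o = float(num.get((race, sex, k), 0))
            rows.append(
                (race, sex, scheme.lowers[k], scheme.uppers[k], outcome, o / t)
            )
    if empty:
        raise CoverageError(f"population cells with zero person-time: {empty[:10]}")
    return RateTable(
        pd.DataFrame(
            rows, columns=["race_ethnicity", "sex", "age_lo", "age_hi", "outcome", "rate"]
        )
    )
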