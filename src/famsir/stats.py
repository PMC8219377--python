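"""Standardized incidence ratio estimation and inference.

The SIR is the ratio O/E of observed events to the count expected under
reference rates applied to the cohort's stratified person-time.  Confidence
intervals treat O as Poisson: exact limits invert the Poisson tail
probabilities (equivalently chi-square quantiles) and are used for fewer
than 100 observed events; for 100 or more, Byar's cube-root normal
approximation to the exact limits is used, which agrees with them to well
under 1% there.

Two SIRs sharing reference rates are compared conditionally: given the total
n = O1 + O2, under equal SIRs O1 is binomial with success probability
pi0 = E1/(E1+E2).  The exact test sums the binomial outcome probabilities no
larger than the observed one (minimum-likelihood two-sided); the chi-square
approximation scores the same null on one degree of freedom.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

__all__ = [
    "CIMethod",
    "SIRResult",
    "ComparisonResult",
    "NonCalculableError",
    "sir_point",
    "exact_poisson_ci",
    "byar_ci",
    "ci_auto",
    "compare_sirs",
    "two_proportion_test",
]

#: Observed-count threshold at and above which Byar's approximation replaces
#: the exact Poisson limits.
BYAR_THRESHOLD = 100


class CIMethod(str, enum.Enum):
    exact_poisson = "exact_poisson"
    byar = "byar"


class NonCalculableError(ValueError):
    """SIR undefined: no expected events in the cell."""


@dataclass(frozen=True)
class SIRResult:
    label: str
    O: int
    E: float
    sir: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    ci_method: Optional[CIMethod]
    alpha: float = 0.05
    status: str = "ok"  # or "not_calculable"

    @classmethod
    def from_counts(cls, label: str, O: int, E: float, alpha: float = 0.05) -> "SIRResult":
        """Build a full result; cells with no observed or expected events are
        emitted with a sentinel status rather than dropped."""
        if E <= 0 or O == 0:
            lo_hi = None
            if E > 0:
                low, high, method = ci_auto(O, E, alpha)
                lo_hi = (low, high, method)
            return cls(
                label, O, E,
                sir=(0.0 if E > 0 else None),
                ci_low=lo_hi[0] if lo_hi else None,
                ci_high=lo_hi[1] if lo_hi else None,
                ci_method=lo_hi[2] if lo_hi else None,
                alpha=alpha,
                status="not_calculable",
            )
        low, high, method = ci_auto(O, E, alpha)
        return cls(label, O, E, sir_point(O, E), low, high, method, alpha)


@dataclass(frozen=True)
class ComparisonResult:
    label1: str
    label2: str
    O1: int
    E1: float
    O2: int
    E2: float
    statistic: float
    p: float
    method: str


def _check_alpha(alpha: float) -> None:
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")


def sir_point(O: int, E: float) -> float:
    """Point estimate O/E; raises :class:`NonCalculableError` when E = 0."""
    if O < 0:
        raise ValueError("observed count must be non-negative")
    if E <= 0:
        raise NonCalculableError("SIR not calculable with zero expected events")
    return O / E


def exact_poisson_ci(O: int, E: float, alpha: float = 0.05) -> tuple[float, float]:
    """Exact Poisson confidence limits for the SIR.

    Inverts the Poisson tail probabilities via the chi-square identity:
    ``low = chi2.ppf(alpha/2, 2*O) / (2*E)`` (zero when O = 0) and
    ``high = chi2.ppf(1 - alpha/2, 2*(O+1)) / (2*E)``, so that
    P(X >= O | mean = low*E) = alpha/2 and P(X <= O | mean = high*E) = alpha/2.
    """
    _check_alpha(alpha)
    if O < 0 or E <= 0:
        raise ValueError("need O >= 0 and E > 0")
    low = 0.0 if O == 0 else float(sps.chi2.ppf(alpha / 2, 2 * O)) / (2 * E)
    high = float(sps.chi2.ppf(1 - alpha / 2, 2 * (O + 1))) / (2 * E)
    return low, high


def byar_ci(O: int, E: float, alpha: float = 0.05) -> tuple[float, float]:
    """Byar's approximation to the exact Poisson limits.

    A cube-root normal transformation of the Poisson count, accurate to a
    fraction of a percent for large O (used at O >= 100):

        low  = (O/E)     * (1 - 1/(9 O)     - z/(3 sqrt(O)))^3
        high = ((O+1)/E) * (1 - 1/(9 (O+1)) + z/(3 sqrt(O+1)))^3

    with z the standard-normal 1 - alpha/2 quantile.  Inapplicable at O = 0
    (use the exact limits).
    """
    _check_alpha(alpha)
    if O < 1:
        raise ValueError("Byar's approximation requires O >= 1; use exact_poisson_ci")
    if E <= 0:
        raise ValueError("need E > 0")
    z = float(sps.norm.ppf(1 - alpha / 2))
    low = (O / E) * (1 - 1 / (9 * O) - z / (3 * np.sqrt(O))) ** 3
    o1 = O + 1
    high = (o1 / E) * (1 - 1 / (9 * o1) + z / (3 * np.sqrt(o1))) ** 3
    return float(low), float(high)


def ci_auto(O: int, E: float, alpha: float = 0.05) -> tuple[float, float, CIMethod]:
    """Confidence limits with the count-dependent method switch: exact
    Poisson below 100 observed events, Byar's approximation at 100 or more
    (the two differ by under 1% at the boundary)."""
    if O < BYAR_THRESHOLD:
        low, high = exact_poisson_ci(O, E, alpha)
        return low, high, CIMethod.exact_poisson
    low, high = byar_ci(O, E, alpha)
    return low, high, CIMethod.byar


def _binom_two_sided(k: int, n: int, p0: float) -> float:
    """Minimum-likelihood two-sided binomial p: sum of outcome probabilities
    not exceeding the observed outcome's probability."""
    pmf = sps.binom.pmf(np.arange(n + 1), n, p0)
    # tolerance guards against ties broken by floating-point noise
    return float(min(1.0, pmf[pmf <= pmf[k] * (1 + 1e-9)].sum()))


def compare_sirs(
    O1: int,
    E1: float,
    O2: int,
    E2: float,
    method: str = "chi_square_approx",
    label1: str = "group1",
    label2: str = "group2",
) -> ComparisonResult:
    """Test equality of two SIRs sharing a reference rate schedule.

    Conditional on n = O1 + O2, equal SIRs make O1 ~ Binomial(n, pi0) with
    pi0 = E1/(E1+E2).  ``method`` selects the exact conditional binomial test
    ("conditional_binomial_exact") or the one-degree-of-freedom chi-square
    approximation ("chi_square_approx").  Symmetric in the two strata.
    """
    if E1 <= 0 or E2 <= 0:
        raise ValueError("comparison requires positive expected counts in both strata")
    n = O1 + O2
    if n < 1:
        raise ValueError("comparison requires at least one observed event")
    pi0 = E1 / (E1 + E2)
    if method == "conditional_binomial_exact":
        p = _binom_two_sided(O1, n, pi0)
        stat = float(O1)
    elif method == "chi_square_approx":
        m1, m2 = n * pi0, n * (1 - pi0)
        stat = (O1 - m1) ** 2 / m1 + (O2 - m2) ** 2 / m2
        p = float(sps.chi2.sf(stat, df=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    return ComparisonResult(label1, label2, O1, E1, O2, E2, float(stat), p, method)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> float:
    """Two-sided pooled z-test of equal proportions (Pearson chi-square
    without continuity correction).

    Degenerate pooled proportions (0 or 1) return p = 1 with a warning.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0 or not 0 <= x <= n:
            raise ValueError("need 0 <= x <= n with n > 0 in both groups")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        warnings.warn("degenerate pooled proportion; test is uninformative")
        return 1.0
    z = (x1 / n1 - x2 / n2) / np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    return float(2 * sps.norm.sf(abs(z)))
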