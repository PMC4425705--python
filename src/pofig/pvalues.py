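"""Distribution of association P-values under null and alternative hypotheses.

A two-sided P-value from a 1-df chi-square (equivalently, squared-Z)
association statistic is uniform on (0, 1) under the null.  Under an
alternative with noncentrality ``gamma`` the statistic is noncentral
chi-square, ``X = (Z + sqrt(gamma))**2`` with ``Z ~ N(0, 1)``, and the
P-value density is the ratio of the noncentral to the central chi-square
density evaluated at the statistic value.  For 1 df this ratio has the
closed form

    f(p | gamma) = exp(-gamma/2) * cosh(sqrt(gamma * x)),   x = Q(1 - p)

where ``Q`` is the central chi-square quantile function.  All heavy-tail
work is done in log space so P-values down to 1e-300 are handled exactly.

The ``family="normal"`` alias treats the statistic as a two-sided |Z| test
with mean shift ``delta = sqrt(gamma)``; the induced P-value distribution
is identical to the chi-square one, so the alias only changes how the
statistic value itself is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "Statistic",
    "StudyDesign",
    "pvalue_to_statistic",
    "alt_pvalue_cdf",
    "alt_pvalue_pdf",
    "log_alt_pvalue_pdf",
    "noncentrality_from_or",
]

_LOG2 = np.log(2.0)


@dataclass(frozen=True)
class Statistic:
    """A test-statistic value with its distribution family.

    ``x`` is the 1-df chi-square statistic for family ``"chisq1"`` or the
    absolute Z-score for family ``"normal"``.
    """

    x: float
    family: str = "chisq1"

    def __post_init__(self):
        if self.family not in ("chisq1", "normal"):
            raise DomainError(f"unknown statistic family {self.family!r}")
        if self.family == "chisq1" and self.x < 0:
            raise DomainError("chi-square statistic must be nonnegative")


@dataclass(frozen=True)
class StudyDesign:
    """Case/control sample sizes in allele counts.

    ``N = n1*n2/(n1+n2)`` is one half of the harmonic mean of the case and
    control allele counts; it is the multiplier that turns a standardized
    effect size into a chi-square noncentrality.
    """

    n1: int
    n2: int

    def __post_init__(self):
        if self.n1 <= 0 or self.n2 <= 0:
            raise DomainError("allele counts n1, n2 must be positive")

    @property
    def N(self) -> float:
        return self.n1 * self.n2 / (self.n1 + self.n2)

    @property
    def n_total(self) -> int:
        return self.n1 + self.n2

    @property
    def sqrt_N(self) -> float:
        """Default meta-analysis weight for this study."""
        return float(np.sqrt(self.N))


def _validate_p(p, *, open_right: bool, open_left: bool = True, name: str = "p"):
    p = np.asarray(p, dtype=float)
    lo_bad = (p <= 0.0) if open_left else (p < 0.0)
    hi_bad = (p >= 1.0) if open_right else (p > 1.0)
    if np.any(lo_bad | hi_bad | ~np.isfinite(p)):
        lo, hi = ("(" if open_left else "["), (")" if open_right else "]")
        raise DomainError(f"{name} must lie in {lo}0, 1{hi}")
    return p


def pvalue_to_statistic(p, family: str = "chisq1"):
    """Invert a two-sided P-value to its test-statistic value.

    Uses the normal-quantile route ``x = [Phi^-1(1 - p/2)]**2`` (the
    survival-function inverse), which is mathematically identical to the
    1-df chi-square quantile but remains accurate for p down to 1e-300.
    Scalar in, scalar out; arrays are broadcast.
    """
    p_arr = _validate_p(p, open_right=False)
    z = stats.norm.isf(p_arr / 2.0)
    if family == "chisq1":
        out = z * z
    elif family == "normal":
        out = z
    else:
        raise DomainError(f"unknown statistic family {family!r}")
    return out if np.ndim(p) else float(out)


def alt_pvalue_cdf(p, gamma, family: str = "chisq1"):
    """CDF of the P-value under the alternative, Pr(P <= p | gamma).

    Computed through the stable normal-tail decomposition
    ``Pr(|Z + b| >= a) = Phi_bar(a - b) + Phi(-a - b)`` with ``a = sqrt(x)``
    and ``b = sqrt(gamma)``, which reduces to ``p`` exactly at gamma = 0.
    """
    p_arr = _validate_p(p, open_right=False, open_left=False)
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise DomainError("gamma must be nonnegative")
    if family == "normal":
        g = g * g  # mean shift delta -> noncentrality delta**2
    elif family != "chisq1":
        raise DomainError(f"unknown statistic family {family!r}")
    with np.errstate(divide="ignore"):
        a = stats.norm.isf(p_arr / 2.0)  # sqrt of chi-square statistic
    b = np.sqrt(g)
    out = stats.norm.sf(a - b) + stats.norm.cdf(-a - b)
    # p == 0 maps to a = inf; both tails vanish.
    out = np.where(p_arr == 0.0, 0.0, out)
    scalar = np.ndim(p) == 0 and np.ndim(gamma) == 0
    return float(out) if scalar else out


def log_alt_pvalue_pdf(p, gamma, family: str = "chisq1"):
    """Log of the P-value density under the alternative (see module docs).

    ``log f = -gamma/2 + logcosh(sqrt(gamma * x))`` with the overflow-safe
    ``logcosh(t) = |t| + log1p(exp(-2|t|)) - log 2``.
    """
    p_arr = _validate_p(p, open_right=True)
    g = np.asarray(gamma, dtype=float)
    if np.any(g < 0):
        raise DomainError("gamma must be nonnegative")
    if family == "normal":
        g = g * g
    elif family != "chisq1":
        raise DomainError(f"unknown statistic family {family!r}")
    z = stats.norm.isf(p_arr / 2.0)
    t = np.abs(np.sqrt(g) * z)
    out = -g / 2.0 + t + np.log1p(np.exp(-2.0 * t)) - _LOG2
    scalar = np.ndim(p) == 0 and np.ndim(gamma) == 0
    return float(out) if scalar else out


def alt_pvalue_pdf(p, gamma, family: str = "chisq1"):
    """P-value density under the alternative; equals 1 everywhere at gamma=0."""
    out = np.exp(log_alt_pvalue_pdf(p, gamma, family=family))
    scalar = np.ndim(p) == 0 and np.ndim(gamma) == 0
    return float(out) if scalar else out


def noncentrality_from_or(odds_ratio, q, design: StudyDesign):
    """Noncentrality implied by an odds ratio under the logistic model.

    gamma = N * (ln OR)^2 * q(1-q), with N the design's harmonic-mean
    factor and q the pooled allele frequency.  Symmetric in OR <-> 1/OR.
    """
    or_arr = np.asarray(odds_ratio, dtype=float)
    q_arr = np.asarray(q, dtype=float)
    if np.any(or_arr <= 0):
        raise DomainError("odds_ratio must be positive")
    if np.any((q_arr <= 0) | (q_arr >= 1)):
        raise DomainError("allele frequency q must lie in (0, 1)")
    out = design.N * np.log(or_arr) ** 2 * q_arr * (1.0 - q_arr)
    scalar = np.ndim(odds_ratio) == 0 and np.ndim(q) == 0
    return float(out) if scalar else out
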