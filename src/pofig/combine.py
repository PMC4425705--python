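"""Combining evidence about one hypothesis across independent studies.

Two routes are provided.  The density-product route multiplies the
per-study marginal P-value densities into a single Bayes factor, which is
identical to sequentially feeding each study's posterior in as the next
study's prior (order does not matter).  The signed P-value route converts
each two-sided P-value to a signed one-sided normal score, pools the
scores with weights (square roots of the studies' harmonic-mean sample
sizes by default), and folds the pooled score back to a two-sided
P-value; this respects effect direction, which the density-product route
on two-sided P-values cannot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import special, stats

from .errors import ConfigurationError, DomainError
from .posterior import PosteriorResult, _posterior_from_log_bayes
from .pvalues import StudyDesign

__all__ = ["StudyEvidence", "combine_posterior", "combine_signed_pvalues"]

_SIGNS = ("+", "-", None)


@dataclass(frozen=True)
class StudyEvidence:
    """One study's evidence about a single hypothesis.

    ``log_marginal`` maps a P-value to the log marginal density for
    genuine signals under that study's design (sample-size-specific
    noncentrality scale); it is only needed for the density-product route.
    """

    p: float
    sign: Optional[str] = None
    weight: float = 1.0
    log_marginal: Optional[Callable] = None

    def __post_init__(self):
        if not 0.0 < self.p < 1.0:
            raise DomainError("study P-value must lie in (0, 1)")
        if self.sign not in _SIGNS:
            raise DomainError("sign must be '+', '-', or None")
        if self.weight <= 0:
            raise DomainError("study weight must be positive")

    @classmethod
    def from_design(cls, p, design: StudyDesign, sign=None, log_marginal=None):
        """Evidence weighted by sqrt(N) of the study's design."""
        return cls(p=p, sign=sign, weight=design.sqrt_N, log_marginal=log_marginal)


def combine_posterior(evidence: Sequence[StudyEvidence], prior_h0: float) -> PosteriorResult:
    """Posterior from the product of per-study marginal densities.

    Ignores effect signs (a documented limitation of combining two-sided
    P-values); use :func:`combine_signed_pvalues` followed by a
    single-study posterior when directions are known.
    """
    evidence = list(evidence)
    if not evidence:
        raise DomainError("combine_posterior needs at least one study")
    if not 0.0 < prior_h0 < 1.0:
        raise DomainError("prior_h0 must lie in (0, 1)")
    log_fbar = 0.0
    for ev in evidence:
        if ev.log_marginal is None:
            raise ConfigurationError(
                "each StudyEvidence needs a log_marginal evaluator for the "
                "density-product combination"
            )
        log_fbar += float(ev.log_marginal(ev.p))
    pr_h0, pofig_val = _posterior_from_log_bayes(log_fbar, prior_h0)
    return PosteriorResult(pofig=float(pofig_val), pr_h0_post=float(pr_h0))


def combine_signed_pvalues(evidence: Sequence[StudyEvidence]) -> float:
    """Direction-aware inverse-normal combination of two-sided P-values.

    Each p_i becomes the one-sided score Phi^-1(p_i/2) (a negative number
    for small p), flipped when the study's sign disagrees with the first
    study's; the weighted sum is normalized by sqrt(sum w_i^2) and folded
    back with p_t = 2*min(p_o, 1 - p_o).  Flipping every sign leaves the
    result unchanged; opposite equal evidence cancels exactly to p_t = 1.
    """
    evidence = list(evidence)
    if not evidence:
        raise DomainError("combine_signed_pvalues needs at least one study")
    if any(ev.sign is None for ev in evidence):
        raise DomainError(
            "all studies need a known effect direction; for sign-free "
            "evidence use combine_posterior instead"
        )
    ref = evidence[0].sign
    agree = np.array([1.0 if ev.sign == ref else -1.0 for ev in evidence])
    w = np.array([ev.weight for ev in evidence])
    scores = stats.norm.ppf(np.array([ev.p for ev in evidence]) / 2.0)
    pooled = float(np.sum(agree * w * scores) / np.sqrt(np.sum(w * w)))
    # 2*min(1-Phi(pooled), Phi(pooled)), computed through the far tail so
    # strongly agreeing studies cannot underflow to an exact zero.
    return float(2.0 * stats.norm.sf(abs(pooled)))
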