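"""Posterior probabilities of hypotheses given association P-values.

The central quantity is the posterior probability that a finding is
genuine,

    POFIG = Pr(HA | p) = 1 - [1 + (1 - Pr(H0))/Pr(H0) * fbar(p)]^-1,

where ``fbar`` is the marginal P-value density for genuine signals and
P-values are uniform under the null.  The bin-mode variant replaces the
sharp null with a near-zero "null bin" and returns the full posterior
over bins; FPRP is the tail-area analogue Pr(H0 | P <= alpha); the mean
of posterior null probabilities over a selected set of findings estimates
the proportion of spurious signals in that set (an FDR estimate).

:class:`PofigPosterior` packages the sharp-null conversion as a
scikit-learn estimator so it composes with pipelines and parameter
searches; the module-level functions are thin wrappers over the same
numerics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import integrate, special
from sklearn.base import BaseEstimator

from .effects import (
    BinTable,
    EffectSizeDistribution,
    ScaleContext,
    discretize,
    log_marginal_exponential,
    marginal_density_binned,
    marginal_density_exact,
    marginal_density_mean,
    resolve_sigma,
)
from .errors import ConfigurationError, DomainError
from .pvalues import StudyDesign, alt_pvalue_cdf, log_alt_pvalue_pdf, pvalue_to_statistic

__all__ = [
    "PosteriorResult",
    "PofigPosterior",
    "pofig_sharp",
    "posterior_bins",
    "fprp",
    "fdr_estimate",
    "prior_from_locus_counts",
]


@dataclass(frozen=True)
class PosteriorResult:
    """Posterior summary for one association record."""

    pofig: float
    pr_h0_post: float
    bin_posteriors: Optional[np.ndarray] = None
    post_mean_effect: Optional[float] = None
    fprp: Optional[float] = None
    degenerate_prior: bool = False


def prior_from_locus_counts(n_loci: int, k_total: int) -> float:
    """Prior Pr(H0) = 1 - n_loci/k_total from genome locus bookkeeping."""
    if not 0 < n_loci < k_total:
        raise ConfigurationError("need 0 < n_loci < k_total")
    return 1.0 - n_loci / k_total


def _posterior_from_log_bayes(log_fbar: float, prior_h0: float):
    """Pr(H0|p) and POFIG from log fbar(p), in log-odds space."""
    log_prior_odds = np.log1p(-prior_h0) - np.log(prior_h0)  # odds of HA
    log_post_odds = log_prior_odds + log_fbar
    pr_h0 = special.expit(-log_post_odds)
    pofig_val = special.expit(log_post_odds)
    return pr_h0, pofig_val


def pofig_sharp(p, prior_h0: float, log_marginal: Callable) -> PosteriorResult:
    """Sharp-null posterior from a P-value and a log marginal-density evaluator.

    ``log_marginal`` maps a P-value to log fbar(p); use
    ``PofigPosterior`` or ``functools.partial(marginal_density_exact, ...,
    log=True)`` to build one.  A degenerate prior (0 or 1) returns the
    prior unchanged with a warning, since no data can move it.
    """
    if not 0.0 <= prior_h0 <= 1.0:
        raise DomainError("prior_h0 must lie in [0, 1]")
    if prior_h0 in (0.0, 1.0):
        warnings.warn("degenerate prior: posterior equals the prior", stacklevel=2)
        return PosteriorResult(pofig=1.0 - prior_h0, pr_h0_post=prior_h0,
                               degenerate_prior=True)
    log_fbar = float(log_marginal(p))
    pr_h0, pofig_val = _posterior_from_log_bayes(log_fbar, prior_h0)
    return PosteriorResult(pofig=float(pofig_val), pr_h0_post=float(pr_h0))


def posterior_bins(p, table: BinTable, bin_priors: Optional[Sequence[float]] = None,
                   ctx: Optional[ScaleContext] = None) -> PosteriorResult:
    """Posterior over effect-size bins, null bin included.

    ``bin_priors`` orders as (null, bin_1, ..., bin_B) and must sum to 1;
    by default the table's weights (null bin first) are normalized into
    priors.  The posterior null probability is the null bin's posterior
    and the posterior mean effect is the prior-scale weighted average of
    representative values.
    """
    if table.null_bin is None:
        raise ConfigurationError("posterior_bins needs a BinTable with a null bin")
    n_hyp = len(table.bins) + 1
    if bin_priors is None:
        w = table.weights(include_null=True)
        priors = w / w.sum()
    else:
        priors = np.asarray(bin_priors, dtype=float)
        if priors.shape != (n_hyp,):
            raise ConfigurationError(
                f"bin_priors must have length {n_hyp} (null bin first)"
            )
        if np.any(priors < 0) or not np.isclose(priors.sum(), 1.0, atol=1e-8):
            raise ConfigurationError("bin_priors must be nonnegative and sum to 1")
    sigma = resolve_sigma(table, ctx)
    gammas = sigma * table.rep_values(include_null=True)
    log_pdf = log_alt_pvalue_pdf(float(p), gammas)
    with np.errstate(divide="ignore"):
        log_post = np.log(priors) + log_pdf
    log_post -= special.logsumexp(log_post)
    post = np.exp(log_post)
    reps = table.rep_values(include_null=True)
    return PosteriorResult(
        pofig=float(1.0 - post[0]),
        pr_h0_post=float(post[0]),
        bin_posteriors=post,
        post_mean_effect=float(post @ reps),
    )


def fprp(alpha: float, prior_h0: float, dist: EffectSizeDistribution,
         ctx: Optional[ScaleContext] = None) -> float:
    """False Positive Report Probability Pr(H0 | P <= alpha).

    The marginal power Fbar(alpha) = E_gamma[Pr(P <= alpha | gamma)] is
    obtained by quadrature over the prior; because Fbar(alpha) <= 1 the
    result can never exceed the prior Pr(H0).
    """
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    if not 0.0 < prior_h0 < 1.0:
        raise DomainError("prior_h0 must lie in (0, 1)")
    dist_gamma = dist.to_noncentrality(ctx)
    if dist_gamma.family == "point":
        power = alt_pvalue_cdf(alpha, dist_gamma.value)
    else:
        fr = dist_gamma.frozen()
        upper = fr.isf(1e-13)
        val, _ = integrate.quad(
            lambda g: alt_pvalue_cdf(alpha, g) * fr.pdf(g),
            0.0, upper, limit=200, epsabs=1e-13, epsrel=1e-10,
        )
        # The integrand beyond `upper` is bounded by the neglected mass.
        power = min(val + 1e-13, 1.0)
    log_bayes = np.log(power) - np.log(alpha)
    pr_h0, _ = _posterior_from_log_bayes(log_bayes, prior_h0)
    return float(pr_h0)


def fdr_estimate(posteriors) -> float:
    """Mean posterior null probability over a selected set of findings."""
    arr = np.asarray(list(posteriors), dtype=float)
    if arr.size == 0:
        raise DomainError("fdr_estimate needs a nonempty collection")
    return float(arr.mean())


class PofigPosterior(BaseEstimator):
    """Convert association P-values to posterior probabilities of association.

    A scikit-learn-style estimator for the sharp-null posterior.  The
    hyperparameters are the prior probability of no association, an
    effect-size prior, and the way the marginal P-value density is
    evaluated; ``fit`` validates them and precomputes the pieces that do
    not depend on the data.

    Parameters
    ----------
    prior_h0 : float
        Prior probability that a tested variant is not associated.
    effect_dist : EffectSizeDistribution or BinTable
        Prior for true-signal effect magnitudes.  A continuous
        distribution feeds the ``exact``/``mean``/``binned`` methods; a
        BinTable forces ``method="binned"``.
    method : {"exact", "mean", "binned"}
        Exact integration over the prior, the typical-effect-size (prior
        mean) approximation, or the tabulated-bins approximation.
    design : StudyDesign, optional
        Required when the effect prior is on the standardized or
        squared-log-OR scale (supplies N).
    n_bins : int
        Number of bins when a continuous prior is discretized for
        ``method="binned"``.
    null_upper : float, optional
        Upper edge of a near-zero null bin carved out during
        discretization (bin-mode posterior only).

    Attributes
    ----------
    log_prior_odds_ : float
        log[(1 - Pr(H0)) / Pr(H0)], set by ``fit``.
    bin_table_ : BinTable
        Discretized prior (only with ``method="binned"``).
    n_features_in_ : int
        Number of columns seen in ``fit``/first ``predict_proba`` call.

    Examples
    --------
    >>> from pofig import EffectSizeDistribution, PofigPosterior
    >>> est = PofigPosterior(prior_h0=1 - 142/12877,
    ...                      effect_dist=EffectSizeDistribution.gamma_prior(1, 17.25))
    >>> est.fit().predict_proba([[8.80e-9]])[0, 0]  # Pr(H0 | p)
    4.6...e-05
    """

    def __init__(self, prior_h0: float = 0.5,
                 effect_dist=None,
                 method: str = "exact",
                 design: Optional[StudyDesign] = None,
                 n_bins: int = 3,
                 null_upper: Optional[float] = None):
        self.prior_h0 = prior_h0
        self.effect_dist = effect_dist
        self.method = method
        self.design = design
        self.n_bins = n_bins
        self.null_upper = null_upper

    # -- scikit-learn plumbing ------------------------------------------------

    def fit(self, X=None, y=None):
        """Validate hyperparameters and precompute the prior odds."""
        if self.effect_dist is None:
            raise ConfigurationError("effect_dist is required")
        if not 0.0 < self.prior_h0 < 1.0:
            raise ConfigurationError("prior_h0 must lie in (0, 1)")
        if self.method not in ("exact", "mean", "binned"):
            raise ConfigurationError(f"unknown method {self.method!r}")

        if isinstance(self.effect_dist, BinTable):
            if self.method != "binned":
                raise ConfigurationError("a BinTable prior requires method='binned'")
            self.bin_table_ = self.effect_dist
        elif self.method == "binned":
            self.bin_table_ = discretize(self.effect_dist, n_bins=self.n_bins,
                                         null_upper=self.null_upper)
        effect_scale = self.effect_dist.effect_scale
        if effect_scale != "noncentrality" and self.design is None:
            raise ConfigurationError(
                f"effect scale {effect_scale!r} requires a StudyDesign; pass "
                "design=StudyDesign(n1, n2) or put the prior on noncentralities"
            )
        self.effect_scale_ = effect_scale
        self.log_prior_odds_ = float(np.log1p(-self.prior_h0) - np.log(self.prior_h0))
        if X is not None:
            X = self._check_X(X)
            self.n_features_in_ = X.shape[1]
        return self

    def _check_X(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] not in (1, 2):
            raise DomainError(
                "X must be (n, 1) P-values or (n, 2) [P-value, allele frequency]"
            )
        if self.effect_scale_ == "sq_log_or" and X.shape[1] != 2:
            raise ConfigurationError(
                "the sq_log_or effect scale needs per-record allele "
                "frequencies: pass X with columns [p, qhat]"
            )
        p = X[:, 0]
        if np.any((p <= 0) | (p >= 1) | ~np.isfinite(p)):
            raise DomainError("P-values must lie strictly inside (0, 1)")
        return X

    def _ctx_for(self, qhat: Optional[float]) -> Optional[ScaleContext]:
        if self.effect_scale_ == "noncentrality":
            return None
        return ScaleContext(N=self.design.N, qhat=qhat)

    def log_marginal(self, p, qhat: Optional[float] = None) -> float:
        """log fbar(p) under the fitted effect model (scalar)."""
        ctx = self._ctx_for(qhat)
        if self.method == "exact":
            return float(marginal_density_exact(p, self.effect_dist, ctx, log=True))
        if self.method == "mean":
            return float(marginal_density_mean(p, self.effect_dist, ctx, log=True))
        return float(marginal_density_binned(p, self.bin_table_, ctx, log=True))

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probabilities, columns ``[Pr(H0|p), Pr(HA|p)]``."""
        if not hasattr(self, "log_prior_odds_"):
            self.fit()
        X = self._check_X(X)
        self.n_features_in_ = X.shape[1]
        log_fbar = np.array([
            self.log_marginal(row[0], row[1] if X.shape[1] == 2 else None)
            for row in X
        ])
        log_post_odds = self.log_prior_odds_ + log_fbar
        return np.column_stack([special.expit(-log_post_odds),
                                special.expit(log_post_odds)])

    def predict(self, X) -> np.ndarray:
        """1 where a finding is more likely genuine than spurious."""
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def transform(self, X) -> np.ndarray:
        """Alias of :meth:`predict_proba` for transformer pipelines."""
        return self.predict_proba(X)

    def fdr(self, X) -> float:
        """Estimated proportion of spurious findings among the records in X."""
        return fdr_estimate(self.predict_proba(X)[:, 0])
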