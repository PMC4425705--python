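"""Effect-size priors and the marginal P-value density for genuine signals.

The prior for true-signal effect magnitudes can live on one of three
scales:

``noncentrality``
    directly on the chi-square noncentrality ``gamma``;
``standardized``
    on ``E = D*q*(1-q)`` (twice the SNP's contribution to additive genetic
    variance), with ``gamma = N * E``;
``sq_log_or``
    on the squared log odds ratio ``D``, with ``gamma = N*q(1-q) * D``
    so the marginal density depends on the sample allele frequency.

In every case the conversion to noncentrality is multiplication by a
scalar ``sigma`` (1, ``N``, or ``N*q(1-q)``), so a gamma-family prior on
any scale maps to a gamma-family prior on noncentralities with the scale
parameter multiplied by ``sigma``.  The marginal P-value density for
genuine signals is the prior expectation of the conditional density,

    fbar(p) = E_gamma[ f(p | gamma) ],

evaluated exactly by adaptive quadrature, approximately by plugging in the
prior mean, or approximately by a weighted sum over tabulated bins.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import integrate, special, stats

from .errors import ConfigurationError, DomainError, NumericalError
from .pvalues import alt_pvalue_cdf, log_alt_pvalue_pdf, pvalue_to_statistic

__all__ = [
    "EffectSizeDistribution",
    "ScaleContext",
    "Bin",
    "BinTable",
    "marginal_density_exact",
    "marginal_density_mean",
    "marginal_density_binned",
    "log_marginal_exponential",
    "discretize",
    "bin_table_from_standardized",
    "read_bin_table",
    "write_bin_table",
]

_EFFECT_SCALES = ("noncentrality", "standardized", "sq_log_or")


@dataclass(frozen=True)
class EffectSizeDistribution:
    """A prior for true-signal effect magnitudes.

    ``family="gamma"`` is the L-shaped Gamma(shape, scale) prior typical of
    association effect sizes (shape <= 1 tapers off from zero); ``"point"``
    is a degenerate single-value prior used for the typical-effect-size
    approximation and for testing.
    """

    family: str = "gamma"
    shape: float = 1.0
    scale: float = 1.0
    value: float = 0.0
    effect_scale: str = "noncentrality"

    def __post_init__(self):
        if self.family not in ("gamma", "point"):
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.effect_scale not in _EFFECT_SCALES:
            raise ConfigurationError(f"unknown effect scale {self.effect_scale!r}")
        if self.family == "gamma" and (self.shape <= 0 or self.scale <= 0):
            raise ConfigurationError("gamma family needs positive shape and scale")
        if self.family == "point" and self.value < 0:
            raise ConfigurationError("point value must be nonnegative")

    @classmethod
    def gamma_prior(cls, shape, scale, effect_scale="noncentrality"):
        return cls(family="gamma", shape=shape, scale=scale, effect_scale=effect_scale)

    @classmethod
    def point(cls, value, effect_scale="noncentrality"):
        return cls(family="point", value=value, effect_scale=effect_scale)

    @property
    def mean(self) -> float:
        if self.family == "point":
            return self.value
        return self.shape * self.scale

    def frozen(self):
        """The scipy frozen distribution (gamma family only)."""
        if self.family != "gamma":
            raise ConfigurationError("only the gamma family has a frozen form")
        return stats.gamma(self.shape, scale=self.scale)

    def to_noncentrality(self, ctx: Optional["ScaleContext"] = None):
        """Re-express this prior directly on the noncentrality scale."""
        sigma = resolve_sigma(self, ctx)
        if self.family == "point":
            return EffectSizeDistribution.point(self.value * sigma)
        return EffectSizeDistribution.gamma_prior(self.shape, self.scale * sigma)


@dataclass(frozen=True)
class ScaleContext:
    """Study context needed to map an effect-size scale to noncentralities.

    ``N`` is the design factor n1*n2/(n1+n2) (required for the standardized
    and sq_log_or scales); ``qhat`` is the sample pooled allele frequency
    (required for sq_log_or only).
    """

    N: Optional[float] = None
    qhat: Optional[float] = None

    def __post_init__(self):
        if self.N is not None and self.N <= 0:
            raise ConfigurationError("N must be positive")
        if self.qhat is not None and not (0.0 <= self.qhat <= 1.0):
            raise ConfigurationError("qhat must lie in [0, 1]")


def resolve_sigma(dist_or_scale, ctx: Optional[ScaleContext]) -> float:
    """Multiplier turning the prior's scale into noncentrality units."""
    effect_scale = getattr(dist_or_scale, "effect_scale", dist_or_scale)
    if effect_scale == "noncentrality":
        return 1.0
    if ctx is None or ctx.N is None:
        raise ConfigurationError(
            f"effect scale {effect_scale!r} needs a ScaleContext with N set"
        )
    if effect_scale == "standardized":
        return float(ctx.N)
    if effect_scale == "sq_log_or":
        if ctx.qhat is None:
            raise ConfigurationError(
                "effect scale 'sq_log_or' needs the sample pooled allele "
                "frequency qhat in the ScaleContext"
            )
        return float(ctx.N * ctx.qhat * (1.0 - ctx.qhat))
    raise ConfigurationError(f"unknown effect scale {effect_scale!r}")


# ---------------------------------------------------------------------------
# Marginal P-value densities


def log_marginal_exponential(x, lam):
    """Log marginal P-value density under an exponential noncentrality prior.

    For gamma ~ Exponential(scale=lam) the prior expectation of
    exp(-gamma/2) cosh(sqrt(gamma*x)) integrates in closed form:

        fbar = 1/(lam*b) + c*sqrt(pi)/(2*lam*b**1.5) * exp(c^2/(4b)) * erf(c/(2*sqrt(b)))

    with b = 1/2 + 1/lam and c = sqrt(x).  Evaluated in log space;
    vectorized over both arguments.  lam = 0 collapses to the null density.
    """
    x = np.asarray(x, dtype=float)
    lam = np.asarray(lam, dtype=float)
    x, lam = np.broadcast_arrays(x, lam)
    out = np.zeros_like(x, dtype=float)
    pos = lam > 0
    if np.any(pos):
        b = 0.5 + 1.0 / lam[pos]
        c = np.sqrt(x[pos])
        arg = c / (2.0 * np.sqrt(b))
        log_t1 = -np.log(lam[pos] * b)
        with np.errstate(divide="ignore"):
            log_erf = np.log(special.erf(arg))
            log_t2 = (
                arg * arg
                + np.log(c, out=np.full_like(c, -np.inf), where=c > 0)
                + 0.5 * np.log(np.pi)
                - np.log(2.0 * lam[pos])
                - 1.5 * np.log(b)
                + log_erf
            )
        out[pos] = np.logaddexp(log_t1, log_t2)
    return out if out.ndim else float(out)


def _log_integrand_factory(x, dist_gamma: EffectSizeDistribution):
    """Log integrand in u = sqrt(gamma) coordinates, Jacobian included."""
    a, s = dist_gamma.shape, dist_gamma.scale
    log_norm = -special.gammaln(a) - a * math.log(s)
    sqrt_x = math.sqrt(x)

    def log_f(u):
        u = np.asarray(u, dtype=float)
        g = u * u
        t = sqrt_x * u
        log_cosh = t + np.log1p(np.exp(-2.0 * t)) - math.log(2.0)
        with np.errstate(divide="ignore"):
            log_prior = log_norm + (a - 1.0) * np.log(g) - g / s
            log_jac = np.log(2.0 * u)
        return -g / 2.0 + log_cosh + log_prior + log_jac

    return log_f


def _marginal_log_density_exact_scalar(p: float, dist_gamma: EffectSizeDistribution) -> float:
    """Adaptive quadrature of the marginal density for a gamma prior on gamma.

    Integrates in u = sqrt(gamma) after shifting by the integrand's log
    maximum so arbitrarily large density ratios (tiny P-values) stay in
    range.  The upper limit covers both the prior's far tail and the point
    where the exponent has fallen 60 nats below its linear-tail crossing.
    """
    x = pvalue_to_statistic(p)
    a, s = dist_gamma.shape, dist_gamma.scale
    log_f = _log_integrand_factory(x, dist_gamma)

    # Upper limit in u: solve b*u^2 - c*u = 60 for the exponential part,
    # and take at least the prior's 1-1e-14 quantile.
    b = 0.5 + 1.0 / s
    c = math.sqrt(x)
    u_tail = (c + math.sqrt(c * c + 4.0 * b * 60.0)) / (2.0 * b)
    u_prior = math.sqrt(dist_gamma.frozen().isf(1e-14))
    upper = max(u_tail, u_prior, 1.0)

    grid = np.linspace(upper / 2048.0, upper, 1024)
    log_vals = log_f(grid)
    shift = float(np.max(log_vals))
    u_mode = float(grid[int(np.argmax(log_vals))])

    def integrand(u):
        return np.exp(log_f(u) - shift)

    val, err = integrate.quad(
        integrand, 0.0, upper, points=[u_mode], limit=400, epsabs=1e-12, epsrel=1e-10
    )
    if not np.isfinite(val) or val <= 0 or err > 1e-6 * max(val, 1e-300):
        raise NumericalError(
            f"marginal-density quadrature did not converge (p={p!r}, "
            f"shape={a}, scale={s}, value={val}, abserr={err})"
        )
    return shift + math.log(val)


def marginal_density_exact(p, dist: EffectSizeDistribution,
                           ctx: Optional[ScaleContext] = None, *, log: bool = False):
    """Marginal P-value density fbar(p) by exact integration over the prior."""
    dist_gamma = dist.to_noncentrality(ctx)
    if dist_gamma.family == "point":
        out = log_alt_pvalue_pdf(p, dist_gamma.value)
    elif dist_gamma.shape == 1.0:
        out = log_marginal_exponential(pvalue_to_statistic(p), dist_gamma.scale)
    else:
        p_arr = np.asarray(p, dtype=float)
        flat = [_marginal_log_density_exact_scalar(float(pi), dist_gamma)
                for pi in np.atleast_1d(p_arr)]
        out = float(flat[0]) if p_arr.ndim == 0 else np.array(flat).reshape(p_arr.shape)
    if not log:
        out = np.exp(out)
    return float(out) if np.ndim(p) == 0 else np.asarray(out)


def marginal_density_mean(p, dist: EffectSizeDistribution,
                          ctx: Optional[ScaleContext] = None, *, log: bool = False):
    """Typical-effect-size approximation: plug the prior mean into f(p|gamma).

    Conservative for very small P-values relative to the exact integral
    (the integrand is convex in gamma there), which makes the resulting
    posterior Pr(H0|p) an overstatement for top hits.
    """
    mu_gamma = dist.mean * resolve_sigma(dist, ctx)
    out = log_alt_pvalue_pdf(p, mu_gamma)
    if not log:
        out = np.exp(out)
    return float(out) if np.ndim(p) == 0 else np.asarray(out)


# ---------------------------------------------------------------------------
# Tabulated (binned) priors


@dataclass(frozen=True)
class Bin:
    """One bin of a discretized effect-size prior.

    ``rep_value`` is the bin's representative effect size (its conditional
    mean under the continuous prior, when built by :func:`discretize`) and
    ``weight`` its probability mass or signal count.
    """

    label: str
    rep_value: float
    weight: float
    lower: float = 0.0
    upper: float = math.inf

    def __post_init__(self):
        if self.weight < 0:
            raise ConfigurationError("bin weight must be nonnegative")
        if not (self.lower <= self.rep_value <= self.upper):
            raise ConfigurationError(
                f"bin {self.label!r}: rep_value {self.rep_value} outside "
                f"[{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class BinTable:
    """An ordered set of effect-size bins, optionally with a null bin.

    The null bin collects effects small enough to be considered spurious
    (e.g. odds ratios in [1, 1.001]); it takes part in the bin-mode
    posterior but is excluded from the genuine-signal marginal density.
    """

    bins: tuple
    null_bin: Optional[Bin] = None
    effect_scale: str = "noncentrality"

    def __post_init__(self):
        object.__setattr__(self, "bins", tuple(self.bins))
        if self.effect_scale not in _EFFECT_SCALES:
            raise ConfigurationError(f"unknown effect scale {self.effect_scale!r}")
        if not self.bins:
            raise ConfigurationError("BinTable needs at least one non-null bin")
        if self.total_weight <= 0:
            raise ConfigurationError("total bin weight must be positive")
        if self.null_bin is not None:
            if self.null_bin.rep_value > min(b.rep_value for b in self.bins):
                raise ConfigurationError(
                    "null bin must have the smallest representative value"
                )

    @property
    def total_weight(self) -> float:
        return float(sum(b.weight for b in self.bins))

    @property
    def all_bins(self) -> tuple:
        """Null bin (if any) first, then the alternative bins."""
        return ((self.null_bin,) if self.null_bin else ()) + self.bins

    def rep_values(self, include_null: bool = False) -> np.ndarray:
        bins = self.all_bins if include_null else self.bins
        return np.array([b.rep_value for b in bins], dtype=float)

    def weights(self, include_null: bool = False) -> np.ndarray:
        bins = self.all_bins if include_null else self.bins
        return np.array([b.weight for b in bins], dtype=float)


def marginal_density_binned(p, table: BinTable, ctx: Optional[ScaleContext] = None,
                            *, include_null: bool = False, log: bool = False):
    """Weight-normalized mixture of f(p|gamma_i) over the table's bins."""
    sigma = resolve_sigma(table, ctx)
    gammas = sigma * table.rep_values(include_null)
    weights = table.weights(include_null)
    if np.all(weights == 0):
        raise ConfigurationError("all bin weights are zero")
    p_arr = np.asarray(p, dtype=float)
    log_pdf = log_alt_pvalue_pdf(p_arr[..., None], gammas[None, ...]
                                 if p_arr.ndim else gammas)
    with np.errstate(divide="ignore"):
        log_w = np.log(weights) - np.log(weights.sum())
    out = special.logsumexp(log_pdf + log_w, axis=-1)
    if not log:
        out = np.exp(out)
    return float(out) if np.ndim(p) == 0 else np.asarray(out)


def _gamma_conditional_mean(dist: EffectSizeDistribution, lower: float, upper: float) -> float:
    """E[X | lower <= X < upper] for a gamma distribution.

    Uses x * pdf(x; a, s) = mean * pdf(x; a+1, s), so the truncated first
    moment is the mean times the mass of the shape-(a+1) distribution.
    """
    fr = dist.frozen()
    fr_up = stats.gamma(dist.shape + 1.0, scale=dist.scale)
    mass = fr.cdf(upper) - fr.cdf(lower)
    if mass <= 0:
        raise NumericalError(f"empty bin [{lower}, {upper}] for {dist}")
    return dist.mean * (fr_up.cdf(upper) - fr_up.cdf(lower)) / mass


def discretize(dist: EffectSizeDistribution, n_bins: int = 3,
               null_upper: Optional[float] = None,
               representative: str = "conditional_mean") -> BinTable:
    """Collapse a continuous effect-size prior into a small bin table.

    For ``n_bins = 3`` the middle bin is centered on the prior mean ``mu``
    with width ``mu`` (edges mu/2 and 3*mu/2) and the outer bins take the
    remaining support, which captures the bulk of an L-shaped prior with
    three representative values (small/medium/large).  For other bin counts
    equal-probability quantile bins are used.  Each bin's weight is its
    prior mass and its representative value the conditional mean within
    the bin (``representative="midpoint"`` switches to interval midpoints
    for sensitivity analysis; the unbounded top bin keeps its conditional
    mean).

    ``null_upper`` carves a separate near-zero null bin [0, null_upper)
    out of the smallest bin.
    """
    if dist.family != "gamma":
        raise ConfigurationError("discretize expects a continuous (gamma) prior")
    mu = dist.mean
    if mu <= 0:
        raise ConfigurationError("prior mean must be positive")
    if n_bins == 3:
        edges = [0.0, mu / 2.0, 1.5 * mu, math.inf]
    elif n_bins >= 1:
        qs = np.linspace(0.0, 1.0, n_bins + 1)[1:-1]
        edges = [0.0, *dist.frozen().ppf(qs), math.inf]
    else:
        raise ConfigurationError("n_bins must be a positive integer")

    null_bin = None
    if null_upper is not None:
        if not 0.0 < null_upper < edges[1]:
            raise ConfigurationError(
                "null_upper must fall inside the smallest bin"
            )
        fr = dist.frozen()
        null_bin = Bin(
            label="null",
            rep_value=_gamma_conditional_mean(dist, 0.0, null_upper),
            weight=float(fr.cdf(null_upper)),
            lower=0.0,
            upper=null_upper,
        )
        edges[0] = null_upper

    labels = {3: ["small", "medium", "large"]}.get(n_bins)
    fr = dist.frozen()
    bins = []
    for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
        weight = float(fr.cdf(hi) - fr.cdf(lo))
        if representative == "conditional_mean" or not math.isfinite(hi):
            rep = _gamma_conditional_mean(dist, lo, hi)
        elif representative == "midpoint":
            rep = 0.5 * (lo + hi)
        else:
            raise ConfigurationError(f"unknown representative rule {representative!r}")
        label = labels[i] if labels else f"bin{i + 1}"
        bins.append(Bin(label=label, rep_value=rep, weight=weight, lower=lo, upper=hi))
    return BinTable(bins=tuple(bins), null_bin=null_bin, effect_scale=dist.effect_scale)


def bin_table_from_standardized(values: Sequence[float], weights: Sequence[float],
                                N: float, labels: Optional[Sequence[str]] = None) -> BinTable:
    """Build a noncentrality bin table from tabulated 2*D*q(1-q) effect sizes.

    External effect-size tables are commonly published on the scale
    2*D*q(1-q) (the SNP's additive-variance contribution), which is 2/N of
    the noncentrality; each tabulated value v maps to gamma = v * N / 2.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.shape != weights.shape or values.ndim != 1:
        raise ConfigurationError("values and weights must be 1-d and equal length")
    gammas = values * N / 2.0
    order = np.argsort(gammas)
    bins = tuple(
        Bin(
            label=(labels[i] if labels else f"bin{k + 1}"),
            rep_value=float(gammas[i]),
            weight=float(weights[i]),
            lower=float(gammas[i]),
            upper=float(gammas[i]),
        )
        for k, i in enumerate(order)
    )
    return BinTable(bins=bins, effect_scale="noncentrality")


# ---------------------------------------------------------------------------
# Serialization (TSV round-trip)

_HEADER = "label\tlower\tupper\trep_value\tweight"


def write_bin_table(table: BinTable, path_or_buf) -> None:
    """Write a bin table as TSV with an effect-scale declaration line."""
    lines = [f"# effect_scale={table.effect_scale}", _HEADER]
    for b in table.all_bins:
        lines.append(
            f"{b.label}\t{float(b.lower)!r}\t{float(b.upper)!r}"
            f"\t{float(b.rep_value)!r}\t{float(b.weight)!r}"
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(text)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(text)


def read_bin_table(path_or_buf) -> BinTable:
    """Read a bin table written by :func:`write_bin_table` (exact round-trip)."""
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines or not lines[0].startswith("# effect_scale="):
        raise ConfigurationError("bin table must start with '# effect_scale=...'")
    effect_scale = lines[0].split("=", 1)[1].strip()
    if lines[1] != _HEADER:
        raise ConfigurationError(f"expected header {_HEADER!r}")
    bins, null_bin = [], None
    for ln in lines[2:]:
        label, lo, hi, rep, w = ln.split("\t")
        b = Bin(label=label, rep_value=float(rep), weight=float(w),
                lower=float(lo), upper=float(hi))
        if label == "null":
            null_bin = b
        else:
            bins.append(b)
    return BinTable(bins=tuple(bins), null_bin=null_bin, effect_scale=effect_scale)
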