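"""Monte-Carlo study of selection effects in multiple-testing experiments.

Each simulated experiment holds ``K`` one-df chi-square association tests.
A test is spurious with probability ``pr_h0`` (its P-value is uniform);
otherwise a squared-log-odds-ratio effect ``D`` is drawn from the
effect-size prior, a population allele frequency ``q`` from a uniform
range, the noncentrality is ``gamma = N * D * q(1-q)``, and the P-value
comes from the statistic ``X = (Z + sqrt(gamma))**2``.  The hidden truth
label and noncentrality are stored for scoring only; posterior estimators
see nothing but the P-value and the binomially sampled allele frequency.

The package's calibration claim is checked by comparing, over many
experiments, the empirical fraction of spurious signals among selected
P-values (the smallest one, or the ``m`` smallest, optionally conditioned
on surviving a Bonferroni or Benjamini-Hochberg filter) with the mean
estimated posterior Pr(H0|p) over the same selection.

Replicates are generated in fixed chunks of 256 with independent seed
substreams, so any single replicate can be regenerated in isolation and
results are bit-identical for a given seed and configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .effects import (
    EffectSizeDistribution,
    discretize,
    log_marginal_exponential,
    marginal_density_exact,
    ScaleContext,
)
from .errors import ConfigurationError, DomainError
from .pvalues import StudyDesign, log_alt_pvalue_pdf, pvalue_to_statistic

__all__ = [
    "SimConfig",
    "SimResult",
    "simulate_experiment",
    "apply_retention",
    "estimate_posteriors",
    "run_cell",
    "run_table",
    "minp_null_fraction_large_k",
    "simulate_scan_replication",
]

REP_CHUNK = 256  # replicates per seed substream

#: Effect-size prior used throughout the simulation study: squared log odds
#: ratio with mean (ln 1.1)^2, i.e. a mean odds ratio of 1.1.
DEFAULT_EFFECT_DIST = EffectSizeDistribution.gamma_prior(
    1.0, math.log(1.1) ** 2, effect_scale="sq_log_or"
)

#: Null-bin odds-ratio interval [1, 1.001] with representative OR 1.0005,
#: expressed as squared log odds ratios.
NULL_BIN_D_UPPER = math.log(1.001) ** 2
NULL_BIN_D_REP = math.log(1.0005) ** 2


@dataclass(frozen=True)
class SimConfig:
    """One cell of the simulation study."""

    K: int = 10
    pr_h0: float = 0.5
    effect_dist: EffectSizeDistribution = DEFAULT_EFFECT_DIST
    design: StudyDesign = StudyDesign(400, 400)
    q_range: tuple = (0.05, 0.95)
    n_reps: int = 1000
    seed: int = 0
    selection: str = "minp"  # none | minp | top_m
    m: int = 1
    retention: str = "none"  # none | bonferroni_0.05 | bh_0.10
    estimators: tuple = ("exact",)

    def __post_init__(self):
        if not 0.0 <= self.pr_h0 <= 1.0:
            raise ConfigurationError("pr_h0 must lie in [0, 1]")
        if self.selection not in ("none", "minp", "top_m"):
            raise ConfigurationError(f"unknown selection {self.selection!r}")
        if self.retention not in ("none", "bonferroni_0.05", "bh_0.10"):
            raise ConfigurationError(f"unknown retention {self.retention!r}")
        if self.selection == "top_m" and not 1 <= self.m <= self.K:
            raise ConfigurationError("need 1 <= m <= K for top_m selection")
        for est in self.estimators:
            if est not in ("exact", "binned", "mean"):
                raise ConfigurationError(f"unknown estimator {est!r}")


@dataclass(frozen=True)
class SimResult:
    """Empirical vs estimated proportion of spurious signals in a selection."""

    empirical: float
    estimated: dict
    se: float
    n_retained: int
    n_reps: int


def _chunk_rng(seed: int, chunk: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(chunk,)))


def _sample_effect(dist: EffectSizeDistribution, rng, size):
    if dist.family == "point":
        return np.full(size, dist.value)
    return rng.gamma(dist.shape, dist.scale, size)


def _simulate_chunk(cfg: SimConfig, chunk: int) -> dict:
    """Generate a (REP_CHUNK, K) block of experiments for one substream."""
    rng = _chunk_rng(cfg.seed, chunk)
    shape = (REP_CHUNK, cfg.K)
    is_null = rng.random(shape) < cfg.pr_h0
    p_null = rng.random(shape)
    D = _sample_effect(cfg.effect_dist, rng, shape)
    q_pop = rng.uniform(cfg.q_range[0], cfg.q_range[1], shape)
    Z = rng.standard_normal(shape)
    n_tot = cfg.design.n_total
    q_sample = rng.binomial(n_tot, q_pop) / n_tot

    if cfg.effect_dist.effect_scale == "sq_log_or":
        gamma = cfg.design.N * D * q_pop * (1.0 - q_pop)
    elif cfg.effect_dist.effect_scale == "standardized":
        gamma = cfg.design.N * D
    else:
        gamma = D
    gamma = np.where(is_null, 0.0, gamma)
    x = (Z + np.sqrt(gamma)) ** 2
    p = np.where(is_null, p_null, stats.chi2.sf(x, 1))
    # Guard the open-interval contract for downstream density evaluation.
    tiny = np.finfo(float).tiny
    p = np.clip(p, tiny, 1.0 - np.finfo(float).epsneg)
    return {"p": p, "is_null": is_null, "q_pop": q_pop,
            "q_sample": q_sample, "gamma_true": gamma}


def simulate_experiment(config: SimConfig, rep_index: int = 0) -> pd.DataFrame:
    """One experiment (K records) as a DataFrame, reproducible in isolation."""
    if rep_index < 0:
        raise DomainError("rep_index must be nonnegative")
    block = _simulate_chunk(config, rep_index // REP_CHUNK)
    row = rep_index % REP_CHUNK
    return pd.DataFrame({k: v[row] for k, v in block.items()})


def _bh_n_significant(p: np.ndarray, level: float = 0.10) -> np.ndarray:
    """Number of rejections of the Benjamini-Hochberg step-up per experiment."""
    K = p.shape[1]
    ps = np.sort(p, axis=1)
    ok = ps <= level * np.arange(1, K + 1) / K
    any_ok = ok.any(axis=1)
    last = K - 1 - np.argmax(ok[:, ::-1], axis=1)
    return np.where(any_ok, last + 1, 0)


def apply_retention(p, rule: str, m: int = 1) -> np.ndarray:
    """Which experiments survive a multiplicity-based retention rule.

    ``p`` is (n_experiments, K) or a single experiment's vector.
    ``bonferroni_0.05`` keeps an experiment iff min p <= 0.05/K;
    ``bh_0.10`` keeps it iff the ``m`` smallest P-values are all declared
    significant by the Benjamini-Hochberg step-up at level 10% over all K.
    """
    p = np.atleast_2d(np.asarray(p, dtype=float))
    K = p.shape[1]
    if rule == "none":
        out = np.ones(p.shape[0], dtype=bool)
    elif rule == "bonferroni_0.05":
        out = p.min(axis=1) <= 0.05 / K
    elif rule == "bh_0.10":
        out = _bh_n_significant(p, 0.10) >= m
    else:
        raise ConfigurationError(f"unknown retention rule {rule!r}")
    return out


def _sigma_for_records(cfg: SimConfig, q_sample: np.ndarray):
    scale = cfg.effect_dist.effect_scale
    if scale == "sq_log_or":
        return cfg.design.N * q_sample * (1.0 - q_sample)
    if scale == "standardized":
        return np.full_like(q_sample, float(cfg.design.N))
    return np.ones_like(q_sample)


def _log_marginal_exact_records(cfg: SimConfig, p, sigma):
    dist = cfg.effect_dist
    if dist.family == "point":
        return log_alt_pvalue_pdf(p, sigma * dist.value)
    if dist.shape == 1.0:
        return log_marginal_exponential(pvalue_to_statistic(p), sigma * dist.scale)
    # General shapes fall back to per-record adaptive quadrature.
    flat_p, flat_s = np.ravel(p), np.ravel(sigma)
    out = np.array([
        marginal_density_exact(
            float(pi),
            EffectSizeDistribution.gamma_prior(dist.shape, dist.scale * si),
            log=True,
        )
        for pi, si in zip(flat_p, flat_s)
    ])
    return out.reshape(np.shape(p))


def estimate_posteriors(records, estimator: str, config: SimConfig) -> np.ndarray:
    """Per-record posterior Pr(H0|p) from the P-value and sample frequency.

    ``estimator`` is one of ``exact`` (integration over the assumed
    effect-size prior), ``binned`` (three Fig-style bins plus a near-zero
    null bin, posterior over bins), or ``mean`` (prior-mean plug-in).
    The truth labels and hidden noncentralities are never consulted.
    """
    if isinstance(records, pd.DataFrame):
        p = records["p"].to_numpy()
        q_sample = records["q_sample"].to_numpy()
    else:
        p, q_sample = records
    p = np.asarray(p, dtype=float)
    q_sample = np.asarray(q_sample, dtype=float)
    sigma = _sigma_for_records(config, q_sample)
    log_prior_odds = (np.log1p(-config.pr_h0) - np.log(config.pr_h0)
                      if 0.0 < config.pr_h0 < 1.0 else None)

    if estimator == "exact":
        log_fbar = _log_marginal_exact_records(config, p, sigma)
    elif estimator == "mean":
        log_fbar = log_alt_pvalue_pdf(p, sigma * config.effect_dist.mean)
    elif estimator == "binned":
        table = discretize(config.effect_dist, n_bins=3)
        reps = table.rep_values() * 1.0  # on the prior's own scale
        weights = table.weights()
        gam = sigma[..., None] * reps
        log_alt = (np.log((1.0 - config.pr_h0) * weights / weights.sum())
                   + log_alt_pvalue_pdf(p[..., None], gam))
        gam0 = sigma * (NULL_BIN_D_REP if config.effect_dist.effect_scale == "sq_log_or"
                        else 0.0)
        log_null = np.log(config.pr_h0) + log_alt_pvalue_pdf(p, gam0)
        denom = np.logaddexp(log_null, special.logsumexp(log_alt, axis=-1))
        return np.exp(log_null - denom)
    else:
        raise ConfigurationError(f"unknown estimator {estimator!r}")
    if log_prior_odds is None:
        return np.full_like(p, config.pr_h0)
    return special.expit(-(log_prior_odds + log_fbar))


def _select_indices(cfg: SimConfig, p: np.ndarray) -> np.ndarray:
    """(n, m) column indices of the selected P-values per experiment."""
    if cfg.selection == "minp":
        return np.argmin(p, axis=1)[:, None]
    if cfg.selection == "top_m":
        idx = np.argpartition(p, cfg.m - 1, axis=1)[:, : cfg.m]
        return idx
    return np.tile(np.arange(p.shape[1]), (p.shape[0], 1))  # selection == none


def run_cell(config: SimConfig) -> SimResult:
    """Empirical and estimated spurious-signal proportions for one cell."""
    n_chunks = -(-config.n_reps // REP_CHUNK)
    emp_fracs, est_fracs = [], {est: [] for est in config.estimators}
    remaining = config.n_reps
    for chunk in range(n_chunks):
        block = _simulate_chunk(config, chunk)
        take = min(REP_CHUNK, remaining)
        remaining -= take
        p = block["p"][:take]
        is_null = block["is_null"][:take]
        q_sample = block["q_sample"][:take]

        keep = apply_retention(p, config.retention,
                               m=config.m if config.selection == "top_m" else 1)
        if not keep.any():
            continue
        sel = _select_indices(config, p)[keep]
        rows = np.arange(p.shape[0])[keep][:, None]
        emp_fracs.append(is_null[rows, sel].mean(axis=1))
        for est in config.estimators:
            post = estimate_posteriors(
                (p[rows, sel], q_sample[rows, sel]), est, config
            )
            est_fracs[est].append(post.mean(axis=1))

    if not emp_fracs:
        return SimResult(empirical=float("nan"), estimated={e: float("nan") for e in
                                                            config.estimators},
                         se=float("nan"), n_retained=0, n_reps=config.n_reps)
    emp = np.concatenate(emp_fracs)
    se = float(emp.std(ddof=1) / math.sqrt(emp.size)) if emp.size > 1 else float("nan")
    return SimResult(
        empirical=float(emp.mean()),
        estimated={est: float(np.concatenate(v).mean()) for est, v in est_fracs.items()},
        se=se,
        n_retained=int(emp.size),
        n_reps=config.n_reps,
    )


def run_table(configs: Sequence[SimConfig]) -> pd.DataFrame:
    """Run a grid of cells and tabulate W (empirical) and the estimators."""
    rows = []
    for cfg in configs:
        res = run_cell(cfg)
        row = {
            "K": cfg.K, "pr_h0": cfg.pr_h0, "selection": cfg.selection,
            "m": cfg.m, "retention": cfg.retention, "n_reps": cfg.n_reps,
            "n_retained": res.n_retained, "empirical": res.empirical, "se": res.se,
        }
        for est, val in res.estimated.items():
            row[f"est_{est}"] = val
        rows.append(row)
    return pd.DataFrame(rows)


def minp_null_fraction_large_k(K: int, pr_h0: float, design: StudyDesign,
                               n_reps: int, seed: int = 0,
                               effect_dist: EffectSizeDistribution = DEFAULT_EFFECT_DIST,
                               q_range: tuple = (0.05, 0.95)) -> SimResult:
    """Probability that the minP of a huge scan is spurious, by shortcut.

    For all-null experiments the minimum of n uniform P-values is
    Beta(1, n), so the null block of a K ~ 1e6 scan is drawn in one shot
    while the (few) genuine signals are simulated explicitly; an
    experiment's minP is spurious iff the null block's minimum undercuts
    the genuine minimum.  Validated against brute force at moderate K.
    """
    emp = []
    n_chunks = -(-n_reps // REP_CHUNK)
    remaining = n_reps
    for chunk in range(n_chunks):
        rng = _chunk_rng(seed, chunk)
        take = min(REP_CHUNK, remaining)
        remaining -= take
        n_gen = rng.binomial(K, 1.0 - pr_h0, size=take)
        total = int(n_gen.sum())
        D = _sample_effect(effect_dist, rng, total)
        q_pop = rng.uniform(q_range[0], q_range[1], total)
        gamma = design.N * D * q_pop * (1.0 - q_pop)
        Z = rng.standard_normal(total)
        p_gen = stats.chi2.sf((Z + np.sqrt(gamma)) ** 2, 1)
        mins = np.full(take, np.inf)
        nz = n_gen > 0
        if nz.any():
            offsets = np.concatenate([[0], np.cumsum(n_gen)[:-1]])
            mins[nz] = np.minimum.reduceat(p_gen, offsets[nz])
        p0 = rng.beta(1.0, np.maximum(K - n_gen, 1))
        emp.append(p0 < mins)
    emp = np.concatenate(emp)
    return SimResult(
        empirical=float(emp.mean()), estimated={},
        se=float(emp.std(ddof=1) / math.sqrt(emp.size)),
        n_retained=int(emp.size), n_reps=n_reps,
    )


def simulate_scan_replication(n_experiments: int = 1000, K: int = 10_000,
                              pr_h0: float = 0.99,
                              scan_design: StudyDesign = StudyDesign(8000, 8000),
                              repl_factor: int = 4,
                              effect_dist: EffectSizeDistribution = DEFAULT_EFFECT_DIST,
                              q_range: tuple = (0.05, 0.95),
                              seed: int = 0) -> pd.DataFrame:
    """Posterior streams for a scan minP, its replication, and the combination.

    Takes the smallest P-value of each simulated scan, re-evaluates the
    same effect (same D and population frequency, fresh noise) in a
    ``repl_factor`` times larger replication sample, and combines the two
    P-values by the direction-aware inverse-normal rule before converting
    to a posterior at the pooled design.  Replication and combined
    posteriors conservatively reuse the scan's effect-size prior.
    """
    if effect_dist.effect_scale != "sq_log_or":
        raise ConfigurationError("scan/replication simulation expects a "
                                 "squared-log-OR effect prior")
    repl_design = StudyDesign(scan_design.n1 * repl_factor,
                              scan_design.n2 * repl_factor)
    N_s, N_r = scan_design.N, repl_design.N
    frames = []
    n_chunks = -(-n_experiments // REP_CHUNK)
    remaining = n_experiments
    for chunk in range(n_chunks):
        rng = _chunk_rng(seed, chunk)
        take = min(REP_CHUNK, remaining)
        remaining -= take
        shape = (take, K)
        is_null = rng.random(shape) < pr_h0
        D = _sample_effect(effect_dist, rng, shape)
        q_pop = rng.uniform(q_range[0], q_range[1], shape)
        direction = np.where(rng.random(shape) < 0.5, 1.0, -1.0)
        gamma_s = np.where(is_null, 0.0, N_s * D * q_pop * (1.0 - q_pop))
        z1 = rng.standard_normal(shape) + direction * np.sqrt(gamma_s)
        p1 = stats.chi2.sf(z1 * z1, 1)
        idx = np.argmin(p1, axis=1)
        rows = np.arange(take)
        p1m, Dm, qm = p1[rows, idx], D[rows, idx], q_pop[rows, idx]
        nullm, dirm, z1m = is_null[rows, idx], direction[rows, idx], z1[rows, idx]

        gamma_r = np.where(nullm, 0.0, N_r * Dm * qm * (1.0 - qm))
        z2 = rng.standard_normal(take) + dirm * np.sqrt(gamma_r)
        p2 = stats.chi2.sf(z2 * z2, 1)

        q1 = rng.binomial(scan_design.n_total, qm) / scan_design.n_total
        q2 = rng.binomial(repl_design.n_total, qm) / repl_design.n_total
        tiny = np.finfo(float).tiny
        p1m, p2 = np.clip(p1m, tiny, 1 - 1e-16), np.clip(p2, tiny, 1 - 1e-16)

        log_prior_odds = np.log1p(-pr_h0) - np.log(pr_h0)

        def _post(p, sigma_scale):
            lf = log_marginal_exponential(pvalue_to_statistic(p),
                                          sigma_scale * effect_dist.scale)
            return special.expit(-(log_prior_odds + lf))

        post1 = _post(p1m, N_s * q1 * (1.0 - q1))
        post2 = _post(p2, N_r * q2 * (1.0 - q2))

        # Direction-aware inverse-normal combination, weights sqrt(N).
        w1, w2 = math.sqrt(N_s), math.sqrt(N_r)
        agree = np.where(np.sign(z1m) == np.sign(z2), 1.0, -1.0)
        pooled = (w1 * stats.norm.ppf(p1m / 2.0)
                  + agree * w2 * stats.norm.ppf(p2 / 2.0)) / math.hypot(w1, w2)
        pt = 2.0 * stats.norm.sf(np.abs(pooled))  # fold via the far tail
        pt = np.clip(pt, tiny, 1.0 - 1e-16)
        n_tot = scan_design.n_total + repl_design.n_total
        q_pool = (q1 * scan_design.n_total + q2 * repl_design.n_total) / n_tot
        post_c = _post(pt, (N_s + N_r) * q_pool * (1.0 - q_pool))

        frames.append(pd.DataFrame({
            "p_scan": p1m, "p_repl": p2, "p_combined": pt,
            "scan_post": post1, "repl_post": post2, "combined_post": post_c,
            "is_null": nullm, "D": Dm, "q_pop": qm,
        }))
    return pd.concat(frames, ignore_index=True)
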