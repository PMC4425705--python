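"""Summary-statistic tables, analysis configuration, and report assembly.

The input format is a TSV with a header; required columns are ``id`` and
``p`` (two-sided P-value, scientific notation welcome), optional columns
``sign``, ``q`` (pooled allele frequency), ``n1``/``n2`` (case/control
allele counts) and ``study``.  Reports mirror the input columns and
append posterior columns, so no information is lost.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .effects import BinTable, EffectSizeDistribution, read_bin_table
from .errors import ConfigurationError, SumstatsError
from .posterior import (
    PofigPosterior,
    fdr_estimate,
    fprp,
    prior_from_locus_counts,
)
from .pvalues import StudyDesign

__all__ = [
    "read_sumstats",
    "write_sumstats",
    "load_crohn_example",
    "AnalysisConfig",
    "run_analysis",
    "sensitivity_grid",
]

REQUIRED_COLUMNS = ("id", "p")
OPTIONAL_COLUMNS = ("sign", "q", "n1", "n2", "study")


def read_sumstats(path_or_buf) -> pd.DataFrame:
    """Read and validate an association summary-statistics TSV.

    P-values must lie in (0, 1]; offending rows are reported with their
    line numbers in the file (header = line 1, comments counted).
    """
    df = pd.read_csv(path_or_buf, sep="\t", comment="#", dtype={"id": str},
                     float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatsError(f"missing required column(s): {', '.join(missing)}")
    try:
        p = pd.to_numeric(df["p"], errors="raise").astype(float)
    except (ValueError, TypeError) as exc:
        raise SumstatsError(f"column 'p' is not numeric: {exc}") from exc
    df["p"] = p
    bad = ~((p > 0.0) & (p <= 1.0)) | ~np.isfinite(p)
    if bad.any():
        # +2: header line plus 1-based indexing (comment lines are skipped
        # by the parser, so line numbers refer to the data as read).
        lines = [int(i) + 2 for i in np.flatnonzero(bad.to_numpy())]
        raise SumstatsError(
            f"P-values outside (0, 1] on line(s) {', '.join(map(str, lines))}",
            lines=lines,
        )
    return df


def write_sumstats(df: pd.DataFrame, path_or_buf) -> None:
    """Write a report TSV with full float precision (17 significant digits)."""
    df.to_csv(path_or_buf, sep="\t", index=False, float_format="%.17g")


def load_crohn_example() -> pd.DataFrame:
    """The packaged Crohn's disease worked example (11 novel loci).

    Scan/replication/combined P-values for the newly identified loci of
    Barrett et al.'s 2008 Crohn's disease GWAS meta-analysis.
    """
    ref = importlib.resources.files("pofig.data") / "crohn_novel_loci.tsv"
    with ref.open("r") as fh:
        return read_sumstats(fh)


def _effect_dist_from_mapping(spec: dict):
    if "bin_table" in spec:
        return read_bin_table(spec["bin_table"])
    family = spec.get("family", "gamma")
    effect_scale = spec.get("effect_scale", "noncentrality")
    if family == "gamma":
        return EffectSizeDistribution.gamma_prior(
            float(spec["shape"]), float(spec["scale"]), effect_scale
        )
    if family == "point":
        return EffectSizeDistribution.point(float(spec["value"]), effect_scale)
    raise ConfigurationError(f"unknown effect-size family {family!r}")


@dataclass
class AnalysisConfig:
    """Declarative description of a posterior-conversion run.

    Exactly one prior form: either ``prior_h0`` directly or the locus-count
    pair ``n_loci``/``k_total`` (prior = 1 - n_loci/k_total).  Exactly one
    effect model: an :class:`EffectSizeDistribution`/:class:`BinTable` or a
    mapping as found in a YAML config file.
    """

    prior_h0: Optional[float] = None
    n_loci: Optional[int] = None
    k_total: Optional[int] = None
    effect_dist: object = None
    method: str = "exact"
    design: Optional[StudyDesign] = None
    with_fprp: bool = False
    p_columns: Sequence[str] = ("p",)
    seed: int = 0

    def resolve_prior(self) -> float:
        direct = self.prior_h0 is not None
        counts = self.n_loci is not None or self.k_total is not None
        if direct == counts:
            raise ConfigurationError(
                "specify exactly one prior form: prior_h0, or n_loci with k_total"
            )
        if direct:
            return float(self.prior_h0)
        if self.n_loci is None or self.k_total is None:
            raise ConfigurationError("locus-count prior needs both n_loci and k_total")
        return prior_from_locus_counts(self.n_loci, self.k_total)

    def resolve_effect_dist(self):
        if self.effect_dist is None:
            raise ConfigurationError("an effect-size model is required")
        if isinstance(self.effect_dist, (EffectSizeDistribution, BinTable)):
            return self.effect_dist
        if isinstance(self.effect_dist, dict):
            return _effect_dist_from_mapping(self.effect_dist)
        raise ConfigurationError(
            f"cannot interpret effect model of type {type(self.effect_dist).__name__}"
        )

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        design = None
        if "n1" in raw and "n2" in raw:
            design = StudyDesign(int(raw.pop("n1")), int(raw.pop("n2")))
        known = {k: raw[k] for k in
                 ("prior_h0", "n_loci", "k_total", "effect_dist", "method",
                  "with_fprp", "p_columns", "seed") if k in raw}
        return cls(design=design, **known)


def run_analysis(config: AnalysisConfig, sumstats: pd.DataFrame) -> pd.DataFrame:
    """Per-record posteriors for each requested P-value column.

    For every column named in ``config.p_columns`` a ``pr_h0|<col>`` and
    ``pofig|<col>`` pair is appended; when several columns are converted a
    density-product combined pair is added as well (order-invariant, equal
    to sequential prior updating).  The returned frame carries the FDR
    estimate for each posterior column in ``df.attrs["fdr"]``.
    """
    prior_h0 = config.resolve_prior()
    est = PofigPosterior(
        prior_h0=prior_h0,
        effect_dist=config.resolve_effect_dist(),
        method=config.method,
        design=config.design,
    ).fit()
    out = sumstats.copy()
    log_fbar_total = np.zeros(len(out))
    log_prior_odds = est.log_prior_odds_
    from scipy.special import expit

    cols = list(config.p_columns)
    if not cols:
        raise ConfigurationError("p_columns must name at least one column")
    for col in cols:
        if col not in out.columns:
            raise ConfigurationError(f"column {col!r} not present in the input")
        qhat = out["q"] if est.effect_scale_ == "sq_log_or" else None
        log_fbar = np.array([
            est.log_marginal(p, None if qhat is None else float(qhat.iloc[i]))
            for i, p in enumerate(out[col].astype(float))
        ])
        log_fbar_total += log_fbar
        out[f"pr_h0|{col}"] = expit(-(log_prior_odds + log_fbar))
        out[f"pofig|{col}"] = expit(log_prior_odds + log_fbar)
    if len(cols) > 1:
        out["pr_h0|combined"] = expit(-(log_prior_odds + log_fbar_total))
        out["pofig|combined"] = expit(log_prior_odds + log_fbar_total)
    if config.with_fprp:
        out["fprp"] = [
            fprp(float(p), prior_h0, config.resolve_effect_dist(),
                 est._ctx_for(None))
            for p in out[cols[0]].astype(float)
        ]
    out.attrs["fdr"] = {
        c.split("|", 1)[1]: fdr_estimate(out[c])
        for c in out.columns if c.startswith("pr_h0|")
    }
    return out


def sensitivity_grid(sumstats: pd.DataFrame,
                     priors: Sequence[float],
                     effect_dists: Sequence,
                     method: str = "exact",
                     design: Optional[StudyDesign] = None,
                     p_column: str = "p") -> pd.DataFrame:
    """Posterior Pr(H0|p) over a grid of priors x effect-size models.

    Long-format output with one row per (record, prior, model) — the
    layout used for sensitivity analyses of the posterior to the assumed
    proportion of susceptibility loci and effect-size distribution.
    """
    if not len(priors) or not len(effect_dists):
        raise ConfigurationError("sensitivity grid needs >= 1 prior and >= 1 model")
    rows = []
    for prior in priors:
        for dist in effect_dists:
            cfg = AnalysisConfig(prior_h0=prior, effect_dist=dist,
                                 method=method, design=design,
                                 p_columns=(p_column,))
            rep = run_analysis(cfg, sumstats)
            for _, r in rep.iterrows():
                rows.append({
                    "id": r["id"], "p": r[p_column], "prior_h0": prior,
                    "effect_dist": _describe_dist(dist),
                    "pr_h0_post": r[f"pr_h0|{p_column}"],
                })
    return pd.DataFrame(rows)


def _describe_dist(dist) -> str:
    if isinstance(dist, BinTable):
        return f"BinTable({len(dist.bins)} bins, {dist.effect_scale})"
    if dist.family == "gamma":
        return f"Gamma({dist.shape:g}, {dist.scale:g}) on {dist.effect_scale}"
    return f"point({dist.value:g}) on {dist.effect_scale}"
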