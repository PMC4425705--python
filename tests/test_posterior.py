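"""Posterior conversion: sharp null, bin mode, FPRP, FDR, estimator API."""

import math

import numpy as np
import pytest
from sklearn.base import clone

from pofig import (
    Bin,
    BinTable,
    ConfigurationError,
    DomainError,
    EffectSizeDistribution,
    PofigPosterior,
    ScaleContext,
    StudyDesign,
    discretize,
    fdr_estimate,
    fprp,
    marginal_density_exact,
    pofig_sharp,
    posterior_bins,
    prior_from_locus_counts,
)


def log_marginal_for(dist, ctx=None):
    return lambda p: marginal_density_exact(p, dist, ctx, log=True)


class TestPofigSharp:
    def test_uninformative_density_leaves_prior(self):
        res = pofig_sharp(0.37, 0.8, lambda p: 0.0)  # fbar = 1 everywhere
        assert res.pofig == pytest.approx(0.2, rel=1e-12)
        assert res.pr_h0_post == pytest.approx(0.8, rel=1e-12)

    def test_posterior_plus_complement_is_one(self, crohn_prior, exp_noncentrality_prior):
        res = pofig_sharp(1e-4, crohn_prior, log_marginal_for(exp_noncentrality_prior))
        assert res.pofig + res.pr_h0_post == pytest.approx(1.0, abs=1e-15)

    def test_degenerate_prior_returns_prior_with_warning(self):
        with pytest.warns(UserWarning):
            res = pofig_sharp(1e-8, 1.0, lambda p: 50.0)
        assert res.pr_h0_post == 1.0 and res.degenerate_prior

    def test_rank_preservation_on_noncentrality_prior(self, exp_noncentrality_prior):
        # With the prior directly on noncentralities, Pr(H0|p) increases in p.
        est = PofigPosterior(prior_h0=0.9, effect_dist=exp_noncentrality_prior).fit()
        ps = np.array([1e-10, 1e-7, 1e-4, 1e-2, 0.1, 0.5, 0.9])
        post = est.predict_proba(ps[:, None])[:, 0]
        assert np.all(np.diff(post) > 0)

    def test_posterior_can_exceed_prior_for_large_p(self, exp_noncentrality_prior):
        # Unlike FPRP, the density-based posterior has no prior ceiling.
        est = PofigPosterior(prior_h0=0.5, effect_dist=exp_noncentrality_prior).fit()
        post = est.predict_proba([[0.95]])[0, 0]
        assert post > 0.5

    def test_sequential_update_equals_density_product(self, exp_noncentrality_prior):
        lm = log_marginal_for(exp_noncentrality_prior)
        p1, p2, prior = 3e-4, 0.02, 0.97
        joint = pofig_sharp(p2, prior, lambda p: lm(p1) + lm(p))
        step1 = pofig_sharp(p1, prior, lm)
        seq = pofig_sharp(p2, step1.pr_h0_post, lm)
        assert seq.pr_h0_post == pytest.approx(joint.pr_h0_post, abs=1e-12)


class TestPosteriorBins:
    def _table(self, null_rep=1e-6):
        dist = EffectSizeDistribution.gamma_prior(1.0, 17.25)
        bins = discretize(dist, 3).bins
        null = Bin("null", null_rep, 1.0, 0.0, 2 * null_rep)
        return BinTable(bins=bins, null_bin=null)

    def test_identical_hypotheses_return_prior(self):
        bins = (Bin("a", 3.0, 1.0, 3.0, 3.0), Bin("b", 3.0, 1.0, 3.0, 3.0))
        table = BinTable(bins=bins, null_bin=Bin("null", 3.0, 1.0, 3.0, 3.0))
        priors = np.array([0.5, 0.3, 0.2])
        res = posterior_bins(0.01, table, priors)
        assert np.allclose(res.bin_posteriors, priors, atol=1e-12)

    def test_posteriors_sum_to_one_and_mean_within_range(self):
        table = self._table()
        res = posterior_bins(1e-5, table, [0.9, 0.05, 0.03, 0.02])
        assert res.bin_posteriors.sum() == pytest.approx(1.0, abs=1e-12)
        reps = table.rep_values(include_null=True)
        assert reps.min() <= res.post_mean_effect <= reps.max()

    def test_matches_sharp_null_to_reported_precision(self, crohn_prior):
        # A near-zero null bin and the sharp null agree to 2 decimals.
        dist = EffectSizeDistribution.gamma_prior(1.0, 17.25)
        table3 = discretize(dist, 3)
        table = BinTable(bins=table3.bins, null_bin=Bin("null", 1e-8, 1.0, 0.0, 2e-8))
        w = table3.weights()
        priors = np.concatenate([[crohn_prior], (1 - crohn_prior) * w / w.sum()])
        for p in [1.81e-5, 1e-3, 0.05]:
            res_bins = posterior_bins(p, table, priors)
            sharp = pofig_sharp(p, crohn_prior, lambda q: _binned_log(q, table3))
            assert res_bins.pr_h0_post == pytest.approx(sharp.pr_h0_post, abs=5e-3)

    def test_largest_bin_gains_mass_as_p_shrinks(self):
        table = self._table()
        posts = [posterior_bins(p, table, [0.7, 0.1, 0.1, 0.1]).bin_posteriors[-1]
                 for p in [1e-2, 1e-4, 1e-6, 1e-8, 1e-10]]
        assert np.all(np.diff(posts) > 0)

    def test_prior_length_mismatch(self):
        with pytest.raises(ConfigurationError):
            posterior_bins(0.01, self._table(), [0.5, 0.5])

    def test_requires_null_bin(self):
        table = discretize(EffectSizeDistribution.gamma_prior(1.0, 1.0), 3)
        with pytest.raises(ConfigurationError):
            posterior_bins(0.01, table)


def _binned_log(p, table):
    from pofig import marginal_density_binned

    return marginal_density_binned(p, table, log=True)


class TestFprp:
    def test_powerless_test_returns_prior(self):
        # A point-mass-at-zero effect prior gives Fbar(alpha) = alpha.
        dist = EffectSizeDistribution.point(0.0)
        assert fprp(0.05, 0.9, dist) == pytest.approx(0.9, rel=1e-10)

    @pytest.mark.parametrize("alpha", [1e-8, 1e-4, 0.05, 0.5, 0.99])
    def test_never_exceeds_prior(self, alpha, exp_noncentrality_prior):
        assert fprp(alpha, 0.9, exp_noncentrality_prior) <= 0.9 + 1e-12

    def test_smaller_than_density_posterior_at_observed_p(
        self, crohn_prior, exp_noncentrality_prior
    ):
        alpha = 8.80e-9
        tail = fprp(alpha, crohn_prior, exp_noncentrality_prior)
        dens = pofig_sharp(alpha, crohn_prior,
                           log_marginal_for(exp_noncentrality_prior)).pr_h0_post
        assert tail < dens

    def test_domain_errors(self, exp_noncentrality_prior):
        with pytest.raises(DomainError):
            fprp(0.0, 0.9, exp_noncentrality_prior)


class TestFdrEstimate:
    def test_singleton_and_mean(self):
        assert fdr_estimate([0.2]) == 0.2
        assert fdr_estimate([0.1, 0.3]) == pytest.approx(0.2)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            fdr_estimate([])


class TestPriorFromLocusCounts:
    def test_arithmetic(self):
        assert prior_from_locus_counts(142, 12877) == pytest.approx(1 - 142 / 12877)

    def test_invalid_counts(self):
        with pytest.raises(ConfigurationError):
            prior_from_locus_counts(10, 10)


class TestEstimatorApi:
    def test_get_set_params_and_clone(self, exp_noncentrality_prior):
        est = PofigPosterior(prior_h0=0.7, effect_dist=exp_noncentrality_prior,
                             method="mean")
        assert est.get_params()["prior_h0"] == 0.7
        est2 = clone(est).set_params(prior_h0=0.8)
        assert est2.prior_h0 == 0.8 and est.prior_h0 == 0.7

    def test_fit_validates_and_sets_trailing_underscore_attrs(
        self, exp_noncentrality_prior
    ):
        est = PofigPosterior(prior_h0=0.9, effect_dist=exp_noncentrality_prior).fit()
        assert est.log_prior_odds_ == pytest.approx(math.log(1 / 9), rel=1e-10)
        with pytest.raises(ConfigurationError):
            PofigPosterior(prior_h0=1.5, effect_dist=exp_noncentrality_prior).fit()
        with pytest.raises(ConfigurationError):
            PofigPosterior(prior_h0=0.5).fit()  # no effect model

    def test_methods_agree_for_point_prior(self):
        dist = EffectSizeDistribution.point(12.0)
        X = [[1e-4], [0.01], [0.3]]
        probs = {
            m: PofigPosterior(0.9, dist, method=m).fit().predict_proba(X)[:, 0]
            for m in ("exact", "mean")
        }
        assert np.allclose(probs["exact"], probs["mean"], rtol=1e-12)

    def test_sq_log_or_scale_needs_frequency_column(self):
        dist = EffectSizeDistribution.gamma_prior(1.0, 0.01, "sq_log_or")
        est = PofigPosterior(0.9, dist, design=StudyDesign(400, 400)).fit()
        with pytest.raises(ConfigurationError):
            est.predict_proba([[1e-4]])
        probs = est.predict_proba([[1e-4, 0.3]])
        assert 0 < probs[0, 0] < 1

    def test_predict_thresholds_at_half(self, exp_noncentrality_prior):
        est = PofigPosterior(0.9, exp_noncentrality_prior).fit()
        labels = est.predict([[1e-9], [0.9]])
        assert list(labels) == [1, 0]

    def test_fdr_shortcut(self, crohn_prior, exp_noncentrality_prior):
        est = PofigPosterior(crohn_prior, exp_noncentrality_prior).fit()
        X = [[1e-6], [1e-4]]
        assert est.fdr(X) == pytest.approx(est.predict_proba(X)[:, 0].mean())
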