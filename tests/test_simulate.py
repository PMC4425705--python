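"""The selection-effect simulation study: generator, retention, calibration."""

import numpy as np
import pytest
from scipy import stats

from pofig import (
    EffectSizeDistribution,
    SimConfig,
    StudyDesign,
    apply_retention,
    estimate_posteriors,
    minp_null_fraction_large_k,
    run_cell,
    run_table,
    simulate_experiment,
    simulate_scan_replication,
)
from pofig.simulate import REP_CHUNK, _simulate_chunk


class TestGenerator:
    def test_all_null_pvalues_are_uniform(self):
        cfg = SimConfig(K=1000, pr_h0=1.0, n_reps=128, seed=5)
        p = np.concatenate([_simulate_chunk(cfg, c)["p"].ravel() for c in range(1)])
        assert stats.kstest(p[:100_000], "uniform").pvalue > 1e-3

    def test_zero_effect_alternatives_are_uniform(self):
        cfg = SimConfig(
            K=1000, pr_h0=0.0, n_reps=128, seed=6,
            effect_dist=EffectSizeDistribution.point(0.0, "sq_log_or"),
        )
        p = _simulate_chunk(cfg, 0)["p"].ravel()
        assert stats.kstest(p[:100_000], "uniform").pvalue > 1e-3

    def test_null_label_fraction_binomial(self):
        cfg = SimConfig(K=10_000, pr_h0=0.5, seed=7)
        is_null = _simulate_chunk(cfg, 0)["is_null"]
        n = is_null.size
        se = np.sqrt(0.25 / n)
        assert abs(is_null.mean() - 0.5) <= 3 * se

    def test_truth_labels_consistent_with_noncentrality(self):
        df = simulate_experiment(SimConfig(K=500, pr_h0=0.4, seed=8), rep_index=3)
        assert (df.loc[df.is_null, "gamma_true"] == 0).all()
        assert (df.loc[~df.is_null, "gamma_true"] > 0).all()
        assert df.p.between(0, 1, inclusive="neither").all()

    def test_replicate_reproducible_in_isolation(self):
        cfg = SimConfig(K=20, pr_h0=0.5, seed=9)
        a = simulate_experiment(cfg, rep_index=300)
        b = simulate_experiment(cfg, rep_index=300)
        assert a.equals(b)
        # and matches the row inside its generation chunk
        block = _simulate_chunk(cfg, 300 // REP_CHUNK)
        assert np.array_equal(a["p"].to_numpy(), block["p"][300 % REP_CHUNK])


class TestRetention:
    def test_bonferroni_threshold(self):
        p = np.full((1, 10), 0.9)
        p[0, 3] = 0.004  # < 0.05/10
        assert apply_retention(p, "bonferroni_0.05")[0]
        p[0, 3] = 0.006
        assert not apply_retention(p, "bonferroni_0.05")[0]

    def test_nothing_significant_never_retained(self):
        p = np.ones((2, 10))
        assert not apply_retention(p, "bonferroni_0.05").any()
        assert not apply_retention(p, "bh_0.10", m=1).any()

    def test_bh_step_up_hand_oracle(self):
        # Hand-executed step-up at level 0.10 over K=10: sorted p
        # (0.001..0.005, rest 1); p(5)=0.005 <= 0.10*5/10 so all five
        # smallest are significant and the experiment is retained at m=5.
        p = np.array([[0.001, 0.002, 0.003, 0.004, 0.005, 1, 1, 1, 1, 1]])
        assert apply_retention(p, "bh_0.10", m=5)[0]
        # Raising the 5th above its step-up bound but keeping one rejection:
        p2 = np.array([[0.001, 0.002, 0.003, 0.004, 0.06, 1, 1, 1, 1, 1]])
        assert not apply_retention(p2, "bh_0.10", m=5)[0]
        assert apply_retention(p2, "bh_0.10", m=4)[0]

    def test_bh_step_up_rescues_smaller_ranks(self):
        # Step-up: a significant higher rank rescues everything below it.
        p = np.array([[0.09, 0.095, 0.096, 0.097, 0.098, 0.0999, 0.59, 0.6, 0.7, 1.0]])
        # p(6)=0.0999 > 0.06 = 0.1*6/10 fails ... check the actual bound:
        # thresholds are 0.01..0.10; p(1..6) all exceed their own bound
        # except none, so nothing is significant here.
        assert not apply_retention(p, "bh_0.10", m=1)[0]
        p[0, 0] = 0.005  # now p(1)=0.005 <= 0.01
        assert apply_retention(p, "bh_0.10", m=1)[0]


class TestEstimators:
    def test_exact_estimator_never_reads_truth(self):
        cfg = SimConfig(K=50, pr_h0=0.5, seed=11)
        df = simulate_experiment(cfg, 0)
        post = estimate_posteriors(df, "exact", cfg)
        shuffled = df.copy()
        shuffled["is_null"] = ~shuffled["is_null"]
        assert np.array_equal(post, estimate_posteriors(shuffled, "exact", cfg))

    def test_estimators_bounded_and_ordered_at_extremes(self):
        cfg = SimConfig(K=100, pr_h0=0.9, seed=12)
        df = simulate_experiment(cfg, 0)
        for est in ("exact", "binned", "mean"):
            post = estimate_posteriors(df, est, cfg)
            assert np.all((post > 0) & (post < 1))

    def test_binned_matches_exact_to_two_decimals_on_minp(self):
        cfg = SimConfig(K=10, pr_h0=0.5, n_reps=4000, seed=13,
                        estimators=("exact", "binned"))
        res = run_cell(cfg)
        assert res.estimated["binned"] == pytest.approx(res.estimated["exact"],
                                                        abs=5e-3)

    def test_mean_estimator_conservative_on_extreme_selection(self):
        # At a deep minP selection the prior-mean plug-in overstates Pr(H0|p).
        cfg = SimConfig(K=200, pr_h0=0.9, n_reps=2000, seed=14,
                        estimators=("exact", "mean"))
        res = run_cell(cfg)
        assert res.estimated["mean"] >= res.estimated["exact"] - 0.01


class TestCalibration:
    @pytest.mark.parametrize("cfg, label", [
        (SimConfig(K=10, pr_h0=0.5, n_reps=6000, seed=21), "minP, no retention"),
        (SimConfig(K=10, pr_h0=0.9, n_reps=6000, seed=22,
                   retention="bonferroni_0.05"), "minP, Bonferroni-retained"),
        (SimConfig(K=100, pr_h0=0.5, n_reps=2000, seed=23,
                   selection="top_m", m=5), "top-5, no retention"),
        (SimConfig(K=10, pr_h0=0.5, n_reps=200_000, seed=24,
                   selection="top_m", m=5, retention="bh_0.10"), "top-5, BH-retained"),
    ])
    def test_exact_estimator_matches_empirical_fraction(self, cfg, label):
        """Mean estimated Pr(H0|p) equals the empirical spurious fraction in
        the selection, whatever the selection or retention rule."""
        res = run_cell(cfg)
        assert res.n_retained > 30, label
        assert abs(res.estimated["exact"] - res.empirical) <= 3 * res.se, label

    def test_enrichment_of_top_hits_with_more_tests(self):
        # With the design and prior fixed, the minP is less often spurious
        # as K grows: selection enriches for genuine signals.
        ws = [run_cell(SimConfig(K=K, pr_h0=0.5, n_reps=3000, seed=25,
                                 estimators=())).empirical
              for K in (10, 100, 1000)]
        assert ws[0] > ws[1] > ws[2]

    def test_determinism(self):
        cfg = SimConfig(K=10, pr_h0=0.5, n_reps=1000, seed=31)
        assert run_cell(cfg) == run_cell(cfg)

    def test_run_table_layout(self):
        df = run_table([SimConfig(K=10, pr_h0=0.5, n_reps=500, seed=32),
                        SimConfig(K=10, pr_h0=0.9, n_reps=500, seed=32)])
        assert list(df["pr_h0"]) == [0.5, 0.9]
        assert {"empirical", "se", "est_exact"}.issubset(df.columns)


class TestLargeKShortcut:
    def test_beta_shortcut_matches_brute_force(self):
        # Same W from the Beta(1, n_null) shortcut and the explicit
        # generator at K=2000, within joint Monte-Carlo error.
        K, pr_h0 = 2000, 1 - 50 / 2000
        design = StudyDesign(2000, 2000)
        brute = run_cell(SimConfig(K=K, pr_h0=pr_h0, design=design,
                                   n_reps=3000, seed=41, estimators=()))
        quick = minp_null_fraction_large_k(K, pr_h0, design, n_reps=3000, seed=42)
        se = np.hypot(brute.se, quick.se)
        assert abs(brute.empirical - quick.empirical) <= 3 * se

    def test_all_null_minp_is_beta(self):
        res = minp_null_fraction_large_k(10**6, 1.0, StudyDesign(2000, 2000),
                                         n_reps=500, seed=43)
        assert res.empirical == 1.0  # no genuine signal can undercut


@pytest.fixture(scope="module")
def streams():
    return simulate_scan_replication(
        n_experiments=600, K=300, pr_h0=0.95,
        scan_design=StudyDesign(2000, 2000), seed=51,
    )


class TestScanReplication:

    def test_null_scan_minp_gives_uniform_replication(self, streams):
        p_repl = streams.loc[streams.is_null, "p_repl"]
        assert len(p_repl) > 50
        assert stats.kstest(p_repl, "uniform").pvalue > 1e-3

    def test_replication_effect_reuse_scales_with_sample_size(self):
        # A genuine minP's replication noncentrality is N_repl*D*q(1-q):
        # with a 4x sample the genuine replication P-values must be far
        # smaller than the scan's on average (stochastic identity check).
        df = simulate_scan_replication(n_experiments=400, K=100, pr_h0=0.2,
                                       scan_design=StudyDesign(2000, 2000), seed=52)
        genuine = df[~df.is_null]
        assert np.median(genuine.p_repl) < np.median(genuine.p_scan)

    def test_combined_posteriors_more_u_shaped(self, streams):
        mid = lambda s: np.mean((s > 0.2) & (s < 0.8))
        assert mid(streams.combined_post) < mid(streams.scan_post)

    def test_posterior_streams_bounded(self, streams):
        for col in ("scan_post", "repl_post", "combined_post"):
            assert streams[col].between(0, 1).all()
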