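import numpy as np
import pytest
from scipy import stats

from latentlens import (
    SynthSpec,
    aggregate_evaluation,
    aggregate_projection,
    bca_interval,
    bootstrap_models,
    contribution_intervals,
    fit_transform_train,
    generate,
)
from latentlens.bootstrap_infer import (
    _match_components,
    confidence_ellipse,
    percentile_interval,
)


@pytest.fixture(scope="module")
def ensemble(scaled_data):
    X, y, _ = scaled_data
    return bootstrap_models(X, y, "pls", {"n_components": 2}, r=100, seed=2)


class TestBCa:
    def test_reduces_to_percentile_when_unbiased_and_symmetric(self):
        # replicates 1..100 with the observed value at the median: z0 = 0,
        # a = 0, so BCa equals the plain percentile interval
        reps = np.arange(1.0, 101.0)
        lo, hi = bca_interval(reps, 50.5)
        assert lo == pytest.approx(3.0, abs=0.01)
        assert hi == pytest.approx(98.0, abs=0.01)
        plo, phi = percentile_interval(reps)
        assert (lo, hi) == pytest.approx((plo, phi), abs=1e-10)

    def test_symmetric_jackknife_keeps_acceleration_zero(self, rng):
        reps = rng.normal(0, 1, 500)
        obs = np.median(reps)
        jk = np.linspace(-1, 1, 30)     # symmetric: skewness term vanishes
        no_jk = bca_interval(reps, obs)
        with_jk = bca_interval(reps, obs, jackknife=jk)
        assert no_jk == pytest.approx(with_jk, abs=1e-9)

    def test_shift_equivariance(self, rng):
        reps = rng.normal(2, 1, 200)
        lo, hi = bca_interval(reps, 2.1)
        lo2, hi2 = bca_interval(reps + 7, 9.1)
        assert (lo2 - lo, hi2 - hi) == pytest.approx((7, 7), abs=1e-9)

    def test_degenerate_replicates_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            lo, hi = bca_interval(np.ones(50), 1.0)
        assert lo == hi == 1.0

    def test_observed_outside_range_clamped_with_warning(self, rng):
        reps = rng.normal(0, 1, 100)
        with pytest.warns(UserWarning, match="clamped"):
            lo, hi = bca_interval(reps, reps.max() + 10)
        assert np.isfinite([lo, hi]).all()

    def test_bias_correction_moves_interval_toward_observed(self, rng):
        reps = rng.normal(0, 1, 500)
        hi_obs = np.quantile(reps, 0.8)      # observed above replicate centre
        lo_b, hi_b = bca_interval(reps, hi_obs)
        lo_p, hi_p = percentile_interval(reps)
        assert lo_b > lo_p and hi_b > hi_p


class TestEnsemble:
    def test_in_bag_multiset_and_out_of_bag_complement(self, ensemble):
        n = ensemble.n_samples
        for b in range(0, ensemble.r, 25):
            ib, oob = ensemble.ib_indices[b], ensemble.oob_indices[b]
            assert len(ib) == n
            np.testing.assert_array_equal(
                np.sort(oob), np.setdiff1d(np.arange(n), ib))

    def test_mean_oob_fraction_near_closed_form(self, ensemble):
        n = ensemble.n_samples
        expect = (1 - 1 / n) ** n           # P(a sample is never drawn)
        frac = ensemble.oob_fractions()
        se = frac.std(ddof=1) / np.sqrt(len(frac))
        assert abs(frac.mean() - expect) < 3 * max(se, 1e-3)

    def test_deterministic_given_seed(self, scaled_data):
        X, y, _ = scaled_data
        a = bootstrap_models(X, y, "pls", {"n_components": 2}, r=5, seed=8)
        b = bootstrap_models(X, y, "pls", {"n_components": 2}, r=5, seed=8)
        np.testing.assert_array_equal(a.yhat, b.yhat)
        np.testing.assert_array_equal(a.weights, b.weights)
        for ia, ib in zip(a.ib_indices, b.ib_indices):
            np.testing.assert_array_equal(ia, ib)

    def test_orientation_harmonisation_improves_alignment(self, scaled_data):
        X, y, _ = scaled_data
        ens = bootstrap_models(X, y, "ann",
                               {"n_hidden": 2, "learning_rate": 0.03},
                               r=20, seed=4)
        ref = ens.reference.x_weights
        cors = []
        for b in range(ens.r):
            for k in range(2):
                cors.append(np.corrcoef(ref[:, k], ens.weights[b, :, k])[0, 1])
        # after sign/permutation matching, alignment is systematically positive
        assert np.mean(cors) > 0.5
        assert np.mean(np.array(cors) > 0) > 0.9

    def test_greedy_matcher_recovers_known_scramble(self, rng):
        ref = rng.normal(size=(30, 3))
        perm_true = np.array([2, 0, 1])
        signs_true = np.array([1.0, -1.0, 1.0])
        scrambled = ref[:, perm_true] * signs_true
        # invert: column j of scrambled is ref column perm_true[j]
        perm, signs = _match_components(ref, scrambled)
        np.testing.assert_array_equal(
            scrambled[:, perm] * signs, ref)

    def test_oob_auc_not_above_ib_auc(self, ensemble):
        ev = aggregate_evaluation(ensemble)
        # expectation-level check: medians ordered (single inversions among
        # resamples are fine)
        assert ev.oob_auc_median <= ev.ib_auc_median + 1e-9

    def test_separable_data_collapses_cis_near_one(self, ensemble):
        ev = aggregate_evaluation(ensemble)
        assert ev.ib_auc_ci[0] > 0.9
        assert ev.oob_auc_ci[0] > 0.8
        assert ev.oob_auc_ci[1] <= 1.0

    def test_null_data_oob_ci_covers_half(self):
        pt, _ = generate(SynthSpec(seed=41, effect_size=0.0))
        X, _ = fit_transform_train(pt.X)
        ens = bootstrap_models(X, pt.class_labels.astype(float), "pls",
                               {"n_components": 1}, r=60, seed=1)
        ev = aggregate_evaluation(ens)
        assert ev.oob_auc_ci[0] < 0.5 < ev.oob_auc_ci[1] + 0.05


class TestProjection:
    def test_aggregate_scores_masking(self, ensemble):
        proj = aggregate_projection(ensemble)
        ib, oob = ensemble.membership()
        i = 0
        sel = ib[:, i]
        np.testing.assert_allclose(
            proj.agg_ib_scores[i], ensemble.scores[sel, i, :].mean(axis=0))
        sel = oob[:, i]
        np.testing.assert_allclose(
            proj.agg_oob_scores[i], ensemble.scores[sel, i, :].mean(axis=0))

    def test_never_oob_sample_flagged_missing(self, scaled_data):
        X, y, _ = scaled_data
        ens = bootstrap_models(X, y, "pls", {"n_components": 2}, r=3, seed=0)
        proj = aggregate_projection(ens)
        if len(proj.never_oob):
            assert np.isnan(proj.agg_oob_scores[proj.never_oob]).all()
        ib, oob = ens.membership()
        np.testing.assert_array_equal(proj.never_oob,
                                      np.nonzero(~oob.any(axis=0))[0])

    def test_isotropic_population_ellipse_radius(self, rng):
        pts = rng.normal(size=(20000, 2))
        _, semi, _ = confidence_ellipse(pts, "population")
        np.testing.assert_allclose(semi, np.sqrt(stats.chi2.ppf(0.95, 2)),
                                   rtol=0.03)

    def test_mean_ellipse_shrinks_as_sqrt_n(self, rng):
        pts = rng.normal(size=(6400, 2))
        _, semi_all, _ = confidence_ellipse(pts, "mean")
        _, semi_quarter, _ = confidence_ellipse(pts[:1600], "mean")
        np.testing.assert_allclose(semi_quarter / semi_all, 2.0, rtol=0.15)

    def test_ellipses_present_for_each_pair_and_class(self, ensemble):
        proj = aggregate_projection(ensemble)
        assert set(proj.ellipses) == {(0, 1)}
        for cls in (0, 1):
            for split in ("ib", "oob"):
                for kind in ("mean", "population"):
                    centre, semi, _ = proj.ellipses[(0, 1)][cls][split][kind]
                    assert np.isfinite(centre).all() and np.all(semi >= 0)


class TestContributionIntervals:
    def test_median_and_significance_structure(self, ensemble, scaled_data):
        _, _, truth = scaled_data
        tab = contribution_intervals(ensemble, "B_PLS")
        assert np.all(tab.ci_low <= tab.ci_high)
        # the BCa interval is bias-corrected toward the full-data estimate,
        # so it need not bracket the replicate median, but it should stay in
        # the replicate range
        reps = ensemble.contributions["B_PLS"]
        assert np.all(tab.ci_low >= reps.min(axis=0) - 1e-12)
        assert np.all(tab.ci_high <= reps.max(axis=0) + 1e-12)
        # planted discriminating features come out significant
        assert np.asarray(tab.significant)[truth.informative_idx].all()

    def test_vip_intervals_flag_lower_bound_above_one(self, ensemble):
        tab = contribution_intervals(ensemble, "VIP")
        np.testing.assert_array_equal(tab.significant, tab.ci_low > 1.0)
        assert tab.threshold == 1.0

    def test_percentile_method_option(self, ensemble):
        tab = contribution_intervals(ensemble, "B_PLS", method="percentile")
        reps = ensemble.contributions["B_PLS"]
        lo, hi = percentile_interval(reps[:, 0])
        assert tab.ci_low[0] == pytest.approx(lo)
        assert tab.ci_high[0] == pytest.approx(hi)

    def test_unstored_metric_rejected(self, ensemble):
        with pytest.raises(ValueError, match="not stored"):
            contribution_intervals(ensemble, "Garson")

    def test_null_feature_interval_crosses_zero(self):
        # pure-noise features: signed contribution CI should include 0
        pt, truth = generate(SynthSpec(seed=51, effect_size=0.0))
        X, _ = fit_transform_train(pt.X)
        ens = bootstrap_models(X, pt.class_labels.astype(float), "pls",
                               {"n_components": 1}, r=100, seed=6)
        # percentile intervals are close to nominal on null features; the
        # bias-corrected default trades some null coverage for power
        tab_pct = contribution_intervals(ens, "B_PLS", method="percentile")
        crossing_pct = (tab_pct.ci_low <= 0) & (tab_pct.ci_high >= 0)
        assert crossing_pct.mean() > 0.9
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            tab = contribution_intervals(ens, "B_PLS")
        crossing = (tab.ci_low <= 0) & (tab.ci_high >= 0)
        assert crossing.mean() > 0.75
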