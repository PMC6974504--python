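import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from latentlens import (
    SynthSpec,
    auc,
    cv_search,
    expand_grid,
    fit_transform_train,
    generate,
    permutation_test,
    r2_q2,
    select_hyperparameters,
)
from latentlens.validate import CVGrid, make_partitions


def _pair_count_auc(y, s):
    """O(n^2) oracle: concordant pairs plus half ties over all case/control
    pairs."""
    y = np.asarray(y)
    s = np.asarray(s, float)
    pos, neg = s[y == 1], s[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        assert auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0

    def test_all_tied_scores(self):
        assert auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = rng.integers(0, 2, 10)
        while np.unique(y).size < 2:
            y = rng.integers(0, 2, 10)
        s = rng.choice([0.1, 0.3, 0.5, 0.7], 10)   # ties on purpose
        assert auc(y, s) == pytest.approx(_pair_count_auc(y, s), abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = rng.integers(0, 2, 20)
        y[:2] = [0, 1]
        s = rng.normal(size=20)
        assert auc(y, s) == pytest.approx(auc(y, np.exp(3 * s)), abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="one class"):
            auc([1, 1, 1], [0.1, 0.2, 0.3])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        y=st.lists(st.integers(0, 1), min_size=4, max_size=15).filter(
            lambda v: 0 < sum(v) < len(v)),
        data=st.data(),
    )
    def test_pair_counting_property(self, y, data):
        s = data.draw(st.lists(
            st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
            min_size=len(y), max_size=len(y)))
        assert auc(y, s) == pytest.approx(_pair_count_auc(y, s), abs=1e-12)


class TestR2Q2:
    def test_perfect_fit_gives_r2_one(self):
        y = np.array([0, 1, 0, 1, 1.0])
        r2, _ = r2_q2(y, y, y * 0)
        assert r2 == pytest.approx(1.0)

    def test_mean_prediction_gives_q2_zero(self):
        y = np.array([0, 0, 1, 1, 1.0])
        _, q2 = r2_q2(y, y, np.full(5, y.mean()))
        assert q2 == pytest.approx(0.0)

    def test_hand_worked_six_sample_example(self):
        y = np.array([0, 0, 0, 1, 1, 1.0])
        y_fit = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
        y_cv = np.array([0.3, 0.4, 0.6, 0.5, 0.6, 0.7])
        ss_tot = 1.5            # 6 deviations of 0.5 squared
        ss_res = 0.01 + 0.04 + 0.09 + 0.09 + 0.04 + 0.01   # 0.28
        press = 0.09 + 0.16 + 0.36 + 0.25 + 0.16 + 0.09    # 1.11
        r2, q2 = r2_q2(y, y_fit, y_cv)
        assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-12)
        assert q2 == pytest.approx(1 - press / ss_tot, abs=1e-12)

    def test_q2_can_be_negative(self):
        y = np.array([0, 0, 1, 1.0])
        _, q2 = r2_q2(y, y, 1 - y)
        assert q2 < 0


class TestCVSearch:
    @pytest.fixture(scope="class")
    def data(self):
        pt, _ = generate(SynthSpec(seed=21))
        X, _ = fit_transform_train(pt.X)
        return X, pt.class_labels.astype(float)

    def test_single_combination_grid(self, data):
        X, y = data
        cv = cv_search(X, y, "pls", [{"n_components": 2}],
                       folds=5, repartitions=2, seed=0)
        assert len(cv) == 1
        row = cv.table.iloc[0]
        assert np.isfinite([row.R2_full, row.Q2_cv, row.AUC_full,
                            row.AUC_cv]).all()
        assert 0 <= row.AUC_cv <= 1

    def test_duplicate_combination_gives_identical_rows(self, data):
        X, y = data
        cv = cv_search(X, y, "pls", [{"n_components": 2}, {"n_components": 2}],
                       folds=5, repartitions=2, seed=0)
        pd.testing.assert_series_equal(cv.table.iloc[0], cv.table.iloc[1],
                                       check_names=False)

    def test_deterministic_given_seed(self, data):
        X, y = data
        grid = expand_grid(n_components=[1, 2])
        a = cv_search(X, y, "pls", grid, folds=3, repartitions=2, seed=9)
        b = cv_search(X, y, "pls", grid, folds=3, repartitions=2, seed=9)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_partitions_paired_across_grid(self, data):
        _, y = data
        a = make_partitions(y, folds=5, repartitions=3, seed=4)
        b = make_partitions(y, folds=5, repartitions=3, seed=4)
        for pa, pb in zip(a, b):
            for (tra, vaa), (trb, vab) in zip(pa, pb):
                np.testing.assert_array_equal(vaa, vab)
        # folds cover every sample exactly once, stratified
        for part in a:
            concat = np.sort(np.concatenate([va for _, va in part]))
            np.testing.assert_array_equal(concat, np.arange(len(y)))
            assert all(np.unique(y[va]).size == 2 for _, va in part)

    def test_q2_peaks_near_true_latent_dimension(self):
        # rank-2 latent structure: the Q2-optimal component count should be
        # at or adjacent to 2
        hits = 0
        for seed in (1, 2, 3):
            pt, _ = generate(SynthSpec(seed=seed))
            X, _ = fit_transform_train(pt.X)
            cv = cv_search(X, pt.class_labels.astype(float), "pls",
                           expand_grid(n_components=[1, 2, 3, 4, 5, 6]),
                           folds=5, repartitions=3, seed=seed)
            best_k = int(cv.table.loc[cv.table.Q2_cv.idxmax(), "n_components"])
            hits += best_k in (1, 2, 3)
        assert hits >= 2

    def test_empty_grid_rejected(self, data):
        X, y = data
        with pytest.raises(ValueError, match="empty"):
            cv_search(X, y, "pls", [])


def _grid_from_points(points):
    """CVGrid stub with prescribed (|R2-Q2|, Q2) coordinates."""
    rows = [{"n_components": i + 1, "R2_full": q + gap, "Q2_cv": q,
             "AUC_full": 1.0, "AUC_cv": 0.9, "Q2_cv_sd": 0.0, "AUC_cv_sd": 0.0}
            for i, (gap, q) in enumerate(points)]
    return CVGrid(family="pls",
                  grid=[{"n_components": i + 1} for i in range(len(points))],
                  table=pd.DataFrame(rows), folds=5, repartitions=1, seed=0)


class TestHyperparameterSelection:
    def test_dominating_point_selected(self):
        cv = _grid_from_points([(0.1, 0.5), (0.05, 0.7), (0.2, 0.6), (0.3, 0.4)])
        sel = select_hyperparameters(cv)
        assert sel.index == 1 and sel.warning is None

    def test_elbow_vertex_selected(self):
        # slopes 8 then 0.5 then 0.1: the largest drop is at the 2nd vertex
        cv = _grid_from_points([(0.05, 0.2), (0.1, 0.6), (0.3, 0.7), (0.5, 0.72)])
        sel = select_hyperparameters(cv)
        assert sel.index == 1
        assert set(sel.hull_indices) == {0, 1, 2, 3}

    def test_collinear_grid_falls_back_with_warning(self):
        cv = _grid_from_points([(0.1, 0.1), (0.2, 0.2), (0.3, 0.3)])
        sel = select_hyperparameters(cv)
        assert sel.index == 2
        assert "degenerate" in sel.warning

    def test_diagnostics_cover_every_point(self):
        cv = _grid_from_points([(0.05, 0.2), (0.1, 0.6), (0.3, 0.7)])
        sel = select_hyperparameters(cv)
        assert len(sel.diagnostics) == 3
        np.testing.assert_allclose(sel.diagnostics["gap"], [0.05, 0.1, 0.3])


class TestPermutation:
    def test_strong_signal_reaches_minimal_p(self):
        pt, _ = generate(SynthSpec(seed=31))
        X, _ = fit_transform_train(pt.X)
        res = permutation_test(X, pt.class_labels.astype(float), "pls",
                               {"n_components": 2}, n_perm=100, seed=3)
        assert res.pvalues["Q2_cv"] == pytest.approx(1 / 101)
        assert res.pvalues["AUC_cv"] == pytest.approx(1 / 101)
        assert np.all(res.null["Q2_cv"] < res.observed["Q2_cv"])

    def test_null_labels_not_significant(self):
        pt, _ = generate(SynthSpec(seed=33, effect_size=0.0))
        X, _ = fit_transform_train(pt.X)
        res = permutation_test(X, pt.class_labels.astype(float), "pls",
                               {"n_components": 2}, n_perm=50, seed=5)
        assert res.pvalues["Q2_cv"] > 0.05

    def test_small_n_perm_warns(self):
        pt, _ = generate(SynthSpec(seed=34, n_per_class=(10, 10),
                                   n_metabolites=8))
        X, _ = fit_transform_train(pt.X)
        with pytest.warns(UserWarning, match="small"):
            permutation_test(X, pt.class_labels.astype(float), "pls",
                             {"n_components": 1}, n_perm=5, seed=0)
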