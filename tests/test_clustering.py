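"""Survey-profile features, k-POD, gap statistic, and PCA."""

import logging

import numpy as np
import pandas as pd
import pytest
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

import termcal as tc
from termcal.clustering import FEATURE_COLUMNS, build_features, \
    regrouped_estimates


def toy_estimates(support_using=50, support_niu=50, t=0.1, surveys=("A",)):
    rows = []
    for s in surveys:
        for use in (True, False):
            for union, bands in ((True, tc.AGE_GROUPS),
                                 (False, ("15-24", "25-49"))):
                for band in bands:
                    n = support_using if use else support_niu
                    rows.append({
                        "survey": s, "use_at_pregnancy": use,
                        "union_at_pregnancy": union, "band": band,
                        "T": t, "n_unweighted": n,
                    })
    return pd.DataFrame(rows)


class TestBuildFeatures:
    def test_threshold_boundary(self):
        est = toy_estimates()
        est.loc[0, "n_unweighted"] = 9
        est.loc[1, "n_unweighted"] = 10
        fm = build_features(est, min_n=10)
        col0 = (f"{'using' if est.loc[0, 'use_at_pregnancy'] else 'notusing'}"
                f"|{'in-union' if est.loc[0, 'union_at_pregnancy'] else 'not-in-union'}"
                f"|{est.loc[0, 'band']}")
        col1 = (f"{'using' if est.loc[1, 'use_at_pregnancy'] else 'notusing'}"
                f"|{'in-union' if est.loc[1, 'union_at_pregnancy'] else 'not-in-union'}"
                f"|{est.loc[1, 'band']}")
        assert np.isnan(fm.X.loc["A", col0])
        assert fm.X.loc["A", col1] == pytest.approx(0.1)

    def test_dense_survey_has_no_missing_cells(self):
        fm = build_features(toy_estimates(), min_n=10)
        assert fm.missing_fraction == 0.0
        assert list(fm.X.columns) == list(FEATURE_COLUMNS)

    def test_all_missing_survey_excluded(self, caplog):
        est = toy_estimates(surveys=("A", "B"))
        est.loc[est["survey"] == "B", "n_unweighted"] = 3
        with caplog.at_level(logging.WARNING):
            fm = build_features(est, min_n=10)
        assert list(fm.X.index) == ["A"]
        assert "all cells missing" in caplog.text

    def test_missingness_concentrates_in_sparse_not_in_union_strata(self):
        """Simulated surveys have few pregnancies to women not in union,
        so masked cells should sit in the not-in-union columns."""
        cfg = tc.SimulationConfig(n_women=4000, seed=11)
        women, _ = tc.simulate_survey(cfg)
        episodes, _ = tc.extract_survey(women)
        fm = build_features(regrouped_estimates(episodes), min_n=10)
        missing_cols = fm.X.columns[fm.X.isna().iloc[0]]
        assert len(missing_cols) > 0
        niu_or_user = [c for c in missing_cols
                       if "not-in-union" in c or c.startswith("using")]
        assert len(niu_or_user) == len(missing_cols)


class TestKpod:
    def test_equals_kmeans_when_nothing_is_missing(self):
        X, labels = tc.planted_profiles(n_surveys=30, missing_frac=0.0,
                                        seed=2)
        assert not X.isna().any().any()
        model = tc.kpod(X, 4, restarts=12, seed=5)
        best = None
        for r in range(12):
            km = KMeans(n_clusters=4, init="k-means++", n_init=1,
                        random_state=5 + r).fit(X.to_numpy())
            if best is None or km.inertia_ < best.inertia_:
                best = km
        assert adjusted_rand_score(best.labels_, model.assignments) == 1.0
        assert model.objective == pytest.approx(best.inertia_)

    def test_recovers_planted_partition_with_masked_cells(self):
        X, labels = tc.planted_profiles(n_surveys=40, missing_frac=0.12,
                                        seed=3)
        model = tc.kpod(X, 4, restarts=25, seed=9)
        assert adjusted_rand_score(labels, model.assignments) >= 0.9

    def test_k_one_centroid_is_observed_column_means(self):
        X, _ = tc.planted_profiles(n_surveys=20, seed=4)
        model = tc.kpod(X, 1, restarts=3, seed=1)
        want = np.nanmean(X.to_numpy(), axis=0)
        assert model.centroids.loc[1].to_numpy() == pytest.approx(want)
        assert set(model.assignments) == {1}

    def test_labels_increase_with_centroid_mean(self):
        X, _ = tc.planted_profiles(n_surveys=40, seed=6)
        model = tc.kpod(X, 4, restarts=10, seed=2)
        means = model.centroids.mean(axis=1).to_numpy()
        assert (np.diff(means) > 0).all()

    def test_seeded_runs_reproducible(self):
        X, _ = tc.planted_profiles(n_surveys=30, seed=8)
        m1 = tc.kpod(X, 3, restarts=8, seed=13)
        m2 = tc.kpod(X, 3, restarts=8, seed=13)
        pd.testing.assert_series_equal(m1.assignments, m2.assignments)
        pd.testing.assert_frame_equal(m1.completed, m2.completed)
        assert m1.objective == m2.objective

    def test_completed_matrix_matches_observations(self):
        X, _ = tc.planted_profiles(n_surveys=30, seed=8)
        model = tc.kpod(X, 3, restarts=8, seed=13)
        obs = ~X.isna()
        assert np.allclose(model.completed.to_numpy()[obs.to_numpy()],
                           X.to_numpy()[obs.to_numpy()])
        assert model.converged

    def test_k_larger_than_surveys_rejected(self):
        X, _ = tc.planted_profiles(n_surveys=5, seed=1)
        with pytest.raises(ValueError):
            tc.kpod(X, 6)


class TestGapStatistic:
    def test_two_separated_archetypes_choose_two(self):
        arch = tc.profile_archetypes().iloc[[0, 3]]
        X, _ = tc.planted_profiles(n_surveys=24, seed=21, archetypes=arch)
        gap = tc.gap_select_k(X, kmax=5, B_refs=8, seed=22, restarts=8)
        assert gap.chosen_k == 2

    def test_single_cloud_chooses_one(self):
        rng = np.random.default_rng(31)
        X = pd.DataFrame(0.15 + rng.normal(0, 0.045, (30, 16)),
                         columns=list(FEATURE_COLUMNS))
        gap = tc.gap_select_k(X, kmax=5, B_refs=8, seed=32, restarts=8)
        assert gap.chosen_k == 1

    def test_table_shape_and_rule(self):
        X, _ = tc.planted_profiles(n_surveys=30, seed=41)
        gap = tc.gap_select_k(X, kmax=4, B_refs=5, seed=42, restarts=6)
        t = gap.table
        assert list(t["k"]) == [1, 2, 3, 4]
        k = gap.chosen_k
        if k < 4:
            row = t[t["k"] == k].iloc[0]
            nxt = t[t["k"] == k + 1].iloc[0]
            assert row["gap"] >= nxt["gap"] - nxt["s_k"]


class TestPCA:
    def test_variance_fractions_valid(self):
        X, _ = tc.planted_profiles(n_surveys=40, seed=51)
        model = tc.kpod(X, 4, restarts=10, seed=52)
        pca = tc.pca_profiles(model.completed)
        vf = pca.variance_fractions
        assert vf.sum() == pytest.approx(1.0)
        assert (np.diff(vf) <= 1e-12).all()
        assert ((vf >= 0) & (vf <= 1)).all()

    def test_first_dimension_weights_all_probabilities_positively(self):
        X, _ = tc.planted_profiles(n_surveys=40, seed=51)
        model = tc.kpod(X, 4, restarts=10, seed=52)
        pca = tc.pca_profiles(model.completed)
        assert pca.loadings.loc["dim1"].sum() > 0

    def test_dominant_direction_captured(self):
        rng = np.random.default_rng(61)
        level = rng.uniform(0.05, 0.5, 50)
        X = pd.DataFrame(level[:, None] + rng.normal(0, 0.01, (50, 16)),
                         columns=list(FEATURE_COLUMNS))
        pca = tc.pca_profiles(X)
        assert pca.variance_fractions[0] > 0.9

    def test_row_duplication_invariance(self):
        X, _ = tc.planted_profiles(n_surveys=25, missing_frac=0.0, seed=71)
        doubled = pd.concat([X, X])
        p1, p2 = tc.pca_profiles(X), tc.pca_profiles(doubled)
        assert p2.variance_fractions == pytest.approx(
            p1.variance_fractions, abs=1e-9)
        assert p2.loadings.to_numpy() == pytest.approx(
            p1.loadings.to_numpy(), abs=1e-6)

    def test_constant_column_dropped(self, caplog):
        X, _ = tc.planted_profiles(n_surveys=20, missing_frac=0.0, seed=81)
        X.iloc[:, 0] = 0.2
        with caplog.at_level(logging.WARNING):
            pca = tc.pca_profiles(X)
        assert pca.dropped_columns == [X.columns[0]]
        assert X.columns[0] not in pca.loadings.columns
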