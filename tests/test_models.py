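"""Regression models: multivariable recovery, oversampling, hierarchical
ranges and routing, validation utilities."""

import numpy as np
import pandas as pd
import pytest

from wristpwv import models, synth


def planted_table(n=20, seed=0, noise=0.0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "age": rng.uniform(40, 85, n),
        "si": rng.uniform(40, 120, n),
        "p2o": rng.uniform(100, 180, n),
        "cycle_len": rng.uniform(180, 256, n),
    })
    x2 = df["si"] / np.cbrt(df["cycle_len"])
    pwv = 10.0 * df["age"] - 2.0 * x2 + 500.0 + rng.normal(0, noise, n)
    return df, pwv


class TestMultivariable:
    def test_exact_recovery_on_noiseless_data(self):
        df, pwv = planted_table()
        m = models.fit_multivariable(df, pwv, "si")
        assert m.C1 == pytest.approx(10.0, rel=1e-9)
        assert m.C2 == pytest.approx(-2.0, rel=1e-9)
        assert m.C3 == pytest.approx(500.0, rel=1e-6)

    def test_constant_age_column_rank_error(self):
        df, pwv = planted_table()
        df["age"] = 60.0
        with pytest.raises(ValueError):
            models.fit_multivariable(df, pwv, "si")

    def test_unbiased_under_noise(self):
        # coefficient estimates over noisy replicates center on the truth
        c1s, c2s = [], []
        for seed in range(30):
            df, pwv = planted_table(n=200, seed=seed, noise=100.0)
            m = models.fit_multivariable(df, pwv, "si")
            c1s.append(m.C1)
            c2s.append(m.C2)
        assert abs(np.mean(c1s) - 10.0) <= 2 * np.std(c1s) / np.sqrt(len(c1s))
        assert abs(np.mean(c2s) + 2.0) <= 2 * np.std(c2s) / np.sqrt(len(c2s))

    def test_p2o_variant_uses_cycle_normalization(self):
        df, _ = planted_table()
        x2 = models.multivariable_predictor(df, "p2o")
        assert np.allclose(x2, df["p2o"] / df["cycle_len"])


class TestOversampleBins:
    def test_bins_balanced_to_max_count(self):
        pwv = [1050.0] * 3 + [1150.0] * 5 + [1250.0] * 2
        df = pd.DataFrame({"pwv": pwv, "x": range(10)})
        out = models.oversample_bins(df, seed=0)
        counts = out.groupby(np.floor(out["pwv"] / 100.0)).size()
        assert set(counts) == {5}
        # originals all retained
        assert out.loc[~out["_oversampled"], "x"].tolist() == list(range(10))

    def test_balanced_input_unchanged(self):
        df = pd.DataFrame({"pwv": [1050.0, 1150.0, 1250.0], "x": [1, 2, 3]})
        out = models.oversample_bins(df, seed=0)
        assert len(out) == 3 and not out["_oversampled"].any()

    def test_single_bin_unchanged(self):
        df = pd.DataFrame({"pwv": [1010.0, 1020.0, 1030.0], "x": [1, 2, 3]})
        assert len(models.oversample_bins(df, seed=0)) == 3

    def test_deterministic(self):
        df = pd.DataFrame({"pwv": np.linspace(1000, 1500, 17), "x": range(17)})
        a = models.oversample_bins(df, seed=3)
        b = models.oversample_bins(df, seed=3)
        pd.testing.assert_frame_equal(a, b)


@pytest.fixture(scope="module")
def cohort():
    X, y, pids = synth.synth_feature_cohort(n_measurements=150, seed=0)
    return X, y.to_numpy(), pids.to_numpy()


class TestHierarchical:
    def test_overlap_range_edges(self, cohort):
        X, y, _ = cohort
        m = models.fit_hierarchical(X, y, tau=1600, W=400, seed=0)
        assert m.low_range_upper == 1800.0
        assert m.high_range_lower == 1400.0

    def test_boundary_row_in_both_submodels(self):
        # a measurement at 1500 with tau=1600, W=400 trains both regressors
        y = 1500.0
        assert y <= 1600 + 200 and y >= 1600 - 200

    def test_zero_overlap_disjoint_at_boundary(self, cohort):
        X, y, _ = cohort
        m = models.fit_hierarchical(X, y, tau=1600, W=0, seed=0)
        assert m.low_range_upper == m.high_range_lower == 1600.0

    def test_routing_contract(self, cohort):
        X, y, _ = cohort
        m = models.fit_hierarchical(X, y, seed=0)
        pred = models.predict_hierarchical(m, X)
        is_low = m.classifier.predict(X[m.feature_names]).astype(bool)
        low_pred = m.low_regressor.predict(X[m.feature_names])
        assert np.allclose(pred[is_low], low_pred[is_low])

    def test_missing_features_listed(self, cohort):
        X, y, _ = cohort
        m = models.fit_hierarchical(X, y, seed=0)
        with pytest.raises(ValueError, match="pat"):
            models.predict_hierarchical(m, X.drop(columns=["pat"]))

    def test_determinism(self, cohort):
        X, y, _ = cohort
        p1 = models.predict_hierarchical(models.fit_hierarchical(X, y, seed=5), X)
        p2 = models.predict_hierarchical(models.fit_hierarchical(X, y, seed=5), X)
        assert np.array_equal(p1, p2)

    def test_sparse_submodel_range_rejected(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"x": rng.normal(size=20)})
        y = np.full(20, 1200.0)  # nothing at or above tau - W/2
        with pytest.raises(ValueError):
            models.fit_hierarchical(X, y, tau=1600, W=0, seed=0)

    def test_general_model_beats_mean_predictor(self, cohort):
        X, y, pids = cohort
        tr, te = models.participant_split(pids, 0.3, seed=1)
        m = models.fit_general(X[tr], y[tr], seed=1)
        rmse = np.sqrt(np.mean((y[te] - m.predict(X[te])) ** 2))
        assert rmse < np.std(y[te])

    def test_in_sample_optimism(self, cohort):
        X, y, _ = cohort
        m = models.fit_general(X, y, seed=0)
        train_rmse = np.sqrt(np.mean((y - m.predict(X)) ** 2))
        X2, y2, _ = synth.synth_feature_cohort(n_measurements=150, seed=99)
        test_rmse = np.sqrt(np.mean((y2.to_numpy() - m.predict(X2)) ** 2))
        assert train_rmse <= test_rmse


class TestSplitsAndValidation:
    def test_participant_split_disjoint(self):
        pids = [f"P{i}" for i in range(10)] * 3
        tr, te = models.participant_split(pids, 0.3, seed=0)
        assert not set(np.asarray(pids)[tr]) & set(np.asarray(pids)[te])

    def test_shared_participants_raise(self):
        with pytest.raises(ValueError):
            models.check_participant_disjoint(["P1", "P2"], ["P2", "P3"])

    def test_loo_counts_one_refit_per_participant(self):
        X, y, pids = synth.synth_feature_cohort(n_measurements=36, n_participants=6, seed=0)
        params, table = models.loo_validate(
            X, y, pids, [{"n_estimators": 20, "max_depth": 2}],
            model="general", oversample=False, seed=0,
        )
        assert len(table) == 6
        assert sorted(table["participant"]) == sorted(pids.unique())

    def test_loo_duplicate_grid_points_same_choice(self):
        X, y, pids = synth.synth_feature_cohort(n_measurements=36, n_participants=6, seed=0)
        grid = [{"n_estimators": 20, "max_depth": 2}] * 2
        params, _ = models.loo_validate(X, y, pids, grid, model="general",
                                        oversample=False, seed=0)
        assert params == grid[0]

    def test_loo_prefers_planted_shallow_depth(self):
        # data generated by a depth-2 split: deep trees only overfit noise
        wins = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = 60
            x = rng.uniform(0, 1, n)
            y = np.where(x < 0.5, 1200.0, 1900.0) + rng.normal(0, 80.0, n)
            X = pd.DataFrame({"x": x, "noise": rng.normal(size=n)})
            pids = pd.Series([f"P{i % 6}" for i in range(n)])
            grid = [
                {"n_estimators": 30, "max_depth": 2},
                {"n_estimators": 30, "max_depth": 8},
            ]
            params, _ = models.loo_validate(
                X, pd.Series(y), pids, grid, model="general", oversample=False, seed=seed
            )
            wins += params["max_depth"] == 2
        assert wins >= 3

    def test_empty_grid_rejected(self):
        X, y, pids = synth.synth_feature_cohort(n_measurements=36, n_participants=6, seed=0)
        with pytest.raises(ValueError):
            models.loo_validate(X, y, pids, [], seed=0)


class TestFeatureImportance:
    def test_informative_feature_ranks_first_everywhere(self):
        rng = np.random.default_rng(2)
        n = 200
        signal = rng.uniform(0, 1, n)
        X = pd.DataFrame({
            "signal": signal,
            "junk1": rng.normal(size=n),
            "junk2": rng.normal(size=n),
        })
        y = 1000.0 + 1200.0 * signal
        m = models.fit_hierarchical(X, y, seed=0)
        ranks = models.feature_importance(m)
        for component, series in ranks.items():
            assert series.index[0] == "signal", component
            assert series.sum() == pytest.approx(1.0, abs=1e-9)

    def test_unfitted_model_rejected(self):
        with pytest.raises(ValueError):
            models.feature_importance(object())
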