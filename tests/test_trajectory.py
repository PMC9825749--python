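import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from mmtraj.core_io import FeatureTable, MicrobiomeDataset, SampleMetadata
from mmtraj.synthetic import SyntheticSpec, generate
from mmtraj.trajectory import (
    compare_models,
    compare_trajectories,
    feature_importance_over_time,
    fit_mmi_model,
    fit_trajectory_curve,
    list_regressors,
    make_regressor,
    predict_mmi,
)


def _line_curve(n=50, slope=2.0, icept=1.0, level=0.95):
    t = np.linspace(0, 10, n)
    return t, fit_trajectory_curve(t, slope * t + icept, level=level)


class TestTrajectoryCurve:
    def test_exact_line_reproduced(self):
        t, curve = _line_curve()
        np.testing.assert_allclose(curve(t), 2.0 * t + 1.0, atol=1e-6)
        assert np.all(curve.residual_scale(t) <= 1e-8)

    def test_prediction_band_wider_than_confidence(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0, 10, 200)
        y = 2 * t + rng.normal(0, 1, 200)
        curve = fit_trajectory_curve(t, y, level=0.9)
        grid = np.linspace(0, 10, 50)
        hw_pred = curve.half_width(grid, "prediction")
        hw_conf = curve.half_width(grid, "confidence")
        assert np.all(hw_pred > hw_conf)

    def test_homoscedastic_scale_recovery(self):
        rng = np.random.default_rng(1)
        t = rng.uniform(0, 10, 500)
        y = 0.5 * t + rng.normal(0, 1.0, 500)
        curve = fit_trajectory_curve(t, y, level=0.9)
        mean_scale = float(np.mean(curve.residual_scale(np.linspace(0, 10, 100))))
        assert 0.9 <= mean_scale <= 1.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trajectory_curve([0, 1, 2], [0, 1, 2], level=0.9)

    def test_level_validated(self):
        t = np.linspace(0, 1, 20)
        with pytest.raises(ValueError):
            fit_trajectory_curve(t, t, level=0.4)


class TestRegistry:
    def test_at_least_ten_regressors(self):
        assert len(list_regressors()) >= 10

    def test_unknown_name_lists_registry(self):
        with pytest.raises(KeyError, match="registry"):
            make_regressor("not_a_model")


class TestFitPredict:
    def test_noiseless_single_feature_recovery(self):
        # one feature equals time exactly: grouped-CV R^2 >= 0.95
        rng = np.random.default_rng(2)
        n_subj, per = 12, 6
        rows, meta = [], []
        for s in range(n_subj):
            for k in range(per):
                t = k + rng.uniform(0, 0.01)
                rows.append([t, rng.normal(), rng.normal()])
                sid = f"s{s}_{k}"
                meta.append(SampleMetadata(sid, f"subj{s}", float(t)))
        vals = pd.DataFrame(rows, columns=["ft", "n1", "n2"],
                            index=[m.sample_id for m in meta])
        ds = MicrobiomeDataset(FeatureTable(vals, "logratio"), meta, "d")
        model = fit_mmi_model(ds, regressor_name="bagged_trees", seed=0)
        from sklearn.metrics import r2_score

        assert r2_score(ds.meta["time"], model.oof_mmi) >= 0.95

    def test_shuffled_labels_have_no_signal(self):
        from sklearn.metrics import r2_score

        hits = 0
        for seed in range(20):
            ds, _ = generate(
                SyntheticSpec(seed=seed, n_subjects=10, samples_per_subject=5, n_features=10)
            )
            rng = np.random.default_rng(seed)
            shuffled = [
                SampleMetadata(m.sample_id, m.subject_id, t, m.group, m.is_reference)
                for m, t in zip(ds.metadata, rng.permutation([m.time for m in ds.metadata]))
            ]
            ds2 = MicrobiomeDataset(ds.table, shuffled, "d")
            model = fit_mmi_model(ds2, regressor_name="ridge", seed=seed)
            hits += r2_score(ds2.meta["time"], model.oof_mmi) <= 0.1
        assert hits >= 18  # >= 90% of runs

    def test_same_seed_identical_predictions(self, fitted_pipeline):
        _, lds, model, _, _ = fitted_pipeline
        m2 = fit_mmi_model(lds, regressor_name="ridge", seed=7, level=0.95)
        r1 = predict_mmi(model, lds)
        r2 = predict_mmi(m2, lds)
        pd.testing.assert_frame_equal(r1.frame, r2.frame)

    def test_displaced_sample_outside_interval(self, fitted_pipeline):
        _, lds, model, _, _ = fitted_pipeline
        res = predict_mmi(model, lds, interval="prediction", level=0.95)
        sid = res.frame.index[0]
        t = res.frame.loc[sid, "time"]
        scale = float(model.curve.residual_scale(t))
        displaced = res.frame.loc[sid, "mmi"] + 10 * scale
        hw = float(model.curve.half_width(t, "prediction", 0.95))
        assert abs(displaced - float(model.curve(t))) > hw

    def test_missing_feature_errors(self, fitted_pipeline):
        _, lds, model, _, _ = fitted_pipeline
        crippled = MicrobiomeDataset(
            FeatureTable(lds.table.values.iloc[:, 1:], "logratio"),
            lds.metadata, "study",
        )
        with pytest.raises(KeyError, match=model.feature_ids_used[0]):
            predict_mmi(model, crippled)

    def test_model_serialization_round_trip(self, fitted_pipeline, tmp_path):
        from mmtraj.trajectory import load_model, save_model

        _, lds, model, _, _ = fitted_pipeline
        p = tmp_path / "model.bin"
        save_model(model, p)
        restored = load_model(p)
        assert restored.feature_ids_used == model.feature_ids_used
        assert restored.seed == model.seed
        r1 = predict_mmi(model, lds)
        r2 = predict_mmi(restored, lds)
        pd.testing.assert_frame_equal(r1.frame, r2.frame)

    def test_mmi_recovery_on_held_out_subjects(self, fitted_pipeline):
        _, lds, model, truth, _ = fitted_pipeline
        t = lds.meta["time"].to_numpy()
        assert spearmanr(model.oof_mmi, t).statistic >= 0.9


class TestFeatureImportance:
    def test_single_feature_model_dominates_attribution(self):
        rng = np.random.default_rng(3)
        n = 60
        meta = [SampleMetadata(f"s{i}", f"subj{i % 6}", float(i % 10)) for i in range(n)]
        vals = pd.DataFrame(
            {"sig": [m.time for m in meta], "n1": rng.normal(size=n), "n2": rng.normal(size=n)},
            index=[m.sample_id for m in meta],
        )
        ds = MicrobiomeDataset(FeatureTable(vals, "logratio"), meta, "d")
        model = fit_mmi_model(ds, regressor_name="tree", seed=0)
        imp = feature_importance_over_time(model, ds, [(0.0, 10.0)])
        row = imp.iloc[0]
        assert row["sig"] / row.sum() >= 0.99

    def test_local_accuracy_for_tree_model(self, fitted_pipeline):
        from mmtraj.attribution import shapley_values

        _, lds, model, _, _ = fitted_pipeline
        X = lds.table.values[model.feature_ids_used].to_numpy()[:20]
        phi, base = shapley_values(model.predict, X, model.background(), n_permutations=2, seed=0)
        np.testing.assert_allclose(phi.sum(axis=1) + base, model.predict(X), atol=1e-6)

    def test_regime_switch_windows(self):
        # f_early informative only for t < 5, f_late only after
        rng = np.random.default_rng(4)
        n = 120
        meta = [SampleMetadata(f"s{i}", f"subj{i % 8}", float(i % 10)) for i in range(n)]
        t = np.array([m.time for m in meta])
        # each feature varies only inside its own regime and sits at its
        # grand mean outside it, so an additive model assigns it no credit
        # in the other window
        early = np.where(t < 5, t - 2.5, 0.0) + rng.normal(0, 0.01, n)
        late = np.where(t >= 5, t - 7.0, 0.0) + rng.normal(0, 0.01, n)
        vals = pd.DataFrame({"early": early, "late": late},
                            index=[m.sample_id for m in meta])
        ds = MicrobiomeDataset(FeatureTable(vals, "logratio"), meta, "d")
        model = fit_mmi_model(ds, regressor_name="ridge", seed=0)
        imp = feature_importance_over_time(model, ds, [(0.0, 5.0), (5.0, 9.0)])
        assert imp.iloc[0]["early"] > imp.iloc[0]["late"]
        assert imp.iloc[1]["late"] > imp.iloc[1]["early"]

    def test_empty_window_warns_and_is_nan(self, fitted_pipeline):
        _, lds, model, _, _ = fitted_pipeline
        with pytest.warns(UserWarning, match="no samples"):
            imp = feature_importance_over_time(model, lds, [(0.0, 1.0), (5.0, 6.0)])
        assert imp.iloc[1].isna().all()


class TestCompareModels:
    def test_sanity_ordering_and_conservation(self, fitted_pipeline):
        _, lds, _, _, _ = fitted_pipeline
        board = compare_models(lds, ["ridge", "dummy"], cv_folds=4, seed=0)
        assert len(board.frame) == 2
        assert board.frame.iloc[0]["model"] == "ridge"
        assert board.frame[board.frame["model"] == "dummy"]["cv_r2_mean"].iloc[0] <= 0.0

    def test_identical_model_identical_scores(self, fitted_pipeline):
        _, lds, _, _, _ = fitted_pipeline
        board = compare_models(lds, ["ridge", "ridge"], cv_folds=4, seed=0)
        r2 = board.frame["cv_r2_mean"].to_numpy()
        assert r2[0] == pytest.approx(r2[1], abs=1e-12)

    def test_fold_hash_stable(self, fitted_pipeline):
        _, lds, _, _, _ = fitted_pipeline
        b1 = compare_models(lds, ["ridge", "dummy"], cv_folds=4, seed=0)
        b2 = compare_models(lds, ["ridge", "dummy"], cv_folds=4, seed=0)
        assert b1.fold_hash == b2.fold_hash


class TestCompareTrajectories:
    def _two_group(self, seed, shift):
        from dataclasses import replace

        from mmtraj.transform import log_ratio_transform, select_denominator

        ds, _ = generate(
            SyntheticSpec(seed=seed, n_subjects=20, samples_per_subject=5, group_shift=shift)
        )
        if shift == 0.0:
            subs = sorted({m.subject_id for m in ds.metadata})
            half = set(subs[:10])
            meta = [replace(m, group="A" if m.subject_id in half else "B") for m in ds.metadata]
            ds = MicrobiomeDataset(ds.table, meta, "study")
        rep = select_denominator(ds, strategy="crossings")
        lr = log_ratio_transform(ds.table, rep.feature_id, pseudocount=0)
        return MicrobiomeDataset(lr, ds.metadata, "study")

    def test_duplicated_group_is_null(self):
        ds = self._two_group(0, 0.0)
        model = fit_mmi_model(ds, regressor_name="ridge", seed=0)
        lin = compare_trajectories(ds, model, "A", "B", method="linear")
        perm = compare_trajectories(ds, model, "A", "B", method="spline_permutation",
                                    n_permutations=99, seed=0)
        assert lin.p_value >= 0.05
        assert perm.p_value >= 0.05

    def test_separated_groups_detected(self):
        ds = self._two_group(1, 0.4)
        model = fit_mmi_model(ds, regressor_name="ridge", seed=1)
        lin = compare_trajectories(ds, model, "reference", "shifted", method="linear")
        perm = compare_trajectories(ds, model, "reference", "shifted",
                                    method="spline_permutation", n_permutations=999, seed=1)
        assert lin.p_value <= 0.01
        assert perm.p_value <= 0.01

    def test_permutation_p_lower_bound(self):
        ds = self._two_group(1, 0.4)
        model = fit_mmi_model(ds, regressor_name="ridge", seed=1)
        perm = compare_trajectories(ds, model, "reference", "shifted",
                                    method="spline_permutation", n_permutations=199, seed=1)
        assert perm.p_value >= 1.0 / 200
        assert perm.p_value == pytest.approx(1.0 / 200)
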