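import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenogrowth.biomass_models import (
    Family,
    ModelEvaluation,
    ModelSpec,
    ResampleSpec,
    compute_metrics,
    crossvalidate_final,
    evaluate_models,
    fit_model,
    predict_biomass,
    select_model,
)
from phenogrowth.core_io import FeatureTable, SchemaError


class TestComputeMetrics:
    def test_perfect_prediction(self):
        m = compute_metrics([1, 2, 3], [1, 2, 3])
        assert m["MAE"] == 0 and m["RMSE"] == 0 and m["R2"] == 1

    def test_equal_magnitude_residuals_make_mae_equal_rmse(self):
        m = compute_metrics([0, 0, 0, 0], [1, -1, 1, -1])
        assert m["MAE"] == m["RMSE"] == 1

    def test_hand_computed_fixture(self):
        # SSres = 4, SStot = 20
        m = compute_metrics([2, 4, 6, 8], [3, 3, 7, 7])
        assert m["MAE"] == pytest.approx(1.0)
        assert m["RMSE"] == pytest.approx(1.0)
        assert m["R2"] == pytest.approx(0.8)
        assert m["R2_corr"] == pytest.approx(0.8)

    def test_zero_variance_actual_undefined_r2(self):
        m = compute_metrics([5, 5, 5], [4, 5, 6])
        assert np.isnan(m["R2"])

    @given(
        st.lists(
            st.floats(-1e4, 1e4, allow_nan=False), min_size=2, max_size=40
        ).flatmap(
            lambda a: st.tuples(
                st.just(a),
                st.lists(
                    st.floats(-1e4, 1e4, allow_nan=False),
                    min_size=len(a),
                    max_size=len(a),
                ),
            )
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_rmse_dominates_mae(self, pair):
        a, p = pair
        m = compute_metrics(a, p)
        assert m["RMSE"] >= m["MAE"] - 1e-12


def _linear_data(rng, n=100, p=10, noise=0.0):
    X = rng.normal(size=(n, p))
    beta = rng.normal(size=p)
    y = X @ beta + noise * rng.normal(size=n)
    return X, y


class TestFitModel:
    def test_lm_fits_realizable_function_exactly(self, rng):
        X, y = _linear_data(rng)
        fm = fit_model(ModelSpec(Family.LM), X, y)
        resid = y - fm.predict(X)
        assert np.linalg.norm(resid) < 1e-8 * np.linalg.norm(y)

    def test_pls_full_components_match_ols(self, rng):
        X, y = _linear_data(rng, n=60, p=8, noise=0.5)
        ols = fit_model(ModelSpec(Family.LM), X, y).predict(X)
        pls = fit_model(
            ModelSpec(Family.PLS, hyperparams={"n_components": 8}), X, y
        ).predict(X)
        np.testing.assert_allclose(pls, ols, rtol=1e-8, atol=1e-8)

    def test_pcr_all_components_match_ols(self, rng):
        X, y = _linear_data(rng, n=60, p=8, noise=0.5)
        ols = fit_model(ModelSpec(Family.LM), X, y).predict(X)
        pcr = fit_model(
            ModelSpec(Family.PC, hyperparams={"n_components": 8}), X, y
        ).predict(X)
        np.testing.assert_allclose(pcr, ols, rtol=1e-8, atol=1e-8)

    def test_rank_deficient_lm_flagged(self, rng):
        X = rng.normal(size=(6, 10))
        y = rng.normal(size=6)
        fm = fit_model(ModelSpec(Family.LM), X, y)
        assert fm.rank_deficient

    def test_mars_fits_hinge_function(self, rng):
        X = rng.uniform(-2, 2, size=(150, 3))
        y = np.maximum(0, X[:, 0] - 0.3) * 2.0 + 1.0
        fm = fit_model(ModelSpec(Family.MARS), X, y)
        pred = fm.predict(X)
        assert np.corrcoef(pred, y)[0, 1] ** 2 > 0.97

    def test_stepwise_selects_active_variables(self, rng):
        X = rng.normal(size=(120, 8))
        y = 3 * X[:, 2] - 2 * X[:, 5] + 0.1 * rng.normal(size=120)
        fm = fit_model(ModelSpec(Family.SM), X, y)
        assert set(fm.model.included_) >= {2, 5}
        assert fm.complexity <= 4


def _tiny_tables(experiment):
    _, feats, _, bio, _ = experiment
    return feats, bio


class TestEvaluateModels:
    def test_repeated_kfold_resample_count(self, small_experiment):
        feats, bio = _tiny_tables(small_experiment)
        ev = evaluate_models(
            feats, bio, ResampleSpec(k=10, repeats=5, seed=1), families=["LM"]
        )
        assert ev.n_resamples == 50
        assert len(ev.resamples[Family.LM]["RMSE"]) == 50

    def test_bootstrap_resample_count(self, small_experiment):
        feats, bio = _tiny_tables(small_experiment)
        ev = evaluate_models(
            feats,
            bio,
            ResampleSpec(scheme="bootstrap", n_boot=25, seed=1),
            families=["LM"],
        )
        assert len(ev.resamples[Family.LM]["RMSE"]) == 25

    def test_deterministic_under_fixed_seed(self, small_experiment):
        feats, bio = _tiny_tables(small_experiment)
        spec = ResampleSpec(k=5, repeats=1, seed=3)
        e1 = evaluate_models(feats, bio, spec, families=["PLS"])
        e2 = evaluate_models(feats, bio, spec, families=["PLS"])
        np.testing.assert_array_equal(
            e1.resamples[Family.PLS]["RMSE"], e2.resamples[Family.PLS]["RMSE"]
        )
        assert e1.best_tune == e2.best_tune

    def test_summary_is_ordered_six_number(self, small_experiment):
        feats, bio = _tiny_tables(small_experiment)
        ev = evaluate_models(
            feats, bio, ResampleSpec(k=5, repeats=2, seed=2), families=["LM", "PLS"]
        )
        s = ev.summary("RMSE")
        for _, row in s.iterrows():
            assert (
                row["Min."]
                <= row["1st Qu."]
                <= row["Median"]
                <= row["3rd Qu."]
                <= row["Max."]
            )
        assert (ev.resamples[Family.PLS]["RMSE"] >= ev.resamples[Family.PLS]["MAE"] - 1e-12).all()

    def test_too_few_plants_for_folds(self, small_experiment):
        feats, bio = _tiny_tables(small_experiment)
        small_bio = type(bio)(bio.data.iloc[:4].copy())
        sel = feats.data["plant_id"].isin(small_bio.data["plant_id"])
        small_feats = FeatureTable(feats.data[sel].copy())
        with pytest.raises(ValueError, match="fewer samples"):
            evaluate_models(
                small_feats, small_bio, ResampleSpec(k=10), families=["LM"]
            )


def _fake_evaluation(metrics_a, metrics_b, comp_a, comp_b):
    fams = [Family.PLS, Family.PC]
    vecs = {
        Family.PLS: {
            "RMSE": np.asarray(metrics_a),
            "MAE": np.asarray(metrics_a),
            "R2": 1 - np.asarray(metrics_a),
            "R2_ss": 1 - np.asarray(metrics_a),
        },
        Family.PC: {
            "RMSE": np.asarray(metrics_b),
            "MAE": np.asarray(metrics_b),
            "R2": 1 - np.asarray(metrics_b),
            "R2_ss": 1 - np.asarray(metrics_b),
        },
    }
    return ModelEvaluation(
        families=fams,
        resamples=vecs,
        best_tune={Family.PLS: {"n_components": comp_a}, Family.PC: {"n_components": comp_b}},
        complexity={Family.PLS: comp_a, Family.PC: comp_b},
        n_resamples=len(metrics_a),
        feature_names=[],
    )


class TestSelectModel:
    def test_single_family_selected(self, small_experiment):
        feats, bio = _tiny_tables(small_experiment)
        ev = evaluate_models(
            feats, bio, ResampleSpec(k=5, repeats=1, seed=0), families=["LM"]
        )
        assert select_model(ev).family is Family.LM

    def test_identical_metrics_prefer_fewer_components(self):
        v = [0.5, 0.6, 0.4, 0.55, 0.45]
        ev = _fake_evaluation(v, v, comp_a=3, comp_b=9)
        assert select_model(ev).family is Family.PLS
        ev2 = _fake_evaluation(v, v, comp_a=9, comp_b=3)
        assert select_model(ev2).family is Family.PC

    def test_parsimony_choice_stays_within_one_se(self, small_experiment):
        feats, bio = _tiny_tables(small_experiment)
        ev = evaluate_models(
            feats,
            bio,
            ResampleSpec(k=5, repeats=2, seed=4),
            families=["LM", "PLS", "PC"],
        )
        spec = select_model(ev)
        means = {f: ev.resamples[f]["RMSE"].mean() for f in ev.families}
        best = min(means.values())
        v = ev.resamples[min(means, key=means.get)]["RMSE"]
        se = np.std(v, ddof=1) / np.sqrt(len(v))
        assert means[spec.family] <= best + se + 1e-12


class TestCrossvalidateFinal:
    def test_leave_one_out_on_12_points(self, rng):
        X, y = _linear_data(rng, n=12, p=2, noise=0.1)
        out = crossvalidate_final(ModelSpec(Family.LM), X, y, k=12, seed=0)
        assert len(out["fold_ss"]) == 12
        assert out["predictions"]["fold"].nunique() == 12

    def test_noise_free_linear_data_cv_ss_vanishes(self, rng):
        X, y = _linear_data(rng, n=40, p=3, noise=0.0)
        out = crossvalidate_final(ModelSpec(Family.LM), X, y, k=10, seed=0)
        assert out["cv_ss"] < 1e-12
        assert out["p_value"] < 1e-10

    def test_fold_assignment_deterministic(self, rng):
        X, y = _linear_data(rng, n=30, p=3, noise=0.5)
        a = crossvalidate_final(ModelSpec(Family.LM), X, y, k=5, seed=7)
        b = crossvalidate_final(ModelSpec(Family.LM), X, y, k=5, seed=7)
        pd.testing.assert_frame_equal(a["predictions"], b["predictions"])

    def test_k_exceeding_n_rejected(self, rng):
        X, y = _linear_data(rng, n=5, p=2)
        with pytest.raises(ValueError, match="exceeds"):
            crossvalidate_final(ModelSpec(Family.LM), X, y, k=10)


class TestPredictBiomass:
    def test_negative_predictions_clipped_and_flagged(self, rng):
        X, y = _linear_data(rng, n=30, p=3, noise=0.0)
        fm = fit_model(ModelSpec(Family.LM), X, y, feature_names=["a", "b", "c"])
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df.insert(0, "day", 1)
        df.insert(0, "plant_id", [f"P{i}" for i in range(30)])
        # force strongly negative targets on some rows
        table = FeatureTable(df)
        out = predict_biomass(fm, table, floor_g=0.01)
        neg = fm.predict(X) < 0.01
        assert (out.loc[neg, "pfb_g"] == 0.01).all()
        assert out["clipped"].equals(pd.Series(neg))

    def test_missing_predictor_is_schema_error(self, rng):
        X, y = _linear_data(rng, n=20, p=2)
        fm = fit_model(ModelSpec(Family.LM), X, y, feature_names=["a", "b"])
        table = FeatureTable(
            pd.DataFrame({"plant_id": ["P1"], "day": [1], "a": [0.5]})
        )
        with pytest.raises(SchemaError, match="missing model predictors"):
            predict_biomass(fm, table)


def test_training_r2_dominates_cv_r2_on_noisy_data(rng):
    """Held-out R^2 should rarely beat training R^2 (anti-overfitting)."""
    wins = 0
    n_sets = 20
    for s in range(n_sets):
        local = np.random.default_rng(s)
        X, y = _linear_data(local, n=60, p=8, noise=2.0)
        fm = fit_model(ModelSpec(Family.LM), X, y)
        train_r2 = compute_metrics(y, fm.predict(X))["R2_corr"]
        cv = crossvalidate_final(ModelSpec(Family.LM), X, y, k=5, seed=s)
        cv_r2 = compute_metrics(
            cv["predictions"]["observed"].to_numpy(),
            cv["predictions"]["predicted"].to_numpy(),
        )["R2_corr"]
        if train_r2 >= cv_r2:
            wins += 1
    assert wins >= 0.9 * n_sets


def test_selected_model_recovers_latent_trajectories_noise_free():
    """On noise-free synthetic data the selected model's per-day biomass
    predictions track the latent trajectory."""
    from phenogrowth.biomass_models import _harvest_design
    from phenogrowth.synthetic import SimConfig, simulate_experiment

    cfg = SimConfig(
        n_genotypes=8, n_reps=3, n_days=14, residual_sd=0.0,
        feature_noise_sd=0.0, water_noise_sd=0.0, seed=5,
    )
    _, feats, _, bio, truth = simulate_experiment(cfg)
    ev = evaluate_models(
        feats, bio, ResampleSpec(k=5, repeats=2, seed=5),
        families=["LM", "PLS", "PC", "SM", "MARS"],
    )
    spec = select_model(ev)
    X, y, cols = _harvest_design(feats, bio)
    fm = fit_model(spec, X, y, feature_names=cols, seed=5)
    pfb = predict_biomass(fm, feats)
    merged = pfb.merge(truth.biomass, on=["plant_id", "day"])
    rel = (merged["pfb_g"] - merged["biomass_g"]).abs() / merged["biomass_g"]
    assert rel.median() <= 0.05
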