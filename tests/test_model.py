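"""The probabilistic inverse model: design, sampling, prediction."""

import numpy as np
import pandas as pd
import pytest

from gaitscreen.model import (
    COORDINATION_COLUMNS,
    GAIT_COLUMNS,
    POSTURE_COLUMNS,
    SEX_COLUMN,
    ModelDesign,
    PosteriorPredictor,
    PredictiveInference,
    SubjectModel,
    split_dataset,
)
from gaitscreen.synthetic import simulate_linear_outcome


class TestSplit:
    def _rows(self, n_nbw=329, n_lbw=39):
        return pd.DataFrame(
            {
                "stride_id": [f"s{i}" for i in range(n_nbw + n_lbw)],
                "birth_weight_category": ["NBW"] * n_nbw + ["LBW"] * n_lbw,
            }
        )

    def test_reference_split_sizes_achievable(self):
        # 368 strides -> 294 train / 35 validation / 39 test
        train, val, test = split_dataset(self._rows(), validation_fraction=35 / 329, seed=0)
        assert (len(train), len(val), len(test)) == (294, 35, 39)

    def test_default_validation_matches_test_size(self):
        train, val, test = split_dataset(self._rows(), seed=0)
        assert len(test) == 39 and len(val) == 39 and len(train) == 290

    def test_partition_is_exact(self):
        rows = self._rows(50, 8)
        train, val, test = split_dataset(rows, seed=3)
        ids = pd.concat([train, val, test])["stride_id"]
        assert sorted(ids) == sorted(rows["stride_id"])
        assert len(set(train.stride_id) & set(val.stride_id)) == 0

    def test_all_lbw_in_test(self):
        _, _, test = split_dataset(self._rows(30, 6), seed=1)
        assert (test["birth_weight_category"] == "LBW").all() and len(test) == 6

    def test_seeded_determinism(self):
        a = split_dataset(self._rows(), seed=7)
        b = split_dataset(self._rows(), seed=7)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_no_lbw_requires_fraction(self):
        with pytest.raises(ValueError, match="validation_fraction"):
            split_dataset(self._rows(40, 0), seed=0)


class TestDesign:
    def test_full_model_has_36_free_parameters(self):
        design = ModelDesign(outcome="age")
        assert design.n_free_parameters == 36
        assert len(design.predictors) == 1 + 9 + 12 + 12
        assert design.predictors[0] == SEX_COLUMN
        assert set(GAIT_COLUMNS) | set(POSTURE_COLUMNS) | set(COORDINATION_COLUMNS) <= set(design.predictors)

    def test_degenerate_predictor_named(self, cohort):
        df = cohort.strides.copy()
        df["cc5"] = 0.7
        with pytest.raises(ValueError, match="cc5"):
            SubjectModel.from_dataframe(df, outcome="age")

    def test_few_rows_warns(self, cohort):
        with pytest.warns(UserWarning, match="training rows"):
            SubjectModel.from_dataframe(cohort.strides.head(20), outcome="age")

    def test_log_transform_default_for_mass(self, cohort):
        m = SubjectModel.from_dataframe(cohort.strides, outcome="mass")
        assert m.design.transform == "log"
        a = SubjectModel.from_dataframe(cohort.strides, outcome="age")
        assert a.design.transform == "identity"


class TestSampling:
    def _toy(self, n=500, sigma=0.5, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "theta": 2.0 + 3.0 * x + sigma * rng.standard_normal(n)})
        return SubjectModel(ModelDesign(outcome="theta", predictors=("x",)), df), df

    def test_posterior_mean_matches_conjugate_oracle(self):
        """Normal-likelihood toy: slope posterior agrees with the analytic
        conjugate posterior within Monte-Carlo error."""
        m, df = self._toy()
        res = m.fit(draws=1000, tune=500, seed=1)
        post = res.posterior()["b_x"]
        # conjugate oracle in the standardized space with sigma fixed at
        # its posterior mean: N(mean = (Z'y/s^2) / (Z'Z/s^2 + 1/4), ...)
        Z = (df.x - df.x.mean()).to_numpy() / df.x.std(ddof=0)
        ys = (df.theta - df.theta.mean()).to_numpy() / df.theta.std(ddof=0)
        s = res.posterior()["epsilon"].mean()
        prec = (Z @ Z) / s**2 + 1 / m.design.slope_prior_sd**2
        oracle_mean = (Z @ ys) / s**2 / prec
        mcse = post.std() / np.sqrt(res.diagnostics().loc["b_x", "ess"])
        # small extra slack: the oracle conditions on a point estimate of sigma
        assert abs(post.mean() - oracle_mean) < 3 * mcse + 5e-4
        assert post.std() == pytest.approx(1 / np.sqrt(prec), rel=0.15)

    def test_same_seed_identical_draws(self):
        m, _ = self._toy(n=100)
        r1 = m.fit(draws=200, tune=100, seed=42)
        r2 = m.fit(draws=200, tune=100, seed=42)
        np.testing.assert_array_equal(r1.chain, r2.chain)

    def test_noiseless_slope_recovery(self, cohort):
        """theta = 2 + 3*G1 exactly: the G1 slope concentrates at the true
        standardized value and all other slopes at zero."""
        design = ModelDesign(outcome="theta")
        df = cohort.strides.copy()
        df["theta"] = 2.0 + 3.0 * df["stride_distance"]
        m = SubjectModel(design, df)
        res = m.fit(draws=500, tune=500, seed=2)
        post = res.posterior()
        true_std = 3.0 * df["stride_distance"].std(ddof=0) / df["theta"].std(ddof=0)
        assert post["b_stride_distance"].mean() == pytest.approx(true_std, abs=0.01)
        others = [c for c in post.columns if c.startswith("b_") and c != "b_stride_distance"]
        assert max(abs(post[c].mean()) for c in others) < 0.01

    def test_diagnostics_emitted_and_converged(self, age_fit):
        d = age_fit.diagnostics()
        assert set(d.columns) == {"rhat", "ess"}
        assert len(d) == 36 + 1  # 36 free parameters + the auxiliary nu
        assert d["rhat"].max() <= 1.01
        assert age_fit.converged

    def test_summary_table_structure(self, age_fit):
        s = age_fit.summary()
        assert {"mean", "sd", "hdi_2.5%", "hdi_97.5%", "rhat", "ess"} <= set(s.columns)
        assert "alpha" in s.index and "epsilon" in s.index and "nu" in s.index
        assert (s.loc[[i for i in s.index if i.startswith("b_")]].shape[0]) == 34

    def test_n_free_parameters_is_36(self, age_fit):
        assert age_fit.n_free_parameters == 36


class TestPrediction:
    def test_point_posterior_collapses_to_linear_predictor(self):
        # one draw, epsilon ~ 0: predictive is a point at alpha + x*beta
        design = ModelDesign(outcome="theta", predictors=("x",))
        draws = np.array([[1.0, 2.0, 1e-12, 30.0]])  # alpha, b_x, eps, nu
        scaling = {"x_mean": np.array([0.0]), "x_sd": np.array([1.0]), "y_mean": 0.0, "y_sd": 1.0}
        pred = PosteriorPredictor(draws, design, scaling)
        rows = pd.DataFrame({"x": [0.5], "theta": [0.0], "stride_id": ["s0"]})
        inf = pred.predict(rows, n_samples=200, seed=0)[0]
        assert inf.samples.std() < 1e-9
        assert inf.samples.mean() == pytest.approx(1.0 + 2.0 * 0.5, abs=1e-6)

    def test_missing_predictor_rejected(self, age_fit, cohort):
        with pytest.raises(ValueError, match="missing predictor"):
            age_fit.predict(cohort.strides.drop(columns=["cc3"]))

    def test_in_sample_deltas_centered(self, age_fit, cohort):
        train_ids = set(age_fit.model.train_rows.stride_id)
        infs = age_fit.predict(cohort.strides, seed=5)
        pooled = np.mean([i.mean_delta for i in infs if i.stride_id in train_ids])
        sd_theta = age_fit.model.train_rows["age"].std()
        assert abs(pooled) < 0.1 * sd_theta

    def test_predictive_sd_stable_across_strides(self, age_fit, cohort):
        # the reference observation noise dominates: per-stride predictive
        # spread varies little between strides
        infs = age_fit.predict(cohort.strides, seed=6)
        sds = np.array([i.sd for i in infs])
        assert sds.std() / sds.mean() < 0.2

    def test_mass_predictions_positive_on_log_scale(self, cohort):
        train, _, _ = split_dataset(cohort.strides, seed=1)
        res = SubjectModel.from_dataframe(train, outcome="mass").fit(draws=400, tune=300, seed=3)
        infs = res.predict(cohort.strides.head(30), seed=7)
        assert all((i.samples > 0).all() for i in infs)

    def test_bundle_round_trip(self, tmp_path, age_fit, cohort):
        age_fit.save_bundle(tmp_path / "bundle")
        pred = PosteriorPredictor.load(tmp_path / "bundle")
        rows = cohort.strides.head(5)
        a = age_fit.predict(rows, n_samples=500, seed=11)
        b = pred.predict(rows, n_samples=500, seed=11)
        for x, y in zip(a, b):
            np.testing.assert_allclose(x.samples, y.samples, rtol=1e-9)


class TestRecovery:
    def test_slope_credible_intervals_cover_truth(self, cohort):
        """Known-coefficient outcomes: 95% intervals cover the generating
        slopes at roughly nominal rate (single-cohort smoke version of the
        multi-replicate calibration check)."""
        design = ModelDesign(outcome="theta")
        p = len(design.predictors)
        rng = np.random.default_rng(0)
        beta = np.zeros(p)
        nz = rng.choice(p, 8, replace=False)
        beta[nz] = rng.normal(0, 1.0, 8)
        df = simulate_linear_outcome(
            cohort.strides, design.predictors, beta, alpha=5.0, sigma=1.0, outcome_name="theta", seed=1
        )
        m = SubjectModel(design, df)
        res = m.fit(draws=800, tune=500, seed=1)
        covered = sum(
            res.slope_interval(pr)[0] <= beta[j] / m.y_sd <= res.slope_interval(pr)[1]
            for j, pr in enumerate(design.predictors)
        )
        assert covered >= 29  # ~85% of 34 even in an unlucky replicate


def test_reference_scale_profile_settings(monkeypatch):
    """profile='reference' requests 32 chains of 2^14 tuning + 2^14 sampling sweeps."""
    design = ModelDesign(outcome="age", predictors=("x",))
    df = pd.DataFrame({"x": np.random.default_rng(0).standard_normal(40)})
    df["age"] = df.x + 1
    m = SubjectModel(design, df)
    recorded = []

    def fake_run(self, sweeps, keep, rng):
        recorded.append((sweeps, keep))
        return np.zeros((keep, self._ndim))

    monkeypatch.setattr(SubjectModel, "_run_chain", fake_run)
    res = m.fit(profile="reference", seed=0)
    assert res.sampler_settings["chains"] == 32
    assert recorded == [(2**15, 2**14)] * 32
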