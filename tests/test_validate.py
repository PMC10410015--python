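"""Klemera-Doubal, homeostatic dysregulation, and validation models."""

import numpy as np
import pandas as pd
import pytest

import physioage as pa
from physioage.cohort import CohortError
from physioage.validate import HDModel, metric_deciles


def _cohort(values: dict, ages) -> pd.DataFrame:
    n = len(ages)
    return pd.DataFrame({"id": range(1, n + 1), "age": ages,
                         "sex": ["F", "M"] * (n // 2) + ["F"] * (n % 2), **values})


class TestKDM:
    def test_noise_free_linear_biomarker_inverts_exactly(self):
        ages = np.linspace(20, 70, 100)
        df = _cohort({"m1": 5.0 + 0.8 * ages}, ages)
        model = pa.fit_kdm(df, screen_r=0.1)
        kdm = pa.score_kdm(model, df)
        np.testing.assert_allclose(kdm.to_numpy(), ages, atol=1e-6)

    def test_noisy_panel_tracks_age(self):
        effects = tuple(
            pa.EffectSpec(f"v{i}", "linear", amplitude=6.0, noise_sd=0.5, baseline_sd=1.0)
            for i in range(10)
        )
        syn = pa.generate_cohort(pa.GeneratorConfig(n_individuals=5000, effects=effects, seed=31))
        model = pa.fit_kdm(syn.cohort)
        kdm = pa.score_kdm(model, syn.cohort)
        assert np.corrcoef(kdm, syn.cohort["age"])[0, 1] > 0.9

    def test_uncorrelated_biomarker_screened_out(self):
        rng = np.random.default_rng(0)
        ages = rng.integers(20, 70, 500).astype(float)
        df = _cohort({"good": 2 * ages + rng.normal(0, 5, 500), "flat": rng.normal(0, 1, 500)}, ages)
        model = pa.fit_kdm(df, screen_r=0.1)
        assert model.included == ["good"]
        assert "flat" in model.excluded

    def test_nothing_passes_screen_raises(self):
        rng = np.random.default_rng(1)
        ages = rng.integers(20, 70, 200).astype(float)
        df = _cohort({"a": rng.normal(size=200), "b": rng.normal(size=200)}, ages)
        with pytest.raises(CohortError):
            pa.fit_kdm(df, screen_r=0.3)


class TestHD:
    @staticmethod
    def _manual_model(cov):
        k = cov.shape[0]
        cols = [f"v{i}" for i in range(k)]
        return HDModel(
            mu=pd.Series(np.zeros(k), index=cols),
            covariance=pd.DataFrame(cov, index=cols, columns=cols),
            log_variables=[],
            standardize=(pd.Series(np.zeros(k), index=cols), pd.Series(np.ones(k), index=cols)),
            reference_description="manual",
        )

    def test_reference_mean_scores_zero(self):
        model = self._manual_model(np.eye(3))
        df = _cohort({"v0": [0.0], "v1": [0.0], "v2": [0.0]}, [30])
        assert pa.score_hd(model, df).iloc[0] == 0.0

    def test_identity_covariance_reduces_to_euclidean(self):
        model = self._manual_model(np.eye(3))
        df = _cohort({"v0": [1.0], "v1": [2.0], "v2": [2.0]}, [30])
        assert pa.score_hd(model, df).iloc[0] == pytest.approx(3.0, abs=1e-12)

    def test_hand_computed_quadratic_form(self):
        """cov [[1,.5],[.5,1]], u = (1,1): d^2 = u' inv(cov) u = 4/3."""
        model = self._manual_model(np.array([[1.0, 0.5], [0.5, 1.0]]))
        df = _cohort({"v0": [1.0], "v1": [1.0]}, [30])
        assert pa.score_hd(model, df).iloc[0] == pytest.approx(np.sqrt(4.0 / 3.0), abs=1e-8)

    def test_matches_explicit_inverse_on_fitted_model(self):
        effects = tuple(
            pa.EffectSpec(f"v{i}", "linear", amplitude=4.0, noise_sd=0.3, baseline_sd=1.0)
            for i in range(5)
        )
        syn = pa.generate_cohort(pa.GeneratorConfig(n_individuals=3000, effects=effects, seed=6))
        model = pa.fit_hd(syn.cohort)
        hd = pa.score_hd(model, syn.cohort.iloc[:50])
        mean, sd = model.standardize
        block = syn.cohort.iloc[:50][list(model.mu.index)]
        u = ((block - mean) / sd) - model.mu
        vi = np.linalg.inv(model.covariance.to_numpy())
        expected = np.sqrt(np.einsum("ij,jk,ik->i", u.to_numpy(), vi, u.to_numpy()))
        np.testing.assert_allclose(hd.to_numpy(), expected, atol=1e-8)

    def test_small_reference_rejected(self):
        effects = tuple(
            pa.EffectSpec(f"v{i}", "linear", amplitude=4.0, noise_sd=0.3, baseline_sd=1.0)
            for i in range(5)
        )
        syn = pa.generate_cohort(pa.GeneratorConfig(n_individuals=200, effects=effects, seed=7))
        with pytest.raises(CohortError):
            pa.fit_hd(syn.cohort, reference_filter=lambda df: df["age"] == df["age"].min())


class TestCoxDeciles:
    @pytest.fixture(scope="class")
    def survival_setup(self):
        effects = tuple(
            pa.EffectSpec(f"v{i}", "linear", amplitude=3.0, noise_sd=0.5, baseline_sd=1.0)
            for i in range(6)
        )
        syn = pa.generate_cohort(pa.GeneratorConfig(n_individuals=8000, effects=effects, seed=41))
        coh = pa.simulate_mortality(syn, beta=0.08, baseline=0.004, max_followup=16, seed=41)
        metric = pd.Series(syn.true_deviation.to_numpy(), index=coh["id"])
        return coh, metric

    def test_reference_decile_is_unity(self, survival_setup):
        coh, metric = survival_setup
        table = pa.cox_deciles(metric, coh)
        ref = table.deciles[table.deciles["decile"] == 5].iloc[0]
        assert (ref["hr"], ref["ci_low"], ref["ci_high"]) == (1.0, 1.0, 1.0)
        assert len(table.deciles) == 10
        assert np.isfinite(table.aic)

    def test_hazard_gradient_recovered(self, survival_setup):
        coh, metric = survival_setup
        table = pa.cox_deciles(metric, coh)
        from scipy.stats import spearmanr

        assert spearmanr(table.deciles["decile"], table.deciles["hr"]).statistic >= 0.9

    def test_ties_assigned_to_lower_decile(self):
        values = pd.Series(np.repeat([1.0, 2.0], 50), index=range(100))
        dec = metric_deciles(values)
        assert set(dec.unique()) <= {1, 6}
        assert (dec[values == 1.0] == 1).all()

    def test_missing_survival_columns_rejected(self, small_cohort):
        metric = pd.Series(0.0, index=small_cohort.cohort["id"])
        with pytest.raises(CohortError):
            pa.cox_deciles(metric, small_cohort.cohort)


class TestAssociations:
    @pytest.fixture(scope="class")
    def assoc_setup(self):
        effects = tuple(
            pa.EffectSpec(f"v{i}", "linear", amplitude=10.0, noise_sd=0.3, baseline_sd=1.0)
            for i in range(6)
        )
        syn = pa.generate_cohort(pa.GeneratorConfig(n_individuals=10_000, effects=effects, seed=51))
        return syn

    def test_planted_two_year_shift_recovered(self, assoc_setup):
        rng = np.random.default_rng(51)
        exposed = rng.random(len(assoc_setup.cohort)) < 0.3
        metric = pd.Series(
            assoc_setup.true_deviation.to_numpy() + 2.0 * exposed, index=assoc_setup.cohort["id"]
        )
        res = pa.associate_covariates(
            metric, assoc_setup.cohort, {"exposure": pd.Series(np.where(exposed, "yes", "no"))}
        )[0]
        assert res.coefficients["coef"].iloc[0] == pytest.approx(2.0, abs=0.3)

    def test_independent_covariate_is_null(self, assoc_setup):
        metric = pd.Series(assoc_setup.true_deviation.to_numpy(), index=assoc_setup.cohort["id"])
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            cov = pd.Series(np.where(rng.random(len(assoc_setup.cohort)) < 0.3, "yes", "no"))
            res = pa.associate_covariates(metric, assoc_setup.cohort, {"x": cov})[0]
            row = res.coefficients.iloc[0]
            hits += (abs(row["coef"]) < 0.2) and (row["p"] > 0.01)
        assert hits >= 9

    def test_daic_zero_for_best_model(self, assoc_setup):
        metric = pd.Series(assoc_setup.true_deviation.to_numpy(), index=assoc_setup.cohort["id"])
        noisy = metric + np.random.default_rng(0).normal(0, 5, len(metric))
        cov = pd.Series(np.where(metric.to_numpy() > 0, "hi", "lo"))
        results = {
            "sharp": pa.associate_covariates(metric, assoc_setup.cohort, {"c": cov})[0],
            "noisy": pa.associate_covariates(noisy, assoc_setup.cohort, {"c": cov})[0],
        }
        table = pa.compare_aic(results)
        assert table["daic"].min() == 0.0

    def test_single_category_rejected(self, assoc_setup):
        metric = pd.Series(assoc_setup.true_deviation.to_numpy(), index=assoc_setup.cohort["id"])
        with pytest.raises(CohortError):
            pa.associate_covariates(
                metric, assoc_setup.cohort, {"c": pd.Series(["same"] * len(assoc_setup.cohort))}
            )
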