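"""Residualized regression: FWL identity against a full-design
least-squares oracle, surrogate-variable behaviour, and fit invariances."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import veganome as v
from veganome.containers import AbundanceMatrix
from veganome.regression import DesignInfo, SurrogateModel, residualize


def _design_from_rng(rng, n):
    cov = pd.DataFrame(
        {
            "age": rng.normal(60, 10, n),
            "sex": rng.integers(0, 2, n).astype(float),
            "race": rng.integers(0, 2, n).astype(float),
            "bmi": rng.normal(27, 4, n),
        },
        index=[f"s{i}" for i in range(n)],
    )
    diet = np.zeros(n)
    diet[: n // 2] = 1.0
    return DesignInfo(diet=rng.permutation(diet), covariates=cov)


def _log_matrix(rng, n, p):
    vals = pd.DataFrame(
        rng.normal(0, 1, (n, p)),
        index=[f"s{i}" for i in range(n)],
        columns=[f"m{j}" for j in range(p)],
    )
    return AbundanceMatrix(vals, state="log")


class TestResidualize:
    def test_projection_annihilates_column_space(self):
        rng = np.random.default_rng(0)
        Q = rng.normal(size=(15, 3))
        c = rng.normal(size=(3, 4))
        out = residualize(Q @ c, Q)
        np.testing.assert_allclose(out, 0.0, atol=1e-10)

    def test_intercept_only_centers_columns(self):
        rng = np.random.default_rng(1)
        M = rng.normal(size=(12, 5))
        out = residualize(M, np.ones((12, 1)))
        np.testing.assert_allclose(out, M - M.mean(axis=0), atol=1e-12)

    def test_projection_is_a_contraction(self):
        rng = np.random.default_rng(2)
        M = rng.normal(size=(20, 6))
        Q = rng.normal(size=(20, 4))
        out = residualize(M, Q)
        assert np.all(
            np.linalg.norm(out, axis=0) <= np.linalg.norm(M, axis=0) + 1e-12
        )
        np.testing.assert_allclose(Q.T @ out, 0.0, atol=1e-8)

    def test_rank_deficient_design_rejected_with_columns(self):
        Q = np.ones((10, 2))
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            residualize(np.random.default_rng(3).normal(size=(10, 2)), Q)


class TestFwlIdentity:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_design_ols_on_small_toys(self, seed):
        """Two-step residualized fit equals the diet coefficient of the
        full multiple regression (12 samples, 3 metabolites)."""
        rng = np.random.default_rng(seed)
        n, p = 12, 3
        design = _design_from_rng(rng, n)
        Y = _log_matrix(rng, n, p)
        fits = v.fit_metabolite_models(Y, design)
        X_full = np.column_stack([
            design.diet, np.ones(n),
            design.covariates[["age", "sex", "race"]].to_numpy(),
        ])
        for j in range(p):
            ols = sm.OLS(Y.to_numpy()[:, j], X_full).fit()
            np.testing.assert_allclose(fits.table["beta"].iloc[j],
                                       ols.params[0], rtol=1e-10)
            np.testing.assert_allclose(fits.table["se"].iloc[j],
                                       ols.bse[0], rtol=1e-10)
            np.testing.assert_allclose(fits.table["t"].iloc[j],
                                       ols.tvalues[0], rtol=1e-10)
            assert fits.df == int(ols.df_resid)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_fwl_identity_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 25))
        design = _design_from_rng(rng, n)
        Y = _log_matrix(rng, n, 2)
        fits = v.fit_metabolite_models(Y, design)
        X_full = np.column_stack([
            design.diet, np.ones(n),
            design.covariates[["age", "sex", "race"]].to_numpy(),
        ])
        beta_full = np.linalg.lstsq(X_full, Y.to_numpy(), rcond=None)[0][0]
        np.testing.assert_allclose(fits.beta, beta_full, rtol=1e-9, atol=1e-12)

    def test_sv_block_enters_full_design_equivalently(self):
        rng = np.random.default_rng(42)
        n, p, k = 30, 4, 2
        design = _design_from_rng(rng, n)
        Y = _log_matrix(rng, n, p)
        scores = np.linalg.qr(
            rng.normal(size=(n, k)) - rng.normal(size=(n, k)).mean(0)
        )[0]
        sv = SurrogateModel(sv_scores=scores, k=k)
        fits = v.fit_metabolite_models(Y, design, sv=sv)
        X_full = np.column_stack([
            design.diet, np.ones(n),
            design.covariates[["age", "sex", "race"]].to_numpy(), scores,
        ])
        for j in range(p):
            ols = sm.OLS(Y.to_numpy()[:, j], X_full).fit()
            np.testing.assert_allclose(fits.table["t"].iloc[j],
                                       ols.tvalues[0], rtol=1e-8)


class TestFitInvariances:
    def test_constant_shift_moves_means_not_effect(self):
        rng = np.random.default_rng(5)
        design = _design_from_rng(rng, 24)
        Y = _log_matrix(rng, 24, 3)
        base = v.fit_metabolite_models(Y, design)
        shifted_vals = Y.values.copy()
        shifted_vals.iloc[:, 1] += 2.5
        shifted = v.fit_metabolite_models(
            AbundanceMatrix(shifted_vals, state="log"), design
        )
        row_b, row_s = base.table.iloc[1], shifted.table.iloc[1]
        np.testing.assert_allclose(row_s["beta"], row_b["beta"], atol=1e-12)
        np.testing.assert_allclose(row_s["t"], row_b["t"], atol=1e-10)
        np.testing.assert_allclose(row_s["fold_change"], row_b["fold_change"])
        np.testing.assert_allclose(
            row_s["adj_mean_vegan"], row_b["adj_mean_vegan"] + 2.5
        )
        np.testing.assert_allclose(
            row_s["adj_mean_nonveg"], row_b["adj_mean_nonveg"] + 2.5
        )

    def test_consistent_sample_permutation_leaves_fits_unchanged(self):
        rng = np.random.default_rng(6)
        n = 26
        design = _design_from_rng(rng, n)
        Y = _log_matrix(rng, n, 3)
        base = v.fit_metabolite_models(Y, design)
        perm = rng.permutation(n)
        design_p = DesignInfo(
            diet=design.diet[perm], covariates=design.covariates.iloc[perm]
        )
        Yp = AbundanceMatrix(Y.values.iloc[perm], state="log")
        out = v.fit_metabolite_models(Yp, design_p)
        pd.testing.assert_frame_equal(base.table, out.table)

    def test_fold_change_is_exponentiated_mean_difference(self):
        rng = np.random.default_rng(7)
        design = _design_from_rng(rng, 24)
        Y = _log_matrix(rng, 24, 2)
        fits = v.fit_metabolite_models(Y, design)
        diff = fits.table["adj_mean_vegan"] - fits.table["adj_mean_nonveg"]
        np.testing.assert_allclose(fits.table["fold_change"], np.exp(diff))
        np.testing.assert_allclose(
            np.sign(np.log(fits.table["fold_change"])),
            np.sign(fits.table["beta"]),
        )
        assert math.isclose(math.exp(0.5), 1.6487, rel_tol=1e-4)


class TestSurrogateEstimation:
    def test_strong_latent_factor_count_recovered(self):
        hits = 0
        for seed in range(10):
            cfg = v.SimulationConfig(
                n_vegan=47, n_nonveg=46, n_metabolites=200,
                subclass_sizes=[10] * 20, frac_nonnull=0.0, n_latent=3,
                latent_sd=1.0, within_subclass_rho=0.0, censor_quantile=0.0,
                seed=800 + seed,
            )
            ds = v.generate_cohort(cfg)
            Y = v.preprocess_pipeline(ds.raw, ds.metadata.table["diet"].to_numpy())
            design = DesignInfo.from_metadata(ds.metadata)
            sv = v.estimate_surrogates(Y, design, n_sv="auto", seed=seed)
            hits += sv.k == 3
        assert hits >= 9

    def test_sv_scores_centered_and_orthogonal(self, small_fits):
        ds, Y, design, _ = small_fits
        sv = v.estimate_surrogates(Y, design, n_sv=2, seed=0)
        np.testing.assert_allclose(sv.sv_scores.mean(axis=0), 0.0, atol=1e-8)
        gram = sv.sv_scores.T @ sv.sv_scores
        np.testing.assert_allclose(gram, np.eye(2), atol=1e-8)

    def test_no_latent_structure_limits_diet_leakage(self):
        cors = []
        for seed in range(5):
            cfg = v.SimulationConfig(
                n_vegan=47, n_nonveg=46, n_metabolites=200,
                subclass_sizes=[10] * 20, frac_nonnull=0.0, n_latent=0,
                within_subclass_rho=0.0, censor_quantile=0.0, seed=900 + seed,
            )
            ds = v.generate_cohort(cfg)
            Y = v.preprocess_pipeline(ds.raw, ds.metadata.table["diet"].to_numpy())
            design = DesignInfo.from_metadata(ds.metadata)
            sv = v.estimate_surrogates(Y, design, n_sv=2, seed=seed)
            # canonical correlation of the SV pair with diet
            x = design.diet - design.diet.mean()
            proj = sv.sv_scores.T @ x / np.linalg.norm(x)
            cors.append(np.linalg.norm(proj))
        assert np.median(cors) < 0.3

    def test_excessive_k_rejected(self, small_fits):
        ds, Y, design, _ = small_fits
        with pytest.raises(ValueError):
            v.estimate_surrogates(Y, design, n_sv=Y.n_samples, seed=0)


class TestModelBehaviour:
    def test_null_metabolites_have_unit_mean_fold_change(self):
        cfg = v.SimulationConfig(
            n_vegan=47, n_nonveg=46, n_metabolites=500,
            subclass_sizes=[10] * 50, frac_nonnull=0.0, n_latent=0,
            within_subclass_rho=0.0, censor_quantile=0.0, seed=13,
        )
        ds = v.generate_cohort(cfg)
        Y = v.preprocess_pipeline(ds.raw, ds.metadata.table["diet"].to_numpy())
        fits = v.fit_unadjusted_models(Y, DesignInfo.from_metadata(ds.metadata))
        assert 0.95 <= fits.table["fold_change"].mean() <= 1.05
        assert np.median(np.abs(fits.t)) < 2.0

    def test_unadjusted_equals_model_with_zero_svs(self, small_fits):
        ds, Y, design, _ = small_fits
        a = v.fit_unadjusted_models(Y, design)
        b = v.fit_metabolite_models(Y, design, sv=None)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_effect_recovery_at_study_scale(self):
        """n=93, delta=log 1.5, sigma=0.5: median absolute error of the
        estimated log fold change stays below 0.1."""
        errs = []
        for seed in range(2):
            cfg = v.SimulationConfig(
                n_vegan=47, n_nonveg=46, n_metabolites=200,
                subclass_sizes=[10] * 20, frac_nonnull=0.5,
                effect_log_fc=v.EffectSpec(math.log(1.5), 0.0, 0.5),
                n_latent=0, within_subclass_rho=0.0, residual_sd=0.5,
                censor_quantile=0.0, seed=20 + seed,
            )
            ds = v.generate_cohort(cfg)
            Y = v.preprocess_pipeline(ds.raw, ds.metadata.table["diet"].to_numpy())
            fits = v.fit_unadjusted_models(Y, DesignInfo.from_metadata(ds.metadata))
            nonnull = ds.truth.nonnull_set
            errs.extend(np.abs(fits.beta[nonnull] - ds.truth.delta[nonnull]))
        assert np.median(errs) < 0.1

    def test_sva_recovers_power_lost_to_unwanted_variation(self):
        """With diet-orthogonal latent variation, the SV-adjusted model
        finds at least as many discoveries as the unadjusted one."""
        from veganome.fdr import fdr_pipeline

        cfg = v.SimulationConfig(
            n_vegan=47, n_nonveg=46, n_metabolites=200,
            subclass_sizes=[10] * 20, frac_nonnull=0.2,
            effect_log_fc=v.EffectSpec(math.log(1.4), 0.0, 0.5),
            n_latent=3, latent_sd=1.0, within_subclass_rho=0.0,
            censor_quantile=0.0, seed=21,
        )
        ds = v.generate_cohort(cfg)
        Y = v.preprocess_pipeline(ds.raw, ds.metadata.table["diet"].to_numpy())
        design = DesignInfo.from_metadata(ds.metadata)
        sv = v.estimate_surrogates(Y, design, n_sv="auto", seed=1)
        adj = v.fit_metabolite_models(Y, design, sv=sv)
        unadj = v.fit_unadjusted_models(Y, design)
        n_adj = fdr_pipeline(adj.residual_y, adj.residual_x, adj.df,
                             B=300, seed=1, t_obs=adj.t,
                             nuisance=adj.nuisance).n_significant()
        n_un = fdr_pipeline(unadj.residual_y, unadj.residual_x, unadj.df,
                            B=300, seed=1, t_obs=unadj.t,
                            nuisance=unadj.nuisance).n_significant()
        assert n_adj >= n_un
        # betas agree within 2 se on unconfounded data
        close = np.abs(adj.beta - unadj.beta) <= 2 * unadj.table["se"].to_numpy()
        assert close.mean() > 0.95
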