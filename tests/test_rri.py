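"""Criterion model: OLS equivalence, factor scoring, latent correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from reserveml import rri, synthetic
from reserveml.rri import RRISpec, fit_rri, latent_correlation, score_rri


@pytest.fixture(scope="module")
def cohort():
    cfg = synthetic.GenerativeConfig(n_participants=3000, seed=42)
    table, latents = synthetic.simulate_model_building_cohort(cfg)
    return cfg, table, latents


def _ols_oracle(cohort_df, spec):
    """Normal-equations least squares, independent of the fitting path."""
    cols = [
        cohort_df[c].to_numpy(float)
        for c in spec.brain_predictors + spec.demographic_predictors + spec.exposure_predictors
    ]
    a, b = spec.exposure_interaction
    cols.append(cohort_df[a].to_numpy(float) * cohort_df[b].to_numpy(float))
    X = np.column_stack([np.ones(len(cohort_df))] + cols)
    y = cohort_df[spec.memory_indicator].to_numpy(float)
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    return X, y, beta


def test_fit_equals_normal_equations_ols(cohort):
    _, table, _ = cohort
    spec = RRISpec()
    params = fit_rri(table, spec)
    X, y, beta = _ols_oracle(table, spec)
    fitted = np.array([params.intercept] + list(params.path_coefficients.values()))
    np.testing.assert_allclose(fitted, beta, atol=1e-10)
    resid = y - X @ beta
    assert params.residual_variance == pytest.approx(resid @ resid / len(y), abs=1e-12)


def test_parameter_recovery_at_large_n():
    cfg = synthetic.GenerativeConfig(n_participants=100_000, seed=77)
    table, _ = synthetic.simulate_model_building_cohort(cfg)
    params = fit_rri(table)
    mc = cfg.memory_coeffs
    truth = {
        "gm_signature": mc["gm"],
        "log_wmh": mc["wmh"],
        "sex": mc["sex"],
        "black_aa": mc["black_aa"],
        "hispanic": mc["hispanic"],
        "prior_exposure": mc["exposure"],
        "spanish": mc["spanish"],
        "prior_exposure:spanish": mc["exposure_spanish"],
    }
    X, y, beta = _ols_oracle(table, RRISpec())
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    ses = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    for j, (name, true_val) in enumerate(truth.items(), start=1):
        assert abs(params.path_coefficients[name] - true_val) < 3 * ses[j], name


def test_constant_memory_degenerate(cohort):
    _, table, _ = cohort
    flat = table.copy()
    flat["memory"] = 1.3
    params = fit_rri(flat)
    assert params.residual_variance == pytest.approx(0.0, abs=1e-20)
    for value in params.path_coefficients.values():
        assert value == pytest.approx(0.0, abs=1e-10)


def test_rank_deficient_design_names_columns(cohort):
    _, table, _ = cohort
    broken = table.copy()
    broken["log_wmh"] = broken["gm_signature"]
    with pytest.raises(ValueError, match="collinear"):
        fit_rri(broken)


def test_scores_equal_residuals_zero_measurement_error(cohort):
    _, table, _ = cohort
    spec = RRISpec()
    params = fit_rri(table, spec)
    scores = score_rri(params, table)
    X, y, beta = _ols_oracle(table, spec)
    resid = y - X @ beta
    np.testing.assert_allclose(scores.raw.to_numpy(), resid, atol=1e-10)
    assert scores.determinacy == 1.0


def test_scores_standardized(cohort):
    _, table, _ = cohort
    scores = score_rri(fit_rri(table), table)
    assert scores.rri.mean() == pytest.approx(0.0, abs=1e-9)
    assert scores.rri.std(ddof=0) == pytest.approx(1.0, abs=1e-9)


def test_shrinkage_matches_conditional_gaussian_oracle(cohort):
    """With measurement error, the posterior mean of the latent residual given
    the observed residual is psi/(psi+sigma_m^2) times the raw residual."""
    _, table, _ = cohort
    sigma_m2 = 0.2
    spec = RRISpec(measurement_error_variance=sigma_m2)
    params = fit_rri(table, spec)
    scores = score_rri(params, table)
    X, y, beta = _ols_oracle(table, spec)
    resid = y - X @ beta
    psi = params.residual_variance
    # conditional-Gaussian oracle: E[R | resid] for jointly normal (R, resid)
    oracle = (psi / (psi + sigma_m2)) * resid
    np.testing.assert_allclose(scores.raw.to_numpy(), oracle, atol=1e-8)
    assert params.determinacy == pytest.approx(psi / (psi + sigma_m2))


def test_missing_predictors_scored_missing(cohort):
    _, table, _ = cohort
    damaged = table.copy()
    damaged.loc[damaged.index[:7], "gm_signature"] = np.nan
    params = fit_rri(damaged)
    assert params.n_dropped_missing == 7
    scores = score_rri(params, damaged)
    assert scores.n_missing == 7
    assert scores.rri.isna().sum() == 7


def test_latent_correlation_self_is_one(cohort):
    _, table, _ = cohort
    params = fit_rri(table)
    scores = score_rri(params, table)
    r, se = latent_correlation(params, table, scores.rri)
    assert r == pytest.approx(1.0, abs=1e-12)


def test_latent_correlation_null_proxy(cohort):
    cfg = synthetic.GenerativeConfig(n_participants=100_000, seed=11)
    table, _ = synthetic.simulate_model_building_cohort(cfg)
    params = fit_rri(table)
    rng = np.random.default_rng(0)
    noise = pd.Series(rng.normal(size=len(table)), index=pd.Index(table["id"], name="id"))
    r, _ = latent_correlation(params, table, noise)
    assert abs(r) < 0.02


def test_latent_correlation_disattenuation_vs_numeric_mle(cohort):
    """With measurement error the latent correlation equals the numeric MLE of
    the single free correlation parameter in the fixed-parameter model."""
    _, table, _ = cohort
    sigma_m2 = 0.25
    spec = RRISpec(measurement_error_variance=sigma_m2)
    params = fit_rri(table, spec)
    rng = np.random.default_rng(3)
    # proxy = latent part plus noise; build from raw residual for realism
    resid = score_rri(params, table).raw / params.determinacy
    proxy = 0.6 * resid + rng.normal(0, 0.8, len(resid))
    proxy = pd.Series(proxy.to_numpy(), index=resid.index)
    r_impl, _ = latent_correlation(params, table, proxy)

    # oracle: maximise the bivariate-normal likelihood of (proxy, resid) over
    # the latent correlation rho, other parameters fixed at their MLEs
    p = (proxy - proxy.mean()).to_numpy() / proxy.std(ddof=0)
    d = resid.to_numpy()
    psi, det = params.residual_variance, params.determinacy
    var_d = psi + sigma_m2

    def neg_loglik(rho):
        # corr(proxy, resid) implied by latent corr rho: rho * sqrt(det)
        r_obs = rho * np.sqrt(det)
        cov = np.array([[1.0, r_obs * np.sqrt(var_d)], [r_obs * np.sqrt(var_d), var_d]])
        inv = np.linalg.inv(cov)
        z = np.column_stack([p, d])
        return 0.5 * len(p) * np.log(np.linalg.det(cov)) + 0.5 * np.einsum(
            "ij,jk,ik->", z, inv, z
        )

    res = minimize_scalar(neg_loglik, bounds=(-0.999, 0.999), method="bounded")
    assert r_impl == pytest.approx(res.x, abs=1e-3)


def test_zero_variance_proxy_rejected(cohort):
    _, table, _ = cohort
    params = fit_rri(table)
    flat = pd.Series(0.5, index=pd.Index(table["id"], name="id"))
    with pytest.raises(ValueError, match="zero variance"):
        latent_correlation(params, table, flat)


def test_scores_invariant_to_predictor_rescaling(cohort):
    _, table, _ = cohort
    scaled = table.copy()
    scaled["gm_signature"] = scaled["gm_signature"] * 13.0 + 5.0
    a = score_rri(fit_rri(table), table).rri
    b = score_rri(fit_rri(scaled), scaled).rri
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)


def test_loglik_maximal_at_mle(cohort):
    """The Gaussian log-likelihood at the fitted parameters beats random
    perturbations of the coefficient vector."""
    _, table, _ = cohort
    spec = RRISpec()
    params = fit_rri(table, spec)
    X, y, beta = _ols_oracle(table, spec)

    def loglik(b, s2):
        r = y - X @ b
        return -0.5 * len(y) * np.log(2 * np.pi * s2) - 0.5 * r @ r / s2

    best = loglik(beta, params.residual_variance)
    rng = np.random.default_rng(5)
    for _ in range(20):
        perturbed = beta + rng.normal(0, 0.05, beta.shape)
        s2 = params.residual_variance * np.exp(rng.normal(0, 0.2))
        assert loglik(perturbed, s2) <= best
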