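"""Generator correctness: determinism, calibration, and generative identity."""

import numpy as np
import pandas as pd
import pytest

from reserveml import synthetic
from reserveml.synthetic import ConfigurationError, GenerativeConfig, null_config


def test_seeded_determinism():
    cfg = GenerativeConfig(n_participants=500, seed=1)
    a, la = synthetic.simulate_model_building_cohort(cfg)
    b, lb = synthetic.simulate_model_building_cohort(cfg)
    pd.testing.assert_frame_equal(a, b)
    np.testing.assert_array_equal(la.reserve, lb.reserve)
    assert len(a) == 500


def test_validation_determinism_and_missing_features():
    cfg = GenerativeConfig(n_participants=120, seed=4)
    c1, l1, _ = synthetic.simulate_validation_cohort(cfg)
    c2, l2, _ = synthetic.simulate_validation_cohort(cfg)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(l1, l2)
    # features the validation studies never collected are entirely missing
    assert c1["waist"].isna().all()
    assert c1["hip"].isna().all()
    assert c1["screener"].notna().all()


@pytest.mark.parametrize(
    "field,value",
    [
        ("sex_prob", 1.5),
        ("race_ethnicity_probs", (0.5, 0.2, 0.2)),
        ("reserve_sd", -1.0),
        ("n_visits", 1),
    ],
)
def test_invalid_config_rejected(field, value):
    with pytest.raises(ConfigurationError, match=field.split("_")[0]):
        GenerativeConfig(**{field: value})


def test_reserve_sd_zero_degenerate():
    cfg = GenerativeConfig(n_participants=4000, seed=2, reserve_sd=0.0)
    cohort, latents = synthetic.simulate_model_building_cohort(cfg)
    assert np.var(latents.reserve) == 0.0
    # residual variance after regressing memory on its literal generators
    # collapses to the memory noise variance
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            cohort.gm_signature,
            cohort.log_wmh,
            cohort.sex,
            cohort.black_aa,
            cohort.hispanic,
            cohort.prior_exposure,
            cohort.spanish,
            cohort.prior_exposure * cohort.spanish,
        ]
    )
    beta, *_ = np.linalg.lstsq(X, cohort.memory.to_numpy(), rcond=None)
    resid = cohort.memory.to_numpy() - X @ beta
    sigma = cfg.noise_sds["memory"]
    assert np.std(resid) == pytest.approx(sigma, rel=0.1)


def test_partial_correlation_of_reserve_with_memory():
    """Partialling out the observed generators, memory correlates with R at
    nearly the closed-form ceiling reserve_sd / sqrt(reserve_sd^2 + sigma^2)."""
    cfg = GenerativeConfig(n_participants=100_000, seed=3)
    cohort, latents = synthetic.simulate_model_building_cohort(cfg)
    X = np.column_stack(
        [
            np.ones(len(cohort)),
            cohort.gm_signature,
            cohort.log_wmh,
            cohort.sex,
            cohort.black_aa,
            cohort.hispanic,
            cohort.prior_exposure,
            cohort.spanish,
            cohort.prior_exposure * cohort.spanish,
        ]
    )
    beta, *_ = np.linalg.lstsq(X, cohort.memory.to_numpy(), rcond=None)
    resid = cohort.memory.to_numpy() - X @ beta
    r = np.corrcoef(resid, latents.reserve)[0, 1]
    ceiling = cfg.reserve_sd / np.hypot(cfg.reserve_sd, cfg.noise_sds["memory"])
    assert r >= 0.9 * ceiling


def test_marginal_calibration_against_analytic_oracle():
    cfg = GenerativeConfig(n_participants=100_000, seed=9)
    cohort, _ = synthetic.simulate_model_building_cohort(cfg)
    n = len(cohort)
    for col, (mean, sd) in synthetic.expected_marginals(cfg).items():
        se_mean = sd / np.sqrt(n)
        se_sd = sd / np.sqrt(2 * n)
        assert abs(cohort[col].mean() - mean) < 3 * se_mean, col
        assert abs(cohort[col].std(ddof=0) - sd) < 3 * se_sd, col


def test_generative_identity_memory_coefficients():
    """Regressing memory on its literal generators (including the latent R)
    recovers the configured coefficients within 3 SEs at n=100000."""
    cfg = GenerativeConfig(n_participants=100_000, seed=5)
    cohort, latents = synthetic.simulate_model_building_cohort(cfg)
    mc = cfg.memory_coeffs
    cols = {
        "gm": cohort.gm_signature,
        "wmh": cohort.log_wmh,
        "sex": cohort.sex,
        "black_aa": cohort.black_aa,
        "hispanic": cohort.hispanic,
        "exposure": cohort.prior_exposure,
        "spanish": cohort.spanish,
        "exposure_spanish": cohort.prior_exposure * cohort.spanish,
        "reserve": latents.reserve,
    }
    X = np.column_stack([np.ones(len(cohort))] + [np.asarray(v, float) for v in cols.values()])
    y = cohort.memory.to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    cov = sigma2 * np.linalg.inv(X.T @ X)
    ses = np.sqrt(np.diag(cov))
    truth = {**mc, "reserve": 1.0}
    for j, name in enumerate(cols, start=1):
        assert abs(beta[j] - truth[name]) < 3 * ses[j], name


def test_reserve_mean_near_zero():
    cfg = GenerativeConfig(n_participants=2000, seed=8)
    _, latents = synthetic.simulate_model_building_cohort(cfg)
    assert abs(latents.reserve.mean()) < 5 / np.sqrt(2000)


def test_gm_change_zero_at_baseline_and_time_monotone():
    cfg = GenerativeConfig(n_participants=60, seed=6)
    _, longi, _ = synthetic.simulate_validation_cohort(cfg)
    base = longi[longi.time == 0]
    assert (base.gm_change == 0).all()
    assert set(base.id) == set(longi.id)
    assert (longi.groupby("id").time.diff().dropna() > 0).all()


def test_moderation_sign_by_reserve_decile():
    """Positive moderation_theta attenuates EF decline per unit of grey-matter
    change: top reserve decile declines less steeply than the bottom decile."""
    cfg = GenerativeConfig(n_participants=4000, seed=7)
    _, longi, latents = synthetic.simulate_validation_cohort(cfg)
    z = pd.Series(latents.reserve, index=latents.ids)
    last = longi[longi.time == longi.time.max()].set_index("id")
    delta_ef = last.ef - longi[longi.time == 0].set_index("id").ef

    def change_coefficient(ids):
        X = np.column_stack([np.ones(len(ids)), last.gm_change.loc[ids]])
        beta, *_ = np.linalg.lstsq(X, delta_ef.loc[ids].to_numpy(), rcond=None)
        return beta[1]

    top = change_coefficient(z[z >= z.quantile(0.9)].index)
    bottom = change_coefficient(z[z <= z.quantile(0.1)].index)
    assert abs(top) < abs(bottom)


def test_null_config_only_changes_theta_and_is_idempotent():
    cfg = GenerativeConfig(n_participants=50, seed=1)
    nc = null_config(cfg)
    assert nc.moderation_theta == 0.0
    assert null_config(nc) == nc
    assert nc.replace(moderation_theta=cfg.moderation_theta) == cfg


def test_null_config_interaction_coefficient_is_zero_at_large_n():
    """Under the null configuration, regressing EF on the generative terms
    gives a reserve x gm_change coefficient indistinguishable from zero."""
    cfg = null_config(GenerativeConfig(n_participants=20_000, seed=10, n_visits=3))
    _, longi, latents = synthetic.simulate_validation_cohort(cfg)
    z = pd.Series(latents.reserve / cfg.reserve_sd, index=latents.ids)
    d = longi.assign(z=longi.id.map(z))
    X = np.column_stack(
        [
            np.ones(len(d)),
            d.time,
            d.gm_baseline,
            d.gm_change,
            d.gm_baseline * d.time,
            d.z,
            d.z * d.time,
            d.z * d.gm_baseline,
            d.z * d.gm_change,
        ]
    )
    y = d.ef.to_numpy()
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(y) - X.shape[1])
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    assert abs(beta[-1]) < 4 * se[-1]
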