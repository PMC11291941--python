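"""Synthetic cohort generation with known latent reserve structure.

The real pipeline was designed for restricted clinical cohorts (memory-clinic
and ageing-study data with MRI).  This module generates cross-sectional and
longitudinal cohorts from an explicit generative model in which the latent
cognitive reserve ``R`` is *known*, so that every downstream stage — criterion
construction, surrogate training, and longitudinal moderation testing — can be
validated against ground truth.

Generative structure (defaults; everything is configurable):

* ``disease_stage ~ N(0, 1)`` — continuous neurodegeneration severity.
* ``R ~ N(0, reserve_sd^2)`` — latent reserve, independent of stage.
* Brain scalars (grey-matter signature, log white-matter-hyperintensity
  volume) are linear in age and disease stage plus noise.
* Episodic memory is linear in brain scalars, demographics, test-exposure
  terms, plus ``R`` and residual noise — so the residual of memory given its
  observed generators is ``R + noise``, mirroring the residual-reserve
  operationalisation.
* Clinical features (screener, word reading, depression, informant ratings,
  vitals, anthropometrics) are linear-Gaussian in (standardised R, disease
  stage, demographics), then rounded/clamped into their legal ranges.
  Informant-rated severity instruments (CDR, ECog) are monotone transforms of
  a shared latent severity score ``disease_stage - lambda_sev * z_R + noise``.
* Longitudinal executive function follows a linear mixed model whose
  grey-matter-change slope effect is attenuated by reserve through the
  interaction coefficient ``moderation_theta``.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "GenerativeConfig",
    "TrueLatents",
    "simulate_model_building_cohort",
    "simulate_validation_cohort",
    "null_config",
    "expected_marginals",
]


class ConfigurationError(ValueError):
    """Raised when a generative configuration field is invalid."""


def _default_reserve_loadings() -> dict[str, float]:
    # Raw feature units per 1 SD of latent reserve.  Screener, word reading
    # and the informant-severity discount are strong; vitals/anthropometrics
    # deliberately weak, so the Minimal feature tier carries little reserve
    # signal relative to the Extended/Full tiers.
    return {
        "education": 0.8,
        "word_reading": 1.8,
        "screener": 1.5,
        "depression": -0.35,
        "severity": -0.80,       # SD units of the latent informant-severity score
        "self_concern": -0.3,    # logit units
        "sbp": -0.5,
        "dbp": -0.3,
        "heart_rate": -0.3,
        "height": 0.002,
        "weight": 0.0,
        "waist": -0.2,
        "hip": 0.1,
    }


def _default_brain_coeffs() -> dict[str, float]:
    return {
        "gm_age": -0.035,     # per year of age
        "gm_stage": -0.55,    # per SD of disease stage
        "wmh_age": 0.030,
        "wmh_stage": 0.35,
    }


def _default_memory_coeffs() -> dict[str, float]:
    return {
        "gm": 0.45,
        "wmh": -0.15,
        "sex": -0.10,
        "black_aa": -0.25,
        "hispanic": -0.20,
        "exposure": 0.25,
        "spanish": -0.10,
        "exposure_spanish": 0.20,
    }


def _default_noise_sds() -> dict[str, float]:
    return {
        "memory": 0.35,
        "gm": 0.60,
        "wmh": 0.80,
        "screener": 1.3,
        "word_reading": 5.5,
        "depression": 1.4,
        "severity": 0.45,
        "sbp": 14.0,
        "dbp": 9.5,
        "heart_rate": 10.5,
        "height": 0.095,
        "bmi": 5.0,
        "waist": 9.0,
        "hip": 7.0,
        "ef": 0.28,
    }


def _default_ef_coeffs() -> dict[str, float]:
    # Fixed effects of the longitudinal executive-function model.  The
    # slope-moderation pathway (reserve x grey-matter change) is governed
    # separately by ``moderation_theta`` so that the null configuration only
    # has to zero a single coefficient.
    return {
        "intercept": 0.0,
        "age0": -0.010,          # per year, centred at the configured mean
        "educ": 0.020,           # per year, centred at 12
        "sex": -0.05,
        "word_reading": 0.010,   # per point, centred at 32
        "time": -0.06,           # per year
        "gm_baseline": 0.35,
        "gm_baseline_time": 0.02,
        "gm_change": 0.55,
        "reserve": 0.30,         # per SD of R: intercept main effect
        "reserve_time": 0.035,   # per SD of R per year: slope main effect
        "reserve_gmb": 0.30,     # intercept moderation (reserve x baseline GM)
        "reserve_gmb_time": 0.0, # slope moderation via baseline GM (off by default)
    }


@dataclass
class GenerativeConfig:
    """All knobs of the synthetic cohort generator.

    Defaults emulate the demographic and clinical marginals of a combined
    memory-clinic / ageing-cohort model-building sample of ~1665 participants
    (age 74 +/- 7.5, education ~14.6 years, 47% male, screener ~27/30), with a
    longitudinal validation arm of annual visits and mean grey-matter atrophy
    of -0.10 SD/year.
    """

    n_participants: int = 1665
    seed: int = 0

    # demographics
    age_mean: float = 74.3
    age_sd: float = 7.5
    educ_mean: float = 14.6
    educ_sd: float = 4.1          # total SD including the reserve pathway
    sex_prob: float = 0.47        # P(male)
    race_ethnicity_probs: tuple[float, float, float] = (0.143, 0.142, 0.715)
    # probability of Spanish-language test administration among
    # Hispanic/Latinx participants
    spanish_prob: float = 0.5
    prior_exposure_prob: float = 0.06

    # latent structure
    reserve_sd: float = 0.6
    reserve_loadings: dict[str, float] = field(default_factory=_default_reserve_loadings)
    brain_coeffs: dict[str, float] = field(default_factory=_default_brain_coeffs)
    memory_coeffs: dict[str, float] = field(default_factory=_default_memory_coeffs)
    noise_sds: dict[str, float] = field(default_factory=_default_noise_sds)

    # longitudinal arm
    atrophy_rate_mean: float = -0.10   # SD units of GM per year
    atrophy_rate_sd: float = 0.08
    atrophy_stage_coeff: float = -0.06  # extra atrophy per SD of disease stage
    n_visits: int = 4
    visit_interval: float = 1.0
    ef_coeffs: dict[str, float] = field(default_factory=_default_ef_coeffs)
    moderation_theta: float = 0.8      # (reserve z) x (GM change) slope attenuation
    re_sd_intercept: float = 0.35
    re_sd_slope: float = 0.08
    re_corr: float = -0.20
    missing_feature_list: tuple[str, ...] = ("waist", "hip")

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        for name in ("sex_prob", "spanish_prob", "prior_exposure_prob"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {p}")
        probs = np.asarray(self.race_ethnicity_probs, dtype=float)
        if probs.shape != (3,) or (probs < 0).any():
            raise ConfigurationError("race_ethnicity_probs must be 3 non-negative values")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ConfigurationError(
                f"race_ethnicity_probs must sum to 1 (got {probs.sum():.15f})"
            )
        for name in ("age_sd", "educ_sd", "reserve_sd", "atrophy_rate_sd",
                     "re_sd_intercept", "re_sd_slope"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for key, sd in self.noise_sds.items():
            if sd < 0:
                raise ConfigurationError(f"noise_sds[{key!r}] must be >= 0")
        if self.n_visits < 2:
            raise ConfigurationError("n_visits must be >= 2 (slope unidentifiable otherwise)")
        if not (-1.0 < self.re_corr < 1.0):
            raise ConfigurationError("re_corr must lie in (-1, 1)")

    def replace(self, **kwargs) -> "GenerativeConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TrueLatents:
    """Ground-truth per-participant latent quantities (for validation only)."""

    ids: np.ndarray
    reserve: np.ndarray          # R, on its natural scale (SD = reserve_sd)
    disease_stage: np.ndarray
    gm_baseline: np.ndarray
    gm_slope: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "reserve": self.reserve,
                "disease_stage": self.disease_stage,
                "gm_baseline": self.gm_baseline,
                "gm_slope": self.gm_slope,
            }
        )


def null_config(config: GenerativeConfig) -> GenerativeConfig:
    """Return the same configuration with slope moderation switched off.

    Only ``moderation_theta`` changes; all reserve pathways into the
    executive-function model (main effects, intercept moderation) are kept, so
    the configuration is a proper null for the slope-moderation test.
    """
    return config.replace(moderation_theta=0.0)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


# fixed structural constants of the clinical-feature equations
SCREENER_BASE = 27.0
SCREENER_STAGE = -2.2
EDUCATION_RANGE = (0, 22)
SCREENER_RANGE = (0, 30)


def _discretized_normal_moments(mu: float, sigma: float, lo: int, hi: int):
    """Exact mean/SD of clip(round_half_up(N(mu, sigma^2)), lo, hi)."""
    from scipy.stats import norm

    ks = np.arange(lo, hi + 1)
    upper = np.where(ks == hi, np.inf, ks + 0.5)
    lower = np.where(ks == lo, -np.inf, ks - 0.5)
    p = norm.cdf(upper, mu, sigma) - norm.cdf(lower, mu, sigma)
    mean = float(np.sum(ks * p))
    var = float(np.sum((ks - mean) ** 2 * p))
    return mean, math.sqrt(var)


def expected_marginals(config: GenerativeConfig) -> dict[str, tuple[float, float]]:
    """Closed-form (mean, SD) of selected marginals under the configuration.

    Age is plain normal; education and the screener are normals passed through
    round-half-up and range clipping, for which the exact discretised moments
    are computed.  Used to check simulation calibration against an
    independent analytic oracle.
    """
    lo = config.reserve_loadings
    out = {"age": (config.age_mean, config.age_sd)}
    out["education"] = _discretized_normal_moments(
        config.educ_mean, config.educ_sd, *EDUCATION_RANGE
    )
    z_var = 1.0 if config.reserve_sd > 0 else 0.0
    screener_sd = math.sqrt(
        z_var * lo["screener"] ** 2 + SCREENER_STAGE**2 + config.noise_sds["screener"] ** 2
    )
    out["screener"] = _discretized_normal_moments(
        SCREENER_BASE, screener_sd, *SCREENER_RANGE
    )
    return out


def _simulate_base(config: GenerativeConfig, rng: np.random.Generator):
    """Draw demographics, latents, brain scalars, memory, clinical features."""
    n = config.n_participants
    cf = config.brain_coeffs
    mc = config.memory_coeffs
    ns = config.noise_sds
    lo = config.reserve_loadings

    ids = np.arange(1, n + 1)
    age = rng.normal(config.age_mean, config.age_sd, n)
    sex = rng.binomial(1, config.sex_prob, n)
    race = rng.choice(3, size=n, p=np.asarray(config.race_ethnicity_probs, float))
    black_aa = (race == 0).astype(int)
    hispanic = (race == 1).astype(int)
    spanish = (rng.random(n) < config.spanish_prob).astype(int) * hispanic
    # prior test exposure is concentrated among Spanish-language participants
    # (enrolled before their first scan), keeping the exposure x Spanish
    # interaction populated at realistic cohort sizes
    p_exp = np.where(
        spanish == 1,
        np.minimum(4.0 * config.prior_exposure_prob, 1.0),
        config.prior_exposure_prob,
    )
    prior_exposure = (rng.random(n) < p_exp).astype(int)

    disease_stage = rng.normal(0.0, 1.0, n)
    reserve = rng.normal(0.0, config.reserve_sd, n)
    # z_R: reserve in SD units; degenerate reserve_sd=0 gives z_R = 0
    z_r = reserve / config.reserve_sd if config.reserve_sd > 0 else np.zeros(n)

    age_c = age - config.age_mean
    gm = cf["gm_age"] * age_c + cf["gm_stage"] * disease_stage + rng.normal(0, ns["gm"], n)
    wmh = cf["wmh_age"] * age_c + cf["wmh_stage"] * disease_stage + rng.normal(0, ns["wmh"], n)

    memory = (
        mc["gm"] * gm
        + mc["wmh"] * wmh
        + mc["sex"] * sex
        + mc["black_aa"] * black_aa
        + mc["hispanic"] * hispanic
        + mc["exposure"] * prior_exposure
        + mc["spanish"] * spanish
        + mc["exposure_spanish"] * prior_exposure * spanish
        + reserve
        + rng.normal(0, ns["memory"], n)
    )

    # education: total pre-rounding SD equals the configured educ_sd, with the
    # reserve loading carving out its share
    educ_noise_sd = math.sqrt(max(config.educ_sd**2 - lo["education"] ** 2, 0.0))
    educ = config.educ_mean + lo["education"] * z_r + rng.normal(0, educ_noise_sd, n)
    educ = np.clip(_round_half_up(educ), 0, 22)

    # shared latent severity for informant instruments; reserve buys headroom
    severity = disease_stage + lo["severity"] * z_r + rng.normal(0, ns["severity"], n)

    screener = np.clip(
        _round_half_up(SCREENER_BASE + lo["screener"] * z_r
                       + SCREENER_STAGE * disease_stage
                       + rng.normal(0, ns["screener"], n)),
        *SCREENER_RANGE,
    )
    word_reading = np.clip(
        _round_half_up(32.0 + lo["word_reading"] * z_r + 0.6 * (educ - config.educ_mean)
                       - 1.0 * disease_stage + rng.normal(0, ns["word_reading"], n)),
        0, 45,
    )
    depression = np.clip(
        _round_half_up(1.7 + lo["depression"] * z_r + 0.6 * disease_stage
                       + rng.normal(0, ns["depression"], n)),
        0, 15,
    )

    cdr_sob = np.clip(np.round((1.5 + 2.0 * severity) * 2) / 2.0, 0, 18)
    cdr_memory = np.select(
        [severity < -0.25, severity < 0.6, severity < 1.6, severity < 2.6],
        [0.0, 0.5, 1.0, 2.0],
        default=3.0,
    )
    ecog_total = np.clip(1.76 + 0.55 * severity + rng.normal(0, 0.25, n), 1.0, 4.0)
    ecog_memory = np.clip(2.10 + 0.65 * severity + rng.normal(0, 0.30, n), 1.0, 4.0)
    concern_logit = 0.7 + 1.0 * severity + lo["self_concern"] * z_r
    self_memory_concern = (rng.random(n) < 1.0 / (1.0 + np.exp(-concern_logit))).astype(int)

    dbp = np.clip(74.3 + lo["dbp"] * z_r + rng.normal(0, ns["dbp"], n), 35, 130)
    pulse_pressure = np.clip(
        60.0 + lo["sbp"] * z_r + 0.5 * age_c + rng.normal(0, 14.0, n), 10, 120
    )
    sbp = dbp + pulse_pressure
    heart_rate = np.clip(66.6 + lo["heart_rate"] * z_r + rng.normal(0, ns["heart_rate"], n), 35, 130)

    height = np.clip(
        1.67 + 0.055 * sex + lo["height"] * z_r + rng.normal(0, ns["height"], n), 1.30, 2.10
    )
    bmi = np.clip(27.5 + rng.normal(0, ns["bmi"], n), 15, 55)
    weight = bmi * height**2 + lo["weight"] * z_r
    waist = np.clip(94.0 + 2.2 * (bmi - 27.5) + 4.0 * sex + lo["waist"] * z_r
                    + rng.normal(0, ns["waist"], n), 55, 160)
    hip = np.clip(104.5 + 2.0 * (bmi - 27.5) - 2.0 * sex + lo["hip"] * z_r
                  + rng.normal(0, ns["hip"], n), 65, 170)

    cohort = pd.DataFrame(
        {
            "id": ids,
            "age": age,
            "education": educ,
            "sex": sex,
            "black_aa": black_aa,
            "hispanic": hispanic,
            "spanish": spanish,
            "prior_exposure": prior_exposure,
            "gm_signature": gm,
            "log_wmh": wmh,
            "memory": memory,
            "sbp": sbp,
            "dbp": dbp,
            "heart_rate": heart_rate,
            "height": height,
            "weight": weight,
            "waist": waist,
            "hip": hip,
            "screener": screener,
            "word_reading": word_reading,
            "depression": depression,
            "cdr_sob": cdr_sob,
            "cdr_memory": cdr_memory,
            "ecog_informant_total": ecog_total,
            "ecog_informant_memory": ecog_memory,
            "self_memory_concern": self_memory_concern,
        }
    )
    return cohort, ids, reserve, z_r, disease_stage, gm


def simulate_model_building_cohort(
    config: GenerativeConfig,
) -> tuple[pd.DataFrame, TrueLatents]:
    """Simulate the cross-sectional model-building cohort.

    Returns the participant table (one row per participant) and the
    ground-truth latents.  Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cohort, ids, reserve, z_r, stage, gm = _simulate_base(config, rng)
    slope = (
        config.atrophy_rate_mean
        + config.atrophy_stage_coeff * stage
        + rng.normal(0, config.atrophy_rate_sd, config.n_participants)
    )
    latents = TrueLatents(ids=ids, reserve=reserve, disease_stage=stage,
                          gm_baseline=gm, gm_slope=slope)
    return cohort, latents


def simulate_validation_cohort(
    config: GenerativeConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, TrueLatents]:
    """Simulate the external-validation cohort.

    Returns ``(cohort, longitudinal, latents)``: a cross-sectional feature
    table (with the configured features forced missing, emulating variables
    the validation studies never collected), a participant-visit table of
    executive function with grey-matter change, and the true latents.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    cohort, ids, reserve, z_r, stage, gm = _simulate_base(config, rng)
    n = config.n_participants

    for feature in config.missing_feature_list:
        if feature not in cohort.columns:
            raise ConfigurationError(
                f"missing_feature_list entry {feature!r} is not a cohort column"
            )
        cohort[feature] = np.nan

    slope = (
        config.atrophy_rate_mean
        + config.atrophy_stage_coeff * stage
        + rng.normal(0, config.atrophy_rate_sd, n)
    )

    # correlated random intercept/slope
    cov = np.array(
        [
            [config.re_sd_intercept**2,
             config.re_corr * config.re_sd_intercept * config.re_sd_slope],
            [config.re_corr * config.re_sd_intercept * config.re_sd_slope,
             config.re_sd_slope**2],
        ]
    )
    u = rng.multivariate_normal(np.zeros(2), cov, size=n)

    ec = config.ef_coeffs
    times = np.arange(config.n_visits) * config.visit_interval
    rows = []
    age0 = cohort["age"].to_numpy()
    educ = cohort["education"].to_numpy()
    sex = cohort["sex"].to_numpy()
    wr = cohort["word_reading"].to_numpy()
    eps = rng.normal(0, config.noise_sds["ef"], (n, config.n_visits))
    for j, t in enumerate(times):
        gm_change = slope * t
        ef = (
            ec["intercept"]
            + ec["age0"] * (age0 - config.age_mean)
            + ec["educ"] * (educ - 12.0)
            + ec["sex"] * sex
            + ec["word_reading"] * (wr - 32.0)
            + ec["time"] * t
            + ec["gm_baseline"] * gm
            + ec["gm_baseline_time"] * gm * t
            + (ec["gm_change"] - config.moderation_theta * z_r) * gm_change
            + ec["reserve"] * z_r
            + ec["reserve_time"] * z_r * t
            + ec["reserve_gmb"] * z_r * gm
            + ec["reserve_gmb_time"] * z_r * gm * t
            + u[:, 0]
            + u[:, 1] * t
            + eps[:, j]
        )
        rows.append(
            pd.DataFrame(
                {
                    "id": ids,
                    "time": t,
                    "ef": ef,
                    "gm_baseline": gm,
                    "gm_change": gm_change,
                    "age0": age0,
                    "educ": educ,
                    "sex": sex,
                    "word_reading": wr,
                }
            )
        )
    longitudinal = (
        pd.concat(rows, ignore_index=True)
        .sort_values(["id", "time"], kind="mergesort")
        .reset_index(drop=True)
    )
    latents = TrueLatents(ids=ids, reserve=reserve, disease_stage=stage,
                          gm_baseline=gm, gm_slope=slope)
    return cohort, longitudinal, latents
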