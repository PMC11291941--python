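"""The residual reserve index (RRI): criterion construction and scoring.

Cognitive reserve is operationalised as the residual variance in episodic
memory performance that brain variables (grey-matter signature, log WMH
volume), demographics (sex, race/ethnicity) and test-exposure terms do not
explain.  With a single composite memory indicator the latent model is a
linear-Gaussian structural model

    memory = intercept + sum_j beta_j * predictor_j + RRI + e_m,

with latent residual RRI ~ N(0, psi) and optional measurement error
e_m ~ N(0, sigma_m^2).  In the default sigma_m^2 = 0 case the maximum
likelihood fit coincides exactly with ordinary least squares, the
posterior-mean (regression-method) factor score is the OLS residual, and
factor-score determinacy is 1.  With measurement error the posterior mean
shrinks the raw residual by psi / (psi + sigma_m^2) and determinacy equals
that same ratio.

Education is deliberately *not* a predictor, so the criterion retains
education-related variance and education can be compared against it as a
proxy downstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RRISpec",
    "RRIParams",
    "FactorScores",
    "fit_rri",
    "score_rri",
    "latent_correlation",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RRISpec:
    """Column bindings for the memory-decomposition model."""

    memory_indicator: str = "memory"
    brain_predictors: tuple[str, ...] = ("gm_signature", "log_wmh")
    demographic_predictors: tuple[str, ...] = ("sex", "black_aa", "hispanic")
    exposure_predictors: tuple[str, ...] = ("prior_exposure", "spanish")
    exposure_interaction: tuple[str, str] | None = ("prior_exposure", "spanish")
    include_education: bool = False
    measurement_error_variance: float = 0.0

    def predictor_names(self) -> list[str]:
        names = list(self.brain_predictors + self.demographic_predictors
                     + self.exposure_predictors)
        if self.exposure_interaction is not None:
            a, b = self.exposure_interaction
            names.append(f"{a}:{b}")
        if self.include_education:
            names.append("education")
        return names


@dataclass
class RRIParams:
    """Estimated parameters of the memory-decomposition model."""

    intercept: float
    path_coefficients: dict[str, float]
    residual_variance: float              # psi, ML (divisor n)
    measurement_error_variance: float = 0.0
    spec: RRISpec = field(default_factory=RRISpec)
    n_fit: int = 0
    n_dropped_missing: int = 0

    def __post_init__(self) -> None:
        if self.residual_variance < 0:
            raise ValueError("residual_variance must be >= 0")
        if self.measurement_error_variance < 0:
            raise ValueError("measurement_error_variance must be >= 0")

    @property
    def determinacy(self) -> float:
        """Squared correlation between the factor score and the latent RRI."""
        total = self.residual_variance + self.measurement_error_variance
        if total == 0:
            return 1.0
        return self.residual_variance / total

    def to_json(self, path) -> None:
        payload = {
            "intercept": self.intercept,
            "path_coefficients": self.path_coefficients,
            "residual_variance": self.residual_variance,
            "measurement_error_variance": self.measurement_error_variance,
            "n_fit": self.n_fit,
            "n_dropped_missing": self.n_dropped_missing,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path, spec: RRISpec | None = None) -> "RRIParams":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(spec=spec or RRISpec(), **payload)


@dataclass
class FactorScores:
    """Per-participant criterion scores.

    ``rri`` holds the standardised scores (mean 0, SD 1 over non-missing
    participants); ``raw`` the unstandardised posterior means; both indexed
    by participant id with NaN where predictors were missing.
    """

    rri: pd.Series
    raw: pd.Series
    determinacy: float
    n_missing: int = 0


def _design_matrix(cohort: pd.DataFrame, spec: RRISpec) -> tuple[np.ndarray, list[str]]:
    cols = []
    names = []
    for name in spec.brain_predictors + spec.demographic_predictors + spec.exposure_predictors:
        cols.append(cohort[name].to_numpy(dtype=float))
        names.append(name)
    if spec.exposure_interaction is not None:
        a, b = spec.exposure_interaction
        cols.append(cohort[a].to_numpy(dtype=float) * cohort[b].to_numpy(dtype=float))
        names.append(f"{a}:{b}")
    if spec.include_education:
        cols.append(cohort["education"].to_numpy(dtype=float))
        names.append("education")
    X = np.column_stack([np.ones(len(cohort))] + cols)
    return X, names


def fit_rri(cohort: pd.DataFrame, spec: RRISpec | None = None) -> RRIParams:
    """Maximum-likelihood fit of the memory-decomposition model.

    In the single-indicator zero-measurement-error default the ML estimates
    equal ordinary least squares, with psi the ML residual variance
    (divisor n).  Rows with any missing predictor or outcome are dropped
    listwise with a logged count.
    """
    spec = spec or RRISpec()
    needed = [spec.memory_indicator] + [
        c for c in spec.brain_predictors + spec.demographic_predictors
        + spec.exposure_predictors
    ]
    if spec.include_education:
        needed.append("education")
    for col in needed:
        if col not in cohort.columns:
            raise KeyError(f"cohort is missing required column {col!r}")

    complete = cohort[needed].notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        logger.info("fit_rri: dropped %d rows with missing values (listwise)", dropped)
    data = cohort.loc[complete]
    X, names = _design_matrix(data, spec)
    y = data[spec.memory_indicator].to_numpy(dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"too few complete rows ({n}) for {p - 1} predictors")

    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # identify (near-)collinear columns via pivoted QR
        _, r, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(
            X, mode="economic", pivoting=True
        )
        diag = np.abs(np.diag(r))
        bad = [(["intercept"] + names)[j] for j in piv[rank:]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    psi = float(resid @ resid / n) - spec.measurement_error_variance
    psi = max(psi, 0.0)
    return RRIParams(
        intercept=float(beta[0]),
        path_coefficients=dict(zip(names, beta[1:].astype(float))),
        residual_variance=psi,
        measurement_error_variance=spec.measurement_error_variance,
        spec=spec,
        n_fit=n,
        n_dropped_missing=dropped,
    )


def _raw_residuals(params: RRIParams, cohort: pd.DataFrame) -> pd.Series:
    spec = params.spec
    needed = [spec.memory_indicator] + list(
        spec.brain_predictors + spec.demographic_predictors + spec.exposure_predictors
    )
    if spec.include_education:
        needed.append("education")
    complete = cohort[needed].notna().all(axis=1)
    data = cohort.loc[complete]
    X, names = _design_matrix(data, spec)
    beta = np.array([params.intercept] + [params.path_coefficients[n] for n in names])
    resid = data[spec.memory_indicator].to_numpy(dtype=float) - X @ beta
    idx = cohort["id"] if "id" in cohort.columns else cohort.index.to_series()
    out = pd.Series(np.nan, index=pd.Index(idx, name="id"), name="residual")
    out.iloc[np.flatnonzero(complete.to_numpy())] = resid
    return out


def score_rri(params: RRIParams, cohort: pd.DataFrame) -> FactorScores:
    """Posterior-mean (regression-method) factor scores of the latent RRI.

    The raw score is ``determinacy * (memory - fitted)``; with zero
    measurement error this is exactly the regression residual.  Standardised
    scores have mean 0 and SD 1 across scored participants.  Participants
    with missing predictors receive NaN with a logged count.
    """
    residual = _raw_residuals(params, cohort)
    n_missing = int(residual.isna().sum())
    if n_missing:
        logger.info("score_rri: %d participants unscored due to missing data", n_missing)
    raw = params.determinacy * residual
    scored = raw.dropna()
    sd = float(scored.std(ddof=0))
    if sd == 0:
        standardized = raw * 0.0
    else:
        standardized = (raw - scored.mean()) / sd
    return FactorScores(
        rri=standardized.rename("rri"),
        raw=raw.rename("raw"),
        determinacy=params.determinacy,
        n_missing=n_missing,
    )


def latent_correlation(
    params: RRIParams, cohort: pd.DataFrame, proxy_scores: pd.Series
) -> tuple[float, float]:
    """Correlation between the latent RRI and an observed proxy score.

    All model parameters are held fixed at ``params``; the single free
    parameter is the latent correlation.  Under the linear-Gaussian model the
    ML estimate is the Pearson correlation between the proxy and the raw
    residual, disattenuated by the square root of factor-score determinacy
    (the residual carries measurement noise the latent does not).  Returns
    ``(r, se)`` with the observed-information standard error
    ``(1 - r^2) / sqrt(n)``.
    """
    residual = _raw_residuals(params, cohort)
    aligned = pd.concat(
        [residual, proxy_scores.rename("proxy").reindex(residual.index)], axis=1
    ).dropna()
    n = len(aligned)
    if n < 3:
        raise ValueError("need at least 3 aligned observations")
    if float(aligned["proxy"].std(ddof=0)) == 0:
        raise ValueError("proxy scores have zero variance")
    r_obs = float(stats.pearsonr(aligned["proxy"], aligned["residual"])[0])
    r = r_obs / np.sqrt(params.determinacy)
    r = float(np.clip(r, -1.0, 1.0))
    se = (1.0 - r**2) / np.sqrt(n)
    return r, float(se)
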