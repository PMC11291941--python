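"""Derived clinical predictors and tiered feature assembly.

Three nested predictor tiers feed the reserve surrogate:

* **Minimal** — variables obtainable at any out-patient visit: age, education,
  sex, diastolic blood pressure, pulse pressure, heart rate, height, BMI and
  three allometric body-shape indices (ABSI, hip index, waist-hip index), and
  a single self-reported memory-concern item.
* **Extended** — Minimal plus a 30-point cognitive screener (MMSE-equivalent;
  MoCA scores are mapped through a configurable crosswalk), a 45-item word
  reading score (50-item forms are rescaled), and a 15-item depression scale.
* **Full** — Extended plus informant-based measures: CDR sum-of-boxes, the
  CDR memory box score, and ECog informant total and memory scores.

Missing source data propagates as ``NaN`` (the MISSING marker) and is never
imputed here; the downstream gradient-boosted learner routes missing values
natively.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "TierSpec",
    "AllometricSpec",
    "ABSI_DEFAULT",
    "HIP_INDEX_DEFAULT",
    "WAIST_HIP_INDEX_DEFAULT",
    "tier_spec",
    "compute_bmi",
    "compute_pulse_pressure",
    "compute_allometric_index",
    "identity_crosswalk",
    "load_crosswalk",
    "validate_crosswalk",
    "convert_moca_to_mmse",
    "convert_amnart50_to_45",
    "assemble_features",
    "assemble_feature_frame",
]

MISSING = float("nan")

MINIMAL_FEATURES = [
    "age",
    "education",
    "sex",
    "dbp",
    "pulse_pressure",
    "heart_rate",
    "height",
    "bmi",
    "absi",
    "hip_index",
    "waist_hip_index",
    "self_memory_concern",
]
EXTENDED_FEATURES = MINIMAL_FEATURES + [
    "screener_mmse_equiv",
    "word_reading_45",
    "depression",
]
FULL_FEATURES = EXTENDED_FEATURES + [
    "cdr_sob",
    "cdr_memory",
    "ecog_informant_total",
    "ecog_informant_memory",
]


@dataclass(frozen=True)
class TierSpec:
    tier: str
    feature_names: tuple[str, ...]


def tier_spec(tier: str) -> TierSpec:
    """Return the TierSpec for ``'minimal' | 'extended' | 'full'``."""
    key = tier.lower()
    table = {
        "minimal": MINIMAL_FEATURES,
        "extended": EXTENDED_FEATURES,
        "full": FULL_FEATURES,
    }
    if key not in table:
        raise ValueError(f"unknown tier {tier!r}; expected minimal/extended/full")
    return TierSpec(tier=key, feature_names=tuple(table[key]))


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index, kg/m^2."""
    if weight <= 0 or height <= 0:
        raise ValueError(f"weight and height must be positive (got {weight}, {height})")
    return weight / height**2


def compute_pulse_pressure(sbp: float, dbp: float) -> float:
    """Systolic minus diastolic blood pressure, mmHg."""
    if sbp < dbp:
        raise ValueError(f"systolic ({sbp}) must be >= diastolic ({dbp})")
    return sbp - dbp


@dataclass(frozen=True)
class AllometricSpec:
    """Power-law body-shape index: ``scale * m * height^h_exp * base^b_exp``.

    ``base`` selects the second normaliser: BMI (kg/m^2) or weight (kg).
    The published indices do not print their constants uniformly across
    cohorts, so the exponents and scale are explicit configuration.
    """

    name: str
    height_exp: float
    base_exp: float
    base: str = "bmi"   # 'bmi' or 'weight'
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")
        if self.base not in ("bmi", "weight"):
            raise ValueError("base must be 'bmi' or 'weight'")


# ABSI: waist (m) normalised for BMI and height (Krakauer convention).
ABSI_DEFAULT = AllometricSpec("ABSI", height_exp=-0.5, base_exp=-2.0 / 3.0, base="bmi")
# Hip index: hip (cm) normalised for weight and height; the scale makes the
# index come out near the raw hip circumference at reference height 1.66 m
# and weight 73 kg.
HIP_INDEX_DEFAULT = AllometricSpec(
    "HI",
    height_exp=0.310,
    base_exp=-0.482,
    base="weight",
    scale=73.0**0.482 / 1.66**0.310,
)
# Waist-hip index: waist/hip ratio normalised for height and BMI.
WAIST_HIP_INDEX_DEFAULT = AllometricSpec(
    "WHI", height_exp=0.5, base_exp=1.0 / 3.0, base="bmi", scale=1.12
)


def compute_allometric_index(
    measurement: float, height: float, base_value: float, spec: AllometricSpec
) -> float:
    """Evaluate an allometric body-shape index.

    ``measurement`` is the circumference (or waist/hip ratio for WHI),
    ``height`` in metres, ``base_value`` the BMI or weight named by the spec.
    """
    if measurement <= 0 or height <= 0 or base_value <= 0:
        raise ValueError("allometric inputs must be positive")
    return spec.scale * measurement * height**spec.height_exp * base_value**spec.base_exp


# ---------------------------------------------------------------------------
# Screener / word-reading conversions


def identity_crosswalk() -> pd.Series:
    """Default MoCA->MMSE crosswalk: the identity on 0..30."""
    return pd.Series(np.arange(31), index=np.arange(31), name="mmse")


def validate_crosswalk(crosswalk: pd.Series) -> pd.Series:
    xs = np.asarray(sorted(crosswalk.index))
    if not np.array_equal(xs, np.arange(31)):
        raise ValueError("crosswalk must cover every MoCA score 0..30")
    ys = crosswalk.loc[np.arange(31)].to_numpy(dtype=float)
    if np.any(np.diff(ys) < 0):
        raise ValueError("crosswalk must be monotone non-decreasing in MoCA")
    if ys.min() < 0 or ys.max() > 30:
        raise ValueError("crosswalk outputs must lie in [0, 30]")
    return crosswalk


def load_crosswalk(path) -> pd.Series:
    """Load a MoCA->MMSE crosswalk CSV with columns ``input,output``."""
    table = pd.read_csv(path)
    cw = pd.Series(table["output"].to_numpy(), index=table["input"].to_numpy())
    return validate_crosswalk(cw)


def convert_moca_to_mmse(moca: int, crosswalk: pd.Series | None = None) -> float:
    if crosswalk is None:
        crosswalk = identity_crosswalk()
    if not float(moca).is_integer() or not (0 <= moca <= 30):
        raise ValueError(f"MoCA score must be an integer in [0, 30], got {moca}")
    key = int(moca)
    if key not in crosswalk.index:
        raise ValueError(f"crosswalk does not cover MoCA score {key}")
    return float(crosswalk.loc[key])


def convert_amnart50_to_45(score50: float, mapping=None) -> float:
    """Rescale a 50-item word-reading score to its 45-item equivalent.

    The default is a proportional rescale with round-half-up; an explicit
    monotone mapping (callable or Series indexed by 0..50) may be supplied to
    reproduce a published conversion exactly.
    """
    if not (0 <= score50 <= 50):
        raise ValueError(f"50-item score must lie in [0, 50], got {score50}")
    if mapping is None:
        return float(math.floor(score50 * 45.0 / 50.0 + 0.5))
    if callable(mapping):
        return float(mapping(score50))
    return float(mapping.loc[score50])


# ---------------------------------------------------------------------------
# Assembly


def _get(record, key):
    """Fetch a source column; absent or null values become MISSING."""
    try:
        value = record[key]
    except (KeyError, IndexError):
        return MISSING
    if value is None:
        return MISSING
    try:
        if pd.isna(value):
            return MISSING
    except (TypeError, ValueError):
        pass
    return value


def _is_missing(x) -> bool:
    return isinstance(x, float) and math.isnan(x)


def assemble_features(
    record,
    tier: TierSpec,
    crosswalk: pd.Series | None = None,
    amnart_mapping=None,
) -> dict[str, float]:
    """Build one tier-specific feature vector from a participant record.

    ``record`` is a mapping / pandas Series of raw columns.  Derived features
    whose sources are missing come out MISSING (NaN); this function never
    raises on missing data.  Key order follows ``tier.feature_names``.
    """
    out: dict[str, float] = {}

    weight, height = _get(record, "weight"), _get(record, "height")
    waist, hip = _get(record, "waist"), _get(record, "hip")
    sbp, dbp = _get(record, "sbp"), _get(record, "dbp")

    bmi = _get(record, "bmi")
    if _is_missing(bmi) and not (_is_missing(weight) or _is_missing(height)):
        bmi = compute_bmi(weight, height)

    derived: dict[str, float] = {
        "bmi": bmi,
        "pulse_pressure": (
            MISSING if _is_missing(sbp) or _is_missing(dbp)
            else compute_pulse_pressure(sbp, dbp)
        ),
    }
    if _is_missing(waist) or _is_missing(height) or _is_missing(bmi):
        derived["absi"] = MISSING
    else:
        derived["absi"] = compute_allometric_index(waist / 100.0, height, bmi, ABSI_DEFAULT)
    if _is_missing(hip) or _is_missing(height) or _is_missing(weight):
        derived["hip_index"] = MISSING
    else:
        derived["hip_index"] = compute_allometric_index(hip, height, weight, HIP_INDEX_DEFAULT)
    if _is_missing(waist) or _is_missing(hip) or _is_missing(height) or _is_missing(bmi):
        derived["waist_hip_index"] = MISSING
    else:
        derived["waist_hip_index"] = compute_allometric_index(
            waist / hip, height, bmi, WAIST_HIP_INDEX_DEFAULT
        )

    # screener: prefer an MMSE-scale score; fall back to MoCA via crosswalk
    screener = _get(record, "screener")
    if _is_missing(screener):
        screener = _get(record, "mmse")
    if _is_missing(screener):
        moca = _get(record, "moca")
        screener = MISSING if _is_missing(moca) else convert_moca_to_mmse(moca, crosswalk)
    derived["screener_mmse_equiv"] = screener

    wr = _get(record, "word_reading")
    if _is_missing(wr):
        wr50 = _get(record, "word_reading_50")
        wr = MISSING if _is_missing(wr50) else convert_amnart50_to_45(wr50, amnart_mapping)
    derived["word_reading_45"] = wr

    concern = _get(record, "self_memory_concern")
    derived["self_memory_concern"] = (
        MISSING if _is_missing(concern) else float(bool(concern))
    )

    for name in tier.feature_names:
        if name in derived:
            out[name] = derived[name]
        else:
            value = _get(record, name)
            out[name] = MISSING if _is_missing(value) else float(value)
    return out


def assemble_feature_frame(
    cohort: pd.DataFrame,
    tier: TierSpec,
    crosswalk: pd.Series | None = None,
    amnart_mapping=None,
) -> pd.DataFrame:
    """Vector-assemble a feature matrix for a whole cohort, indexed by id."""
    rows = [
        assemble_features(rec, tier, crosswalk=crosswalk, amnart_mapping=amnart_mapping)
        for rec in cohort.to_dict("records")
    ]
    frame = pd.DataFrame(rows, columns=list(tier.feature_names))
    if "id" in cohort.columns:
        frame.index = pd.Index(cohort["id"].to_numpy(), name="id")
    return frame
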