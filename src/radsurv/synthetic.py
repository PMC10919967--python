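"""Synthetic inputs for the full RADS pipeline.

The fitted coefficient values and covariance matrices of the underlying
LSS risk models, and the European baseline incidence tables, live in
external references that this package does not redistribute. This module
generates plausible stand-ins with the same file formats the pipeline
reads, so every stage is testable end to end.

The generator calibrates by construction instead of fitting: each model
family's leading coefficient is chosen so that its excess risk at the
reference profile (D = 1 Gy, e = 30, a = 70, K = 0, averaged over the two
sexes) equals ``err_scale`` (ERR models) or ``ear_scale`` (EAR models)
exactly. The reference ages mirror the centering of the risk effect
modifiers around age at exposure 30 and attained age 70 used when the
original models were fitted. Calibration makes every downstream number
analytically predictable in tests.

Default scales (ERR 0.5 per Gy, EAR 50 per 10,000 PY per Gy, baseline
peaking at 3000 per 100,000 PY at age 85) are typical all-solid-cancer
magnitudes for adult European populations, so synthetic mission estimates
land in the same few-percent range as published astronaut risk figures.

Covariances are built as ``sigma sigma^T  *  R`` with per-coefficient
standard deviations ``relative_sd * |coefficient|`` and a common
off-diagonal correlation, positive semi-definite by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .core import BaselineRateTable
from .errors import ConfigurationError
from .risk_models import (
    FAMILY_COEFFICIENTS,
    ExposureProfile,
    RiskModelSpec,
    evaluate_excess_risk,
)

#: reference covariates at which generated models are calibrated
REFERENCE_DOSE = 1.0
REFERENCE_AGE_AT_EXPOSURE = 30.0
REFERENCE_ATTAINED_AGE = 70.0

#: quadratic share of the linear-quadratic dose response at 1 Gy
_LQ_BETA_SHARE = 0.3

#: fixed male/female multipliers on the baseline rates (sex-average is 1)
_BASELINE_SEX_FACTOR = {"male": 1.1, "female": 0.9}

#: log-linear slope of the synthetic baseline (per year of age)
_BASELINE_SLOPE = 0.08

#: modifier coefficients per family; ``nu_err``/``nu_ear`` give the ERR and
#: EAR attained-age trends (ERR declines, EAR rises with attained age)
_FAMILY_SHAPES: dict[str, dict] = {
    "BEIR7": dict(tau=-0.30, nu_err=-1.4, nu_ear=1.0),
    "GRANT_L": dict(tau=-0.20, nu_err=-1.6, nu_ear=1.2, phi=-0.10, sigma=0.25),
    "GRANT_LQ": dict(tau=-0.20, nu_err=-1.6, nu_ear=1.2, phi=-0.10, sigma=0.25),
    "PRESTON_L": dict(tau=-0.25, nu_err=-1.5, nu_ear=1.1, phi=-0.08, sigma=0.20),
    "INWORKS_L": dict(tau=-0.15, nu1=-0.05, nu2=-0.03, nu3=-0.02, sigma=0.30),
    "INWORKS_LQ": dict(tau=-0.15, nu1=-0.05, nu2=-0.03, nu3=-0.02, sigma=0.30),
    "UNSCEAR_L": dict(sigma=0.20, epsilon=0.40, nu_err=-1.3, nu_ear=0.9),
    "UNSCEAR_LQ": dict(sigma=0.20, epsilon=0.40, nu_err=-1.3, nu_ear=0.9),
}

#: female-to-male ratio of the sex-specific BEIR7 linear coefficients
_BEIR_FEMALE_MALE_RATIO = 1.5


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic-input generator.

    ``err_scale`` / ``ear_scale`` are the target excess risks per Gy at the
    reference covariates; ``relative_sd`` the coefficient standard deviation
    as a fraction of the coefficient; ``correlation`` the common
    off-diagonal coefficient correlation; ``baseline_peak_rate`` the
    sex-averaged incidence per 100,000 person-years at age 85.
    """

    seed: int = 0
    err_scale: float = 0.5
    ear_scale: float = 50.0
    relative_sd: float = 0.2
    correlation: float = 0.3
    baseline_peak_rate: float = 3000.0

    def __post_init__(self) -> None:
        if self.err_scale <= 0 or self.ear_scale <= 0:
            raise ConfigurationError("risk scales must be > 0")
        if self.relative_sd < 0:
            raise ConfigurationError("relative_sd must be >= 0")
        if self.baseline_peak_rate <= 0:
            raise ConfigurationError("baseline_peak_rate must be > 0")
        max_p = max(len(v) for v in FAMILY_COEFFICIENTS.values())
        if not -1.0 / (max_p - 1) < self.correlation < 1.0:
            raise ConfigurationError(
                f"correlation must lie in (-1/{max_p - 1}, 1) to keep "
                f"covariances positive semi-definite, got {self.correlation}"
            )


def _covariance(coefficients: dict[str, float], names: tuple[str, ...],
                config: SyntheticConfig) -> np.ndarray:
    sd = np.array([config.relative_sd * abs(coefficients[k]) for k in names])
    p = len(names)
    R = np.full((p, p), config.correlation)
    np.fill_diagonal(R, 1.0)
    return np.outer(sd, sd) * R


def _base_coefficients(family: str, endpoint: str) -> dict[str, float]:
    """Modifier coefficients (everything except the dose-response terms)."""
    shape = _FAMILY_SHAPES[family]
    names = FAMILY_COEFFICIENTS[family]
    coeffs: dict[str, float] = {}
    for name in names:
        if name in ("alpha", "alpha_male", "alpha_female", "beta"):
            continue
        if name == "nu":
            coeffs["nu"] = shape["nu_err"] if endpoint == "ERR" else shape["nu_ear"]
        else:
            coeffs[name] = shape[name]
    return coeffs


def _calibrated_spec(family: str, endpoint: str, scale: float,
                     config: SyntheticConfig) -> RiskModelSpec:
    coeffs = _base_coefficients(family, endpoint)
    # sex-averaged modifier at the reference profile: the (1 + sigma*s)
    # families average to 1 exactly; the exp(sigma*s) families to cosh(sigma)
    if family.startswith("UNSCEAR"):
        sex_avg = float(np.cosh(coeffs["sigma"]))
    else:
        sex_avg = 1.0
    target = scale / sex_avg  # required dose response at D = 1 Gy
    if family == "BEIR7":
        male = 2.0 * target / (1.0 + _BEIR_FEMALE_MALE_RATIO)
        coeffs["alpha_male"] = male
        coeffs["alpha_female"] = _BEIR_FEMALE_MALE_RATIO * male
    elif family.endswith("_LQ"):
        coeffs["alpha"] = (1.0 - _LQ_BETA_SHARE) * target
        coeffs["beta"] = _LQ_BETA_SHARE * target
    else:
        coeffs["alpha"] = target
    names = FAMILY_COEFFICIENTS[family]
    return RiskModelSpec(family, endpoint, coeffs,
                         _covariance(coeffs, names, config))


def generate_model_registry(config: SyntheticConfig) -> list[RiskModelSpec]:
    """All 8 families x 2 endpoints, calibrated at the reference profile.

    Each ERR spec evaluates to exactly ``config.err_scale`` (and each EAR
    spec to ``config.ear_scale``) at D = 1 Gy, e = 30, a = 70, K = 0 when
    averaged over the two sexes.
    """
    specs = []
    for family in FAMILY_COEFFICIENTS:
        specs.append(_calibrated_spec(family, "ERR", config.err_scale, config))
        specs.append(_calibrated_spec(family, "EAR", config.ear_scale, config))
    return specs


def reference_excess_risk(spec: RiskModelSpec) -> float:
    """Sex-averaged excess risk of a spec at the calibration profile."""
    values = []
    for sex in ("male", "female"):
        profile = ExposureProfile(REFERENCE_DOSE, REFERENCE_AGE_AT_EXPOSURE,
                                  REFERENCE_ATTAINED_AGE, sex)
        values.append(evaluate_excess_risk(spec, profile))
    return float(np.mean(values))


def generate_baseline(config: SyntheticConfig) -> BaselineRateTable:
    """Gompertz-like synthetic baseline incidence, ages 0-100, both sexes.

    Rates are log-linear in age (hence strictly increasing everywhere) and
    scaled so that the sex-averaged rate at age 85 equals
    ``config.baseline_peak_rate`` per 100,000 person-years; males run a
    fixed 10% above and females 10% below the average.
    """
    ages = np.arange(0, 101, dtype=float)
    rows = []
    for age in ages:
        for sex in ("male", "female"):
            rate = (config.baseline_peak_rate * _BASELINE_SEX_FACTOR[sex]
                    * np.exp(_BASELINE_SLOPE * (age - 85.0)))
            rows.append({"age": age, "sex": sex, "rate_per_100000": rate})
    return BaselineRateTable(pd.DataFrame(rows))


def generate_mission_scenarios() -> list[dict]:
    """Mission scenarios: 180-day lunar (0.17 Sv), Mars (1 Sv), zero-dose
    control; age at exposure 40, attained age 65, each sex.

    The mission doses are treated numerically as weighted colon dose in Gy.
    """
    scenarios = []
    for label, dose in (("lunar", 0.17), ("mars", 1.0), ("control", 0.0)):
        for sex in ("male", "female"):
            scenarios.append({
                "label": label,
                "weighted_dose": dose,
                "age_at_exposure": 40.0,
                "attained_age": 65.0,
                "sex": sex,
            })
    return scenarios


def save_scenarios(scenarios: list[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"scenarios": scenarios}, fh, sort_keys=False)


def load_scenarios(path) -> list[dict]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return list(doc["scenarios"])
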