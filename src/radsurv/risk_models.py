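"""Excess-risk model families for all-solid-cancer incidence.

Eight model families fitted to the Life Span Study (LSS) of the atomic-bomb
survivors are supported, each in an excess relative risk (ERR) and an excess
absolute risk (EAR) variant with identical mathematical form but separate
coefficients:

========== =====================================================================
family     risk form (D = weighted colon dose in Gy, e = age at exposure,
           a = attained age, s = sex code, K = total shielded kerma)
========== =====================================================================
BEIR7      alpha_s * D * exp(tau * e') * (a/70)^nu,
           e' = (e-30)/10 for e < 30, else 0; alpha_s is sex-specific
GRANT_L    alpha * D * exp(tau*(e-30)/10 + nu*ln(a/70) + phi*1[K>4]) * (1+sigma*s)
GRANT_LQ   (alpha*D + beta*D^2) * the GRANT_L modifier product
PRESTON_L  same form as GRANT_L, fitted independently
INWORKS_L  alpha * D * exp(tau*(e-30)/10 + nu(a)*(a-70)/10) * (1+sigma*s),
           nu(a) piecewise constant: nu1 (a<60), nu2 (60<=a<80), nu3 (a>=80)
INWORKS_LQ (alpha*D + beta*D^2) * the INWORKS_L modifier product
UNSCEAR_L  alpha * D * exp(sigma*s + epsilon*ln((a-e)/40) + nu*ln(a/70))
UNSCEAR_LQ (alpha*D + beta*D^2) * the UNSCEAR_L modifier product
========== =====================================================================

ERR is dimensionless (a multiplier on baseline rates); EAR is expressed in
excess cases per 10,000 person-years.

Sex coding: s = -1 for males and +1 for females inside the (1 + sigma*s) and
exp(sigma*s) modifiers (the symmetric convention common in LSS analyses).
The BEIR7 family instead carries sex-specific linear coefficients
``alpha_male`` / ``alpha_female``.

Model evaluation is pure and stateless: Monte Carlo perturbation enters only
through the ``override`` mapping of coefficient names to replacement values,
which may be scalars or broadcastable arrays.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError, DomainError

logger = logging.getLogger(__name__)

ENDPOINTS = ("ERR", "EAR")

#: canonical coefficient order per family; covariance matrices follow it
FAMILY_COEFFICIENTS: dict[str, tuple[str, ...]] = {
    "BEIR7": ("alpha_male", "alpha_female", "tau", "nu"),
    "GRANT_L": ("alpha", "tau", "nu", "phi", "sigma"),
    "GRANT_LQ": ("alpha", "beta", "tau", "nu", "phi", "sigma"),
    "PRESTON_L": ("alpha", "tau", "nu", "phi", "sigma"),
    "INWORKS_L": ("alpha", "tau", "nu1", "nu2", "nu3", "sigma"),
    "INWORKS_LQ": ("alpha", "beta", "tau", "nu1", "nu2", "nu3", "sigma"),
    "UNSCEAR_L": ("alpha", "sigma", "epsilon", "nu"),
    "UNSCEAR_LQ": ("alpha", "beta", "sigma", "epsilon", "nu"),
}

FAMILIES = tuple(FAMILY_COEFFICIENTS)

SEX_CODE = {"male": -1.0, "female": 1.0}

#: shielded-kerma threshold (Gy) above which the phi adjustment applies
KERMA_THRESHOLD = 4.0

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class ExposureProfile:
    """Covariates at which excess risks are evaluated.

    Parameters
    ----------
    weighted_dose
        Weighted colon dose D in Gy (gamma plus RBE-weighted neutron dose).
    age_at_exposure
        Age e at exposure, in years.
    attained_age
        Attained age a, in years; must exceed ``age_at_exposure``.
    sex
        ``"male"`` or ``"female"``.
    shielded_kerma
        Total shielded kerma K in Gy; only the indicator K > 4 enters the
        GRANT/PRESTON modifier. Defaults to 0, appropriate for mission
        predictions.
    """

    weighted_dose: float
    age_at_exposure: float
    attained_age: float
    sex: str
    shielded_kerma: float = 0.0

    def __post_init__(self) -> None:
        if self.weighted_dose < 0:
            raise DomainError(f"weighted_dose must be >= 0, got {self.weighted_dose}")
        if not 0 < self.age_at_exposure < self.attained_age:
            raise DomainError(
                "require 0 < age_at_exposure < attained_age, got "
                f"e={self.age_at_exposure}, a={self.attained_age}"
            )
        if self.sex not in SEX_CODE:
            raise DomainError(f"sex must be one of {sorted(SEX_CODE)}, got {self.sex!r}")
        if self.shielded_kerma < 0:
            raise DomainError(f"shielded_kerma must be >= 0, got {self.shielded_kerma}")

    @property
    def sex_code(self) -> float:
        return SEX_CODE[self.sex]


@dataclass(frozen=True)
class RiskModelSpec:
    """One excess-risk model: family, endpoint, coefficients, covariance.

    ``coefficients`` must contain exactly the names the family uses (see
    ``FAMILY_COEFFICIENTS``); ``covariance`` is the symmetric coefficient
    covariance matrix in that canonical order.
    """

    family: str
    endpoint: str
    coefficients: Mapping[str, float]
    covariance: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILY_COEFFICIENTS:
            raise ConfigurationError(f"unknown model family {self.family!r}")
        if self.endpoint not in ENDPOINTS:
            raise ConfigurationError(f"endpoint must be ERR or EAR, got {self.endpoint!r}")
        names = FAMILY_COEFFICIENTS[self.family]
        got = set(self.coefficients)
        unknown = got - set(names)
        if unknown:
            raise ConfigurationError(
                f"{self.family}: unknown coefficient name(s) {sorted(unknown)}"
            )
        missing = set(names) - got
        if missing:
            raise ConfigurationError(
                f"{self.family}: missing coefficient(s) {sorted(missing)}"
            )
        cov = np.asarray(self.covariance, dtype=float)
        p = len(names)
        if cov.shape != (p, p):
            raise ConfigurationError(
                f"{self.family}: covariance must be {p}x{p}, got {cov.shape}"
            )
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ConfigurationError(f"{self.family}: covariance is not symmetric")
        if np.any(np.diag(cov) < -_PSD_TOL):
            raise ConfigurationError(f"{self.family}: covariance has negative diagonal")
        scale = max(1.0, float(np.max(np.abs(cov))) if cov.size else 1.0)
        if np.linalg.eigvalsh(cov).min() < -_PSD_TOL * scale:
            raise ConfigurationError(
                f"{self.family}: covariance is not positive semi-definite"
            )
        object.__setattr__(self, "covariance", cov)
        object.__setattr__(self, "coefficients", dict(self.coefficients))

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        return FAMILY_COEFFICIENTS[self.family]

    def coefficient_vector(self) -> np.ndarray:
        """Mean coefficient values in canonical order."""
        return np.array([self.coefficients[k] for k in self.coefficient_names], float)

    @property
    def key(self) -> tuple[str, str]:
        return (self.family, self.endpoint)


def exposure_age_transform_beir(age_at_exposure: float) -> float:
    """BEIR VII age-at-exposure transform e' = (e-30)/10 below 30, else 0."""
    if age_at_exposure <= 0:
        raise DomainError(f"age_at_exposure must be > 0, got {age_at_exposure}")
    if age_at_exposure < 30.0:
        return (age_at_exposure - 30.0) / 10.0
    return 0.0


def attained_age_coefficient_inworks(attained_age, nu1, nu2, nu3):
    """Piecewise-constant INWORKS attained-age coefficient.

    Returns nu1 for a < 60, nu2 for 60 <= a < 80 and nu3 for a >= 80.
    Accepts scalar or array ``attained_age`` (and broadcastable nu values).
    """
    a = np.asarray(attained_age, dtype=float)
    if np.any(a <= 0):
        raise DomainError("attained_age must be > 0")
    out = np.select([a < 60.0, a < 80.0], [np.asarray(nu1), np.asarray(nu2)],
                    default=np.asarray(nu3))
    if np.isscalar(attained_age) and np.ndim(out) == 0:
        return float(out)
    return out


def _merged_coefficients(spec: RiskModelSpec, override: Mapping | None) -> dict:
    if not override:
        return dict(spec.coefficients)
    unknown = set(override) - set(spec.coefficient_names)
    if unknown:
        raise ConfigurationError(
            f"{spec.family}: override names not in model: {sorted(unknown)}"
        )
    merged = dict(spec.coefficients)
    merged.update(override)
    return merged


def excess_risk_curve(
    spec: RiskModelSpec,
    profile: ExposureProfile,
    ages,
    override: Mapping | None = None,
) -> np.ndarray:
    """Evaluate the model's excess risk at fixed (D, e, s, K) over attained ages.

    ``ages`` may be a scalar or an array; coefficient overrides may carry
    broadcastable arrays (e.g. shape ``(n, 1)`` against an age grid of shape
    ``(g,)`` yields an ``(n, g)`` result), which is how the Monte Carlo stage
    evaluates all realisations at once.
    """
    a = np.asarray(ages, dtype=float)
    if np.any(a <= 0):
        raise DomainError("attained ages must be > 0")
    c = _merged_coefficients(spec, override)
    D = profile.weighted_dose
    e = profile.age_at_exposure
    s = profile.sex_code
    fam = spec.family

    if fam == "BEIR7":
        alpha = c["alpha_male"] if profile.sex == "male" else c["alpha_female"]
        e_star = exposure_age_transform_beir(e)
        return alpha * D * np.exp(c["tau"] * e_star) * (a / 70.0) ** c["nu"]

    if fam.endswith("_LQ"):
        dose_term = c["alpha"] * D + c["beta"] * D * D
    else:
        dose_term = c["alpha"] * D

    if fam in ("GRANT_L", "GRANT_LQ", "PRESTON_L"):
        kerma = 1.0 if profile.shielded_kerma > KERMA_THRESHOLD else 0.0
        log_mod = (c["tau"] * (e - 30.0) / 10.0
                   + c["nu"] * np.log(a / 70.0)
                   + c["phi"] * kerma)
        return dose_term * np.exp(log_mod) * (1.0 + c["sigma"] * s)

    if fam in ("INWORKS_L", "INWORKS_LQ"):
        nu_a = attained_age_coefficient_inworks(a, c["nu1"], c["nu2"], c["nu3"])
        log_mod = c["tau"] * (e - 30.0) / 10.0 + nu_a * (a - 70.0) / 10.0
        return dose_term * np.exp(log_mod) * (1.0 + c["sigma"] * s)

    if fam in ("UNSCEAR_L", "UNSCEAR_LQ"):
        if np.any(a - e <= 0):
            raise DomainError(
                f"{fam}: attained age must exceed age at exposure "
                f"(time since exposure enters through ln((a-e)/40))"
            )
        log_mod = (c["sigma"] * s
                   + c["epsilon"] * np.log((a - e) / 40.0)
                   + c["nu"] * np.log(a / 70.0))
        return dose_term * np.exp(log_mod)

    raise ConfigurationError(f"unknown model family {fam!r}")  # pragma: no cover


def evaluate_excess_risk(
    spec: RiskModelSpec,
    profile: ExposureProfile,
    override: Mapping[str, float] | None = None,
) -> float:
    """Excess risk of one model at the profile's attained age.

    Returns the ERR (dimensionless) or EAR (per 10,000 person-years)
    depending on ``spec.endpoint``. A dose of zero always yields zero.
    """
    value = excess_risk_curve(spec, profile, profile.attained_age, override)
    return float(np.asarray(value).reshape(-1)[0]) if np.ndim(value) else float(value)


# ---------------------------------------------------------------------------
# registry I/O


def save_model_registry(specs: Sequence[RiskModelSpec], path) -> None:
    """Write a list of model specs to a YAML registry file (lossless)."""
    docs = []
    for spec in specs:
        docs.append({
            "family": spec.family,
            "endpoint": spec.endpoint,
            "coefficients": {k: float(spec.coefficients[k])
                             for k in spec.coefficient_names},
            "covariance": [[float(v) for v in row] for row in spec.covariance],
        })
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"models": docs}, fh, sort_keys=False)


def load_model_registry(path) -> list[RiskModelSpec]:
    """Read model specs from a YAML registry file, validating each."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "models" not in payload:
        raise ConfigurationError(f"{path}: expected a top-level 'models' list")
    specs = []
    for doc in payload["models"]:
        specs.append(RiskModelSpec(
            family=doc["family"],
            endpoint=doc["endpoint"],
            coefficients={str(k): float(v) for k, v in doc["coefficients"].items()},
            covariance=np.asarray(doc["covariance"], dtype=float),
        ))
    return specs
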