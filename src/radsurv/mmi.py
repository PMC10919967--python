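"""Multi-model inference (MMI): information-criterion weights and
model-averaged excess risks.

Candidate models are weighted with normalized Akaike weights
``w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)`` where ``Delta_i`` is the
model's AIC or BIC difference to the best model. Because the underlying
likelihood fits are external to this package, weight sets normally arrive as
configuration files; :func:`weights_from_criterion_values` builds them from
raw criterion values when those are available.

Averaging happens on the excess-risk scale, per evaluation point. Each
weight set carries one weight map per endpoint (ERR and EAR) because the two
endpoints were weighted separately in the underlying fits.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigurationError
from .risk_models import (
    ENDPOINTS,
    FAMILIES,
    ExposureProfile,
    RiskModelSpec,
    excess_risk_curve,
)

logger = logging.getLogger(__name__)

CRITERIA = ("AIC", "BIC")
BASELINE_METHODS = ("original", "same")

_SUM_TOL = 1e-9


@dataclass(frozen=True)
class MMIWeightSet:
    """Per-model weights for one (criterion, baseline-method) pair.

    ``weights`` maps endpoint ("ERR"/"EAR") to a family -> weight map.
    Families absent from a map carry weight zero. Within each endpoint the
    weights must be non-negative and sum to one (tolerance 1e-9). An endpoint
    absent from ``weights`` contributes zero excess risk, which is useful for
    reduced test configurations.
    """

    criterion: str
    baseline_method: str
    weights: Mapping[str, Mapping[str, float]]

    def __post_init__(self) -> None:
        if self.criterion not in CRITERIA:
            raise ConfigurationError(f"criterion must be AIC or BIC, got {self.criterion!r}")
        if self.baseline_method not in BASELINE_METHODS:
            raise ConfigurationError(
                f"baseline_method must be 'original' or 'same', got {self.baseline_method!r}"
            )
        clean: dict[str, dict[str, float]] = {}
        for endpoint, wmap in self.weights.items():
            if endpoint not in ENDPOINTS:
                raise ConfigurationError(f"unknown endpoint {endpoint!r}")
            unknown = set(wmap) - set(FAMILIES)
            if unknown:
                raise ConfigurationError(f"unknown families in weight map: {sorted(unknown)}")
            vals = {fam: float(w) for fam, w in wmap.items()}
            if any(w < 0 for w in vals.values()):
                raise ConfigurationError(f"{endpoint}: negative weight")
            total = sum(vals.values())
            if abs(total - 1.0) > _SUM_TOL:
                raise ConfigurationError(
                    f"{endpoint}: weights sum to {total!r}, expected 1 within {_SUM_TOL}"
                )
            clean[endpoint] = vals
        object.__setattr__(self, "weights", clean)

    @property
    def key(self) -> tuple[str, str]:
        return (self.criterion, self.baseline_method)

    def endpoint_weights(self, endpoint: str) -> dict[str, float]:
        return dict(self.weights.get(endpoint, {}))


def degenerate_weight_set(
    family: str,
    criterion: str = "BIC",
    baseline_method: str = "original",
) -> MMIWeightSet:
    """Weight set putting all weight on a single family for both endpoints
    (single-model evaluation through the MMI machinery)."""
    return MMIWeightSet(criterion, baseline_method,
                        {"ERR": {family: 1.0}, "EAR": {family: 1.0}})


def weights_from_criterion_values(ic_values: Mapping[str, float]) -> dict[str, float]:
    """Normalized Akaike/Schwarz weights from raw AIC or BIC values.

    ``w_i = exp(-(IC_i - min IC)/2)``, normalized to sum to one. The result
    is invariant under adding a constant to every criterion value.
    """
    if not ic_values:
        raise ConfigurationError("at least one model is required")
    vals = {k: float(v) for k, v in ic_values.items()}
    if any(not math.isfinite(v) for v in vals.values()):
        raise ConfigurationError("criterion values must be finite")
    best = min(vals.values())
    raw = {k: math.exp(-(v - best) / 2.0) for k, v in vals.items()}
    total = sum(raw.values())
    return {k: v / total for k, v in raw.items()}


def averaged_excess_risk_curve(
    weight_set: MMIWeightSet,
    endpoint: str,
    specs: Sequence[RiskModelSpec],
    profile: ExposureProfile,
    ages,
    overrides: Mapping[str, Mapping] | None = None,
):
    """Weighted-average excess risk over an attained-age grid.

    ``overrides`` maps family name to a coefficient override for that
    family's spec of the requested endpoint (the Monte Carlo entry point;
    override values may be broadcastable arrays).
    """
    wmap = weight_set.endpoint_weights(endpoint)
    index = {spec.key: spec for spec in specs}
    total = np.zeros_like(np.asarray(ages, dtype=float))
    for family, weight in wmap.items():
        if weight == 0.0:
            continue
        spec = index.get((family, endpoint))
        if spec is None:
            raise ConfigurationError(
                f"weight {weight} on {family}/{endpoint} but no matching model spec"
            )
        override = overrides.get(family) if overrides else None
        total = total + weight * excess_risk_curve(spec, profile, ages, override)
    return total


def model_averaged_excess_risk(
    weight_set: MMIWeightSet,
    endpoint: str,
    specs: Sequence[RiskModelSpec],
    profile: ExposureProfile,
    overrides: Mapping[str, Mapping] | None = None,
) -> float:
    """Model-averaged excess risk sum_i w_i ER_i at the profile's attained age."""
    value = averaged_excess_risk_curve(
        weight_set, endpoint, specs, profile, profile.attained_age, overrides
    )
    return float(np.asarray(value).reshape(-1)[0]) if np.ndim(value) else float(value)


# ---------------------------------------------------------------------------
# weight-set config I/O


def save_weight_set(weight_set: MMIWeightSet, path) -> None:
    payload = {
        "criterion": weight_set.criterion,
        "baseline_method": weight_set.baseline_method,
        "weights": {ep: {fam: float(w) for fam, w in wmap.items()}
                    for ep, wmap in weight_set.weights.items()},
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_weight_set(path, renormalize_tol: float = 1e-6) -> MMIWeightSet:
    """Load a weight-set config file.

    Endpoint weights whose sum deviates from one by no more than
    ``renormalize_tol`` are renormalized exactly (logged); larger deviations
    raise :class:`ConfigurationError`.
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        raw = {str(ep): {str(f): float(w) for f, w in wmap.items()}
               for ep, wmap in doc["weights"].items()}
        criterion = str(doc["criterion"])
        baseline_method = str(doc["baseline_method"])
    except (KeyError, TypeError, AttributeError) as exc:
        raise ConfigurationError(f"{path}: malformed weight-set file: {exc}") from exc
    for endpoint, wmap in raw.items():
        total = sum(wmap.values())
        if abs(total - 1.0) > renormalize_tol:
            raise ConfigurationError(
                f"{path}: {endpoint} weights sum to {total}, "
                f"outside tolerance {renormalize_tol}"
            )
        if total != 1.0 and total > 0:
            logger.info("%s: renormalizing %s weights (sum was %.12g)",
                        path, endpoint, total)
            raw[endpoint] = {f: w / total for f, w in wmap.items()}
    return MMIWeightSet(criterion, baseline_method, raw)
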