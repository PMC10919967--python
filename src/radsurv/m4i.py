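"""Multi-method-multi-model inference (M4I).

Multi-model inference yields four method-level RADS estimates per mission
scenario — one for each combination of information criterion (AIC, BIC) and
baseline-fitting method (each model's original baseline vs. a common "same"
parametric baseline). Because no single method can be clearly favoured, the
four estimates are combined into one general RADS estimate by a weighted
mean (equal weights 1/4 by default; the published general estimates are
exactly the equal-weight means of the method-level points).

The uncertainty of the combined estimate uses Gaussian error propagation for
a weighted mean of independent inputs:

    sigma = sqrt( sum_k v_k^2 sigma_k^2 )

which for equal weights over four inputs is sqrt(sum sigma_k^2) / 4. The
four methods in truth share the underlying data, so the propagated interval
is approximate (treating them as independent ignores positive correlation).
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DataError
from .montecarlo import RADSEstimate

#: the four (criterion, baseline-method) combinations, in canonical order
METHOD_KEYS: tuple[tuple[str, str], ...] = (
    ("AIC", "original"),
    ("AIC", "same"),
    ("BIC", "original"),
    ("BIC", "same"),
)

_Z95 = 1.96  # two-sided 95% normal quantile, at the precision used throughout


class MethodEstimateSet(dict):
    """Mapping (criterion, baseline_method) -> RADSEstimate, exactly the
    four AIC/BIC x original/same combinations for one scenario."""

    def __init__(self, estimates: Mapping[tuple[str, str], RADSEstimate]):
        got = set(estimates)
        expected = set(METHOD_KEYS)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise DataError(
                f"method estimate set must hold exactly {sorted(expected)}; "
                f"missing {missing}, unexpected {extra}"
            )
        super().__init__({k: estimates[k] for k in METHOD_KEYS})


def _resolve_weights(method_weights: Mapping | None) -> np.ndarray:
    if method_weights is None:
        return np.full(len(METHOD_KEYS), 1.0 / len(METHOD_KEYS))
    try:
        v = np.array([float(method_weights[k]) for k in METHOD_KEYS])
    except KeyError as exc:
        raise ConfigurationError(f"method_weights missing key {exc}") from exc
    if np.any(v < 0):
        raise ConfigurationError("method weights must be >= 0")
    if abs(v.sum() - 1.0) > 1e-9:
        raise ConfigurationError(f"method weights sum to {v.sum()!r}, expected 1")
    return v


def m4i_point(estimates: MethodEstimateSet,
              method_weights: Mapping | None = None) -> float:
    """Weighted mean of the four method-level RADS points (default 1/4 each)."""
    if not isinstance(estimates, MethodEstimateSet):
        estimates = MethodEstimateSet(estimates)
    v = _resolve_weights(method_weights)
    points = np.array([estimates[k].point for k in METHOD_KEYS])
    return float(v @ points)


def m4i_propagated_sigma(sigmas: Sequence[float] | Mapping[tuple[str, str], float],
                         method_weights: Mapping | None = None) -> float:
    """Gaussian-propagated standard deviation of the weighted mean.

    ``sigmas`` is either a sequence aligned with ``METHOD_KEYS`` or a
    mapping keyed by them. With equal weights this is
    ``sqrt(sum sigma_k^2) / 4``.
    """
    if isinstance(sigmas, Mapping):
        s = np.array([float(sigmas[k]) for k in METHOD_KEYS])
    else:
        s = np.asarray(list(sigmas), dtype=float)
        if s.size != len(METHOD_KEYS):
            raise DataError(f"expected {len(METHOD_KEYS)} sigmas, got {s.size}")
    if np.any(s < 0):
        raise DataError("standard deviations must be >= 0")
    v = _resolve_weights(method_weights)
    return float(math.sqrt(float(np.sum(v * v * s * s))))


def _sigma_of(estimate: RADSEstimate, sigma_source: str) -> float:
    if sigma_source == "mc_sd":
        if estimate.realisations is None:
            raise DataError(
                f"{estimate.method_label or 'estimate'}: sigma_source='mc_sd' "
                "requires stored realisations"
            )
        return estimate.mc_sd
    if sigma_source == "ci_halfwidth":
        return (estimate.ci_high - estimate.ci_low) / (2.0 * _Z95)
    raise ConfigurationError(
        f"sigma_source must be 'mc_sd' or 'ci_halfwidth', got {sigma_source!r}"
    )


def m4i_estimate(
    estimates: MethodEstimateSet,
    sigma_source: str = "mc_sd",
    method_weights: Mapping | None = None,
) -> RADSEstimate:
    """One general RADS estimate from the four method-level estimates.

    The point is the weighted mean of the four points; the 95% CI is
    ``point +/- 1.96 * sigma`` with sigma from Gaussian error propagation,
    truncated to [0, 1). Per-method sigmas come from the Monte Carlo
    standard deviation of each method's realisations (``"mc_sd"``) or from
    the CI half-width divided by 1.96 (``"ci_halfwidth"``).
    """
    if not isinstance(estimates, MethodEstimateSet):
        estimates = MethodEstimateSet(estimates)
    point = m4i_point(estimates, method_weights)
    sigmas = [_sigma_of(estimates[k], sigma_source) for k in METHOD_KEYS]
    sigma = m4i_propagated_sigma(sigmas, method_weights)
    lo = max(0.0, point - _Z95 * sigma)
    hi = min(point + _Z95 * sigma, np.nextafter(1.0, 0.0))
    return RADSEstimate(point, lo, hi, realisations=None, method_label="m4i")
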