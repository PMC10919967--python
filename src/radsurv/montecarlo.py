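"""Monte Carlo uncertainty propagation for RADS.

95% confidence intervals are obtained from (by default) 1000 realisations of
the full RADS calculation. Each realisation draws

* every model's coefficient vector from its asymptotic multivariate normal
  distribution (mean = fitted coefficients, covariance = the spec's
  covariance matrix); models are resampled independently of one another, and
  the ERR and EAR variants of a family are resampled independently (no
  cross-model or cross-endpoint covariance is available);
* a Poisson-resampled baseline rate table: each cell's expected event count
  ``lambda = rate_fraction * person_years`` is replaced by a Poisson(lambda)
  draw divided by the person-year denominator.

Draws are untruncated, so individual coefficient realisations can be
negative; any negative excess hazard that results is floored at zero per age
step (the flooring fraction is logged at DEBUG level).

A single pseudo-random stream per run is seeded from ``settings.seed``; the
draw order is: coefficients in model-registry order, then baseline cells in
age-major order with male before female. The interval is the 2.5th-97.5th
percentile range of the realisations; the reported point estimate is the
plug-in value at the mean coefficients and unperturbed baseline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .core import (
    BaselineRateTable,
    RADSSettings,
    _check_coverage,
    age_grid,
    rads_point_estimate,
)
from .errors import ConfigurationError, DataError
from .mmi import MMIWeightSet, averaged_excess_risk_curve
from .risk_models import ExposureProfile, RiskModelSpec

logger = logging.getLogger(__name__)

_SEX_ORDER = ("male", "female")


@dataclass(frozen=True)
class RADSEstimate:
    """A RADS point estimate with its Monte Carlo 95% interval.

    ``realisations`` holds the Monte Carlo sample behind the percentile
    interval (may be ``None`` for estimates built from published numbers).
    ``method_label`` identifies the producing method, e.g. ``"AIC-original"``,
    ``"single-model:GRANT_L"`` or ``"m4i"``.
    """

    point: float
    ci_low: float
    ci_high: float
    realisations: np.ndarray | None = None
    method_label: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.point < 1.0:
            raise DataError(f"point estimate {self.point} outside [0, 1)")
        if not (0.0 <= self.ci_low <= self.ci_high < 1.0):
            raise DataError(
                f"invalid interval [{self.ci_low}, {self.ci_high}]"
            )

    @property
    def mc_sd(self) -> float:
        """Sample standard deviation of the realisations."""
        if self.realisations is None:
            raise DataError(
                f"{self.method_label or 'estimate'}: no realisations stored"
            )
        return float(np.std(self.realisations, ddof=1))


def _draw_coefficient_matrix(spec: RiskModelSpec, n: int,
                             rng: np.random.Generator) -> np.ndarray:
    """n multivariate-normal coefficient draws, shape (n, p), canonical order."""
    mean = spec.coefficient_vector()
    try:
        return rng.multivariate_normal(mean, spec.covariance, size=n, method="svd")
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded upstream
        raise ConfigurationError(
            f"{spec.family}/{spec.endpoint}: covariance not usable for sampling"
        ) from exc


def sample_coefficients(spec: RiskModelSpec, n: int, seed: int) -> list[dict]:
    """n coefficient draws from the spec's asymptotic normal distribution.

    Returns a list of named coefficient maps; reproducible given ``seed``.
    A zero covariance matrix returns the mean coefficients exactly.
    """
    rng = np.random.default_rng(seed)
    draws = _draw_coefficient_matrix(spec, n, rng)
    names = spec.coefficient_names
    return [dict(zip(names, map(float, row))) for row in draws]


def sample_baseline(baseline: BaselineRateTable, person_years: int,
                    seed: int) -> BaselineRateTable:
    """Poisson-resample every baseline cell.

    Each cell's expected count ``lambda = rate_fraction * person_years`` is
    replaced by a Poisson(lambda) draw divided by ``person_years``. Cells
    with rate zero stay zero. Cell order: age-major, male before female.
    """
    if person_years <= 0:
        raise ConfigurationError("person_years must be > 0")
    rng = np.random.default_rng(seed)
    new = {}
    lam = {sex: baseline.rate_fractions(sex) * person_years for sex in _SEX_ORDER}
    # interleave to honour the age-major, male-first draw order
    stacked = np.column_stack([lam[sex] for sex in _SEX_ORDER])  # (bands, 2)
    draws = rng.poisson(stacked) / float(person_years)
    for j, sex in enumerate(_SEX_ORDER):
        new[sex] = draws[:, j]
    return baseline.with_rate_fractions(new)


def rads_with_ci(
    weight_set: MMIWeightSet,
    specs: Sequence[RiskModelSpec],
    baseline: BaselineRateTable,
    profile: ExposureProfile,
    settings: RADSSettings,
    label: str | None = None,
) -> RADSEstimate:
    """RADS point estimate with a Monte Carlo percentile 95% CI.

    The point estimate is the plug-in value at the mean coefficients and the
    unperturbed baseline. ``settings.mc_realisations`` realisations are
    generated by jointly resampling all model coefficients (independently
    per model, in registry order) and, unless ``settings.baseline_sampling``
    is off, the baseline rates. All realisations are computed vectorized
    over the age grid.
    """
    point = rads_point_estimate(weight_set, specs, baseline, profile, settings)
    n = settings.mc_realisations
    rng = np.random.default_rng(settings.seed)

    # coefficient draws, registry order; kept as (n, 1) columns so the model
    # forms broadcast against the age grid
    overrides_by_endpoint: dict[str, dict[str, dict]] = {"ERR": {}, "EAR": {}}
    for spec in specs:
        draws = _draw_coefficient_matrix(spec, n, rng)
        overrides_by_endpoint[spec.endpoint][spec.family] = {
            name: draws[:, j:j + 1] for j, name in enumerate(spec.coefficient_names)
        }

    grid = age_grid(profile, settings)
    if grid.size == 0:
        realisations = np.zeros(n)
        return RADSEstimate(point, 0.0, 0.0, realisations,
                            label or "-".join(weight_set.key))
    _check_coverage(baseline, grid[0], grid[-1])

    # baseline rates on the grid: (n, g) under resampling, (g,) otherwise
    W = baseline.interpolation_matrix(grid)
    if settings.baseline_sampling:
        py = float(settings.person_years_per_stratum)
        lam = {sex: baseline.rate_fractions(sex) * py for sex in _SEX_ORDER}
        stacked = np.column_stack([lam[sex] for sex in _SEX_ORDER])
        cell_draws = rng.poisson(np.broadcast_to(stacked, (n,) + stacked.shape)) / py
        sex_idx = _SEX_ORDER.index(profile.sex)
        m = cell_draws[:, :, sex_idx] @ W.T
    else:
        m = W @ baseline.rate_fractions(profile.sex)

    err = averaged_excess_risk_curve(weight_set, "ERR", specs, profile, grid,
                                     overrides_by_endpoint["ERR"])
    ear = averaged_excess_risk_curve(weight_set, "EAR", specs, profile, grid,
                                     overrides_by_endpoint["EAR"])
    err, ear = np.broadcast_arrays(np.atleast_2d(err), np.atleast_2d(ear))

    mult = settings.transfer_weight_err * err * m
    add = settings.transfer_weight_ear * ear / 10_000.0
    raw = mult + add / (1.0 if settings.ddref_scope == "all" else settings.ddref)
    if settings.ddref_scope == "all":
        raw = raw / settings.ddref
    floored = np.count_nonzero(raw < 0)
    if floored:
        logger.debug("floored %d / %d negative hazard values (%.3f%%)",
                     floored, raw.size, 100.0 * floored / raw.size)
    h = np.maximum(raw, 0.0)
    H = np.trapezoid(h, grid, axis=-1)
    realisations = np.atleast_1d(-np.expm1(-H))
    if realisations.size == 1 and n > 1:
        # no stochastic component reached the hazard (e.g. all weights on
        # deterministic inputs): replicate the single value
        realisations = np.full(n, float(realisations[0]))
    ci_low, ci_high = np.percentile(realisations, [2.5, 97.5])
    return RADSEstimate(point, float(ci_low), float(ci_high), realisations,
                        label or "-".join(weight_set.key))
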