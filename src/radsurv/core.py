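"""RADS: Radiation Attributed Decrease of Survival.

RADS at attained age ``a`` for a person exposed at age ``e`` to weighted
dose ``D`` is

    RADS(a | e, D) = 1 - exp(-H(a | e, D))

where the cumulative radiation-attributed hazard H integrates the excess
hazard from the end of the latency period to the attained age,

    H(a | e, D) = integral_{e+l}^{a} h(u, e, D) du,

and the excess hazard mixes the multiplicative (ERR) and additive (EAR) risk
transfers against the population baseline incidence m(a):

    h(a, e, D) = [ w_err * ERR(D,a,e) * m(a) + w_ear * EAR(D,a,e)/10000 ] / DDREF.

The 0.5/0.5 transfer weighting follows ICRP (2007) practice for all solid
cancer; DDREF defaults to 2. The division by DDREF applies to the whole
bracketed sum by default (configurable to the EAR term only, since either
reading of the combined formula is defensible).

Numerical choices: the hazard integral uses the composite trapezoidal rule
on a uniform age grid (default 1-year step, the attained age appended when
it does not fall on the grid), which is exact for piecewise-linear
integrands. Baseline rates are linearly interpolated between age-band
midpoints and held flat beyond the table edges. Rates are stored in files
per 100,000 person-years and converted exactly once, at load, to
per-person-year fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError
from .mmi import MMIWeightSet, averaged_excess_risk_curve
from .risk_models import ExposureProfile, RiskModelSpec

logger = logging.getLogger(__name__)

RATE_DENOMINATOR = 100_000.0  # persons behind the per-100,000 PY rate unit
EAR_DENOMINATOR = 10_000.0    # EAR is expressed per 10,000 person-years


@dataclass(frozen=True)
class RADSSettings:
    """Fixed parameters of the RADS calculation.

    Parameters
    ----------
    ddref
        Dose and dose rate effectiveness factor dividing the excess hazard
        (default 2).
    latency
        Lag l in years between exposure and the start of excess-risk
        accumulation (default 5 years, the conventional solid-cancer value;
        the choice is a modelling assumption, not a fitted quantity).
    transfer_weight_err, transfer_weight_ear
        Multiplicative/additive risk-transfer weights (default 0.5 each,
        per ICRP 2007).
    lss_neutron_rbe
        Relative biological effectiveness weighting the neutron dose
        component inside the weighted colon dose (default 10).
    grid_step
        Age step of the hazard quadrature grid in years (default 1).
    mc_realisations
        Monte Carlo sample size for confidence intervals (default 1000).
    seed
        Seed of the single pseudo-random stream used by the Monte Carlo.
    person_years_per_stratum
        Person-year denominator assumed when Poisson-resampling baseline
        rates (default 100,000).
    ddref_scope
        ``"all"``: DDREF divides the whole ERR+EAR sum (default);
        ``"ear_only"``: DDREF divides only the additive EAR term.
    baseline_sampling
        Whether the Monte Carlo Poisson-resamples the baseline rates.
    """

    ddref: float = 2.0
    latency: float = 5.0
    transfer_weight_err: float = 0.5
    transfer_weight_ear: float = 0.5
    lss_neutron_rbe: float = 10.0
    grid_step: float = 1.0
    mc_realisations: int = 1000
    seed: int = 0
    person_years_per_stratum: int = 100_000
    ddref_scope: str = "all"
    baseline_sampling: bool = True

    def __post_init__(self) -> None:
        if self.ddref <= 0:
            raise ConfigurationError(f"ddref must be > 0, got {self.ddref}")
        if self.latency < 0:
            raise ConfigurationError(f"latency must be >= 0, got {self.latency}")
        if self.transfer_weight_err < 0 or self.transfer_weight_ear < 0:
            raise ConfigurationError("transfer weights must be >= 0")
        if self.grid_step <= 0:
            raise ConfigurationError(f"grid_step must be > 0, got {self.grid_step}")
        if self.mc_realisations < 1:
            raise ConfigurationError("mc_realisations must be >= 1")
        if self.person_years_per_stratum <= 0:
            raise ConfigurationError("person_years_per_stratum must be > 0")
        if self.ddref_scope not in ("all", "ear_only"):
            raise ConfigurationError(
                f"ddref_scope must be 'all' or 'ear_only', got {self.ddref_scope!r}"
            )

    def with_(self, **kwargs) -> "RADSSettings":
        return replace(self, **kwargs)


def weighted_dose(gamma_dose: float, neutron_dose: float, rbe: float = 10.0) -> float:
    """Weighted colon dose: gamma dose plus RBE-weighted neutron dose (Gy)."""
    if gamma_dose < 0 or neutron_dose < 0:
        raise DomainError("dose components must be >= 0")
    if rbe <= 0:
        raise DomainError(f"rbe must be > 0, got {rbe}")
    return gamma_dose + rbe * neutron_dose


@dataclass(frozen=True)
class BaselineRateTable:
    """Age- and sex-specific baseline all-solid-cancer incidence rates m(a).

    Backed by a DataFrame with columns ``age`` (band start in years),
    ``sex`` (``male``/``female``) and ``rate_per_100000`` (incidence per
    100,000 person-years). Both sexes must share the same age bands, the
    band starts must be strictly increasing, and bands are interpreted as
    ``[start, next start)`` with the last band as wide as its predecessor.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        required = {"age", "sex", "rate_per_100000"}
        if not required.issubset(df.columns):
            raise DataError(f"baseline table needs columns {sorted(required)}")
        if (df["rate_per_100000"] < 0).any():
            raise DataError("baseline rates must be >= 0")
        sexes = set(df["sex"].unique())
        if sexes != {"male", "female"}:
            raise DataError(f"baseline table must cover both sexes, found {sorted(sexes)}")
        ages_by_sex = {}
        for sex, grp in df.groupby("sex"):
            ages = grp["age"].to_numpy(dtype=float)
            if not np.all(np.diff(np.sort(ages)) > 0):
                raise DataError(f"{sex}: age bands must be strictly increasing")
            ages_by_sex[sex] = np.sort(ages)
        if not np.array_equal(ages_by_sex["male"], ages_by_sex["female"]):
            raise DataError("male and female age bands differ")
        clean = (df[["age", "sex", "rate_per_100000"]]
                 .astype({"age": float, "sex": str, "rate_per_100000": float})
                 .sort_values(["age", "sex"], ascending=[True, True],
                              key=lambda s: s.map({"male": 0, "female": 1})
                              if s.name == "sex" else s)
                 .reset_index(drop=True))
        object.__setattr__(self, "table", clean)

    # -- construction / I/O -------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "BaselineRateTable":
        """Read ``age,sex,rate_per_100000`` CSV (UTF-8, comma-separated)."""
        df = pd.read_csv(path)
        return cls(df)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    # -- geometry -----------------------------------------------------------

    @property
    def band_starts(self) -> np.ndarray:
        return np.unique(self.table["age"].to_numpy(dtype=float))

    @property
    def band_widths(self) -> np.ndarray:
        starts = self.band_starts
        if len(starts) == 1:
            return np.array([1.0])
        widths = np.diff(starts)
        return np.append(widths, widths[-1])

    @property
    def band_midpoints(self) -> np.ndarray:
        return self.band_starts + self.band_widths / 2.0

    @property
    def coverage(self) -> tuple[float, float]:
        """(first band start, last band end) in years."""
        starts = self.band_starts
        return float(starts[0]), float(starts[-1] + self.band_widths[-1])

    # -- rates --------------------------------------------------------------

    def rate_fractions(self, sex: str) -> np.ndarray:
        """Per-person-year rates in band order (the unit conversion point)."""
        grp = self.table[self.table["sex"] == sex].sort_values("age")
        return grp["rate_per_100000"].to_numpy(dtype=float) / RATE_DENOMINATOR

    def interpolation_matrix(self, grid: np.ndarray) -> np.ndarray:
        """Linear map W with W @ rate_fractions = m(grid).

        Rates are attached to band midpoints, linearly interpolated between
        them and held flat beyond the first/last midpoint. Precomputing the
        map lets the Monte Carlo interpolate thousands of resampled rate
        vectors with one matrix product.
        """
        mids = self.band_midpoints
        g = np.asarray(grid, dtype=float)
        W = np.zeros((g.size, mids.size))
        idx = np.searchsorted(mids, g, side="right")
        for i, (x, j) in enumerate(zip(g, idx)):
            if j <= 0:
                W[i, 0] = 1.0
            elif j >= mids.size:
                W[i, -1] = 1.0
            else:
                t = (x - mids[j - 1]) / (mids[j] - mids[j - 1])
                W[i, j - 1] = 1.0 - t
                W[i, j] = t
        return W

    def interpolate(self, sex: str, grid) -> np.ndarray:
        """m(a) as per-person-year fractions on an age grid."""
        g = np.atleast_1d(np.asarray(grid, dtype=float))
        return self.interpolation_matrix(g) @ self.rate_fractions(sex)

    def with_rate_fractions(self, sex_to_fractions: Mapping[str, np.ndarray]
                            ) -> "BaselineRateTable":
        """Copy of the table with replaced per-person-year rates."""
        df = self.table.copy()
        for sex, fracs in sex_to_fractions.items():
            mask = df["sex"] == sex
            order = df.loc[mask].sort_values("age").index
            df.loc[order, "rate_per_100000"] = np.asarray(fracs) * RATE_DENOMINATOR
        return BaselineRateTable(df)


def excess_hazard(err: float, ear: float, baseline_rate: float,
                  settings: RADSSettings) -> float:
    """Excess hazard h (per person-year) from ERR, EAR and the baseline rate.

    ``baseline_rate`` is m(a) as a per-person-year fraction; ``ear`` is per
    10,000 person-years. Negative combined hazards (possible under Monte
    Carlo coefficient draws) are floored at zero.
    """
    if baseline_rate < 0:
        raise DomainError("baseline_rate must be >= 0")
    return float(_hazard(np.asarray(err), np.asarray(ear),
                         np.asarray(baseline_rate), settings))


def _hazard(err, ear, m, settings: RADSSettings):
    """Vectorized excess hazard; floors negative values at zero."""
    mult = settings.transfer_weight_err * err * m
    add = settings.transfer_weight_ear * ear / EAR_DENOMINATOR
    if settings.ddref_scope == "all":
        h = (mult + add) / settings.ddref
    else:
        h = mult + add / settings.ddref
    return np.maximum(h, 0.0)


def age_grid(profile: ExposureProfile, settings: RADSSettings) -> np.ndarray:
    """Uniform quadrature grid over [e + l, a]; empty when a <= e + l."""
    start = profile.age_at_exposure + settings.latency
    stop = profile.attained_age
    if stop <= start:
        return np.empty(0)
    grid = np.arange(start, stop, settings.grid_step)
    if stop - grid[-1] > 1e-9:
        grid = np.append(grid, stop)
    else:
        grid[-1] = stop
    return grid


def _check_coverage(baseline: BaselineRateTable, start: float, stop: float) -> None:
    lo, hi = baseline.coverage
    if start < lo - 1e-9 or stop > hi + 1e-9:
        raise DataError(
            f"baseline rates cover ages [{lo}, {hi}) but the hazard integral "
            f"needs [{start}, {stop}]"
        )


def cumulative_hazard(
    er_provider: Callable[[np.ndarray], tuple],
    baseline: BaselineRateTable,
    profile: ExposureProfile,
    settings: RADSSettings,
) -> float:
    """Cumulative excess hazard H = integral of h over [e + l, a].

    ``er_provider`` maps an attained-age array to (ERR, EAR) arrays
    evaluated at fixed (D, e, s). Returns 0 when the attained age does not
    exceed age at exposure plus latency.
    """
    grid = age_grid(profile, settings)
    if grid.size == 0:
        return 0.0
    _check_coverage(baseline, grid[0], grid[-1])
    err, ear = er_provider(grid)
    m = baseline.interpolate(profile.sex, grid)
    h = _hazard(np.asarray(err, float), np.asarray(ear, float), m, settings)
    return float(np.trapezoid(h, grid))


def rads(H) -> float:
    """RADS = 1 - exp(-H); strictly increasing in H, bounded in [0, 1)."""
    H_arr = np.asarray(H, dtype=float)
    if np.any(H_arr < 0):
        raise DomainError("cumulative hazard must be >= 0")
    out = -np.expm1(-H_arr)
    return float(out) if np.ndim(H) == 0 else out


def rads_point_estimate(
    weight_set: MMIWeightSet,
    specs: Sequence[RiskModelSpec],
    baseline: BaselineRateTable,
    profile: ExposureProfile,
    settings: RADSSettings,
    overrides: Mapping[str, Mapping] | None = None,
) -> float:
    """Plug-in RADS at the mean coefficients (or explicit overrides).

    Composes the model-averaged ERR/EAR curves, the excess hazard, its
    cumulative integral and the RADS transform.
    """
    def er_provider(ages: np.ndarray):
        err = averaged_excess_risk_curve(weight_set, "ERR", specs, profile,
                                         ages, overrides)
        ear = averaged_excess_risk_curve(weight_set, "EAR", specs, profile,
                                         ages, overrides)
        return err, ear

    return rads(cumulative_hazard(er_provider, baseline, profile, settings))
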