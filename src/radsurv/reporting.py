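"""Pipeline orchestration and report generation.

Ties the stages together the way a mission risk assessment runs them: load
the model registry, the four MMI weight sets, the baseline rate table and
the mission scenarios; compute the four method-level RADS estimates (with
Monte Carlo CIs), optionally the single linear-Grant-model estimate, and
the combined M4I general estimate per scenario; write machine-readable CSV
and human-readable text reports.

All RADS values are fractions internally and are multiplied by 100 only at
the output boundary, where they are formatted with two decimals.

A replay mode applies the M4I combiner directly to a CSV of method-level
point estimates and CIs (in percent), such as published mission risk
tables; the packaged ``published_method_estimates.csv`` carries the
method-level RADS values reported for the reference lunar (0.17 Sv) and
Mars (1 Sv) missions at age at exposure 40 and attained age 65.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import BaselineRateTable, RADSSettings, rads_point_estimate
from .errors import ConfigurationError, DataError
from .m4i import METHOD_KEYS, MethodEstimateSet, m4i_estimate
from .mmi import MMIWeightSet, degenerate_weight_set, load_weight_set
from .montecarlo import RADSEstimate, rads_with_ci
from .risk_models import ExposureProfile, RiskModelSpec, load_model_registry
from .synthetic import load_scenarios

logger = logging.getLogger(__name__)

#: method column labels used in report and replay CSVs
METHOD_LABELS = {
    ("AIC", "original"): "aic_original",
    ("AIC", "same"): "aic_same",
    ("BIC", "original"): "bic_original",
    ("BIC", "same"): "bic_same",
}
SINGLE_MODEL_FAMILY = "GRANT_L"


def published_estimates_path() -> Path:
    """Path of the packaged published method-level estimates CSV."""
    return Path(resources.files("radsurv").joinpath(
        "data/published_method_estimates.csv"))


def packaged_weight_sets() -> dict[tuple[str, str], MMIWeightSet]:
    """The four packaged MMI weight-set fixtures, keyed (criterion, baseline)."""
    root = resources.files("radsurv").joinpath("data/weights")
    out = {}
    for key, label in METHOD_LABELS.items():
        out[key] = load_weight_set(Path(root.joinpath(f"{label}.yaml")))
    return out


def load_weight_sets(paths: Sequence) -> dict[tuple[str, str], MMIWeightSet]:
    """Load weight-set files; requires exactly the four method combinations."""
    out: dict[tuple[str, str], MMIWeightSet] = {}
    for path in paths:
        ws = load_weight_set(path)
        if ws.key in out:
            raise ConfigurationError(f"duplicate weight set for {ws.key}")
        out[ws.key] = ws
    missing = [k for k in METHOD_KEYS if k not in out]
    if missing:
        raise ConfigurationError(f"missing weight sets for {missing}")
    return out


@dataclass(frozen=True)
class RunConfig:
    """Inputs of one pipeline run."""

    registry_path: Path
    weight_set_paths: tuple
    baseline_path: Path
    scenarios_path: Path
    out_dir: Path
    settings: RADSSettings = field(default_factory=RADSSettings)
    include_single_model: bool = True


def _child_seed(base_seed: int, *indices: int) -> int:
    """Deterministic per-(scenario, method) seed below 2**31."""
    ss = np.random.SeedSequence((int(base_seed),) + tuple(int(i) for i in indices))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def scenario_estimates(
    weight_sets: Mapping[tuple[str, str], MMIWeightSet],
    specs: Sequence[RiskModelSpec],
    baseline: BaselineRateTable,
    profile: ExposureProfile,
    settings: RADSSettings,
    scenario_index: int = 0,
    include_single_model: bool = True,
) -> dict[str, RADSEstimate]:
    """All method-level estimates plus the M4I combination for one profile."""
    out: dict[str, RADSEstimate] = {}
    method_set = {}
    for j, key in enumerate(METHOD_KEYS):
        ws = weight_sets[key]
        est = rads_with_ci(ws, specs, baseline, profile,
                           settings.with_(seed=_child_seed(settings.seed,
                                                           scenario_index, j)))
        method_set[key] = est
        out[METHOD_LABELS[key]] = est
    if include_single_model:
        single_ws = degenerate_weight_set(SINGLE_MODEL_FAMILY)
        out["grant"] = rads_with_ci(
            single_ws, specs, baseline, profile,
            settings.with_(seed=_child_seed(settings.seed, scenario_index,
                                            len(METHOD_KEYS))),
            label=f"single-model:{SINGLE_MODEL_FAMILY}",
        )
    out["m4i"] = m4i_estimate(MethodEstimateSet(method_set), sigma_source="mc_sd")
    return out


def run_pipeline(config: RunConfig) -> pd.DataFrame:
    """Run every scenario and write ``report.csv`` and ``report.txt``.

    Returns the report DataFrame (RADS in percent). Identical seeds and
    inputs give byte-identical output files.
    """
    specs = load_model_registry(config.registry_path)
    weight_sets = load_weight_sets(config.weight_set_paths)
    baseline = BaselineRateTable.from_csv(config.baseline_path)
    scenarios = load_scenarios(config.scenarios_path)

    rows = []
    for i, scenario in enumerate(scenarios):
        profile = ExposureProfile(
            weighted_dose=float(scenario["weighted_dose"]),
            age_at_exposure=float(scenario["age_at_exposure"]),
            attained_age=float(scenario["attained_age"]),
            sex=str(scenario["sex"]),
        )
        estimates = scenario_estimates(
            weight_sets, specs, baseline, profile, config.settings,
            scenario_index=i, include_single_model=config.include_single_model,
        )
        for method, est in estimates.items():
            rows.append({
                "scenario": scenario["label"],
                "sex": scenario["sex"],
                "dose_gy": profile.weighted_dose,
                "method": method,
                "rads_pct": 100.0 * est.point,
                "ci_low_pct": 100.0 * est.ci_low,
                "ci_high_pct": 100.0 * est.ci_high,
            })
    report = pd.DataFrame(rows)

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report.to_csv(out_dir / "report.csv", index=False, float_format="%.6f")
    with open(out_dir / "report.txt", "w", encoding="utf-8") as fh:
        fh.write(format_report(report))
    logger.info("wrote %s", out_dir / "report.csv")
    return report


def format_report(report: pd.DataFrame) -> str:
    """Human-readable per-scenario table, percentages with two decimals."""
    lines = []
    for (scenario, sex), grp in report.groupby(["scenario", "sex"], sort=False):
        dose = grp["dose_gy"].iloc[0]
        lines.append(f"{scenario} ({dose:g} Gy weighted dose), {sex}")
        for _, row in grp.iterrows():
            lines.append(
                f"  {row['method']:<13s} RADS = {row['rads_pct']:5.2f}% "
                f"(95% CI: {row['ci_low_pct']:5.2f}%; {row['ci_high_pct']:5.2f}%)"
            )
        lines.append("")
    return "\n".join(lines)


def dose_response_table(
    weight_sets: Mapping[tuple[str, str], MMIWeightSet],
    specs: Sequence[RiskModelSpec],
    baseline: BaselineRateTable,
    age_at_exposure: float,
    attained_age: float,
    sex: str,
    doses: Sequence[float],
    settings: RADSSettings,
    include_single_model: bool = True,
) -> pd.DataFrame:
    """RADS point estimates (percent) on a dose grid, one column per method.

    The tabular analogue of the published dose-response figures; no Monte
    Carlo is run (point estimates only).
    """
    columns: dict[str, list[float]] = {METHOD_LABELS[k]: [] for k in METHOD_KEYS}
    if include_single_model:
        columns["grant"] = []
    for dose in doses:
        if dose == 0.0:
            for label in columns:
                columns[label].append(0.0)
            continue
        profile = ExposureProfile(float(dose), age_at_exposure, attained_age, sex)
        for key in METHOD_KEYS:
            value = rads_point_estimate(weight_sets[key], specs, baseline,
                                        profile, settings)
            columns[METHOD_LABELS[key]].append(100.0 * value)
        if include_single_model:
            value = rads_point_estimate(degenerate_weight_set(SINGLE_MODEL_FAMILY),
                                        specs, baseline, profile, settings)
            columns["grant"].append(100.0 * value)
    out = pd.DataFrame({"dose_gy": list(doses), **columns})
    return out


# ---------------------------------------------------------------------------
# replay of published method-level estimates


def load_method_estimates(path_or_df) -> pd.DataFrame:
    """Validate a method-estimate CSV (percent units).

    Columns: ``method`` (e.g. ``aic_original``), ``sex``, ``mission``,
    ``point``, ``ci_low``, ``ci_high``. Rows whose method is not one of the
    four MMI combinations (e.g. single-model rows) are allowed and kept.
    """
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) \
        else pd.read_csv(path_or_df)
    required = {"method", "sex", "mission", "point", "ci_low", "ci_high"}
    if not required.issubset(df.columns):
        raise DataError(f"method-estimate table needs columns {sorted(required)}")
    return df


def replay_published_estimates(
    estimates: pd.DataFrame | None = None,
    method_weights: Mapping | None = None,
) -> pd.DataFrame:
    """Apply the M4I combiner to a table of method-level estimates.

    Uses the packaged published estimates when ``estimates`` is None. Points
    and CI bounds are read in percent, combined on the fraction scale with
    sigmas from CI half-widths, and reported back in percent with the point
    rounded to two decimals.
    """
    df = load_method_estimates(estimates if estimates is not None
                               else published_estimates_path())
    label_to_key = {v: k for k, v in METHOD_LABELS.items()}
    rows = []
    for (sex, mission), grp in df.groupby(["sex", "mission"], sort=False):
        method_set = {}
        for _, row in grp.iterrows():
            key = label_to_key.get(row["method"])
            if key is None:
                continue
            method_set[key] = RADSEstimate(
                point=row["point"] / 100.0,
                ci_low=row["ci_low"] / 100.0,
                ci_high=row["ci_high"] / 100.0,
                realisations=None,
                method_label=row["method"],
            )
        missing = [METHOD_LABELS[k] for k in METHOD_KEYS if k not in method_set]
        if missing:
            raise DataError(f"{sex}/{mission}: missing method rows {missing}")
        combined = m4i_estimate(MethodEstimateSet(method_set),
                                sigma_source="ci_halfwidth",
                                method_weights=method_weights)
        rows.append({
            "sex": sex,
            "mission": mission,
            "m4i_pct": round(100.0 * combined.point, 2),
            "ci_low_pct": round(100.0 * combined.ci_low, 2),
            "ci_high_pct": round(100.0 * combined.ci_high, 2),
        })
    return pd.DataFrame(rows)


def cross_method_differences(estimates: pd.DataFrame | None = None) -> dict:
    """Spread statistics between methods, from point estimates alone (percent).

    Returns, over all sex x mission contexts:

    * ``original_aic_vs_others_min`` / ``..._max``: the smallest and largest
      absolute difference between the AIC-weighted RADS and each of the
      other two methods (BIC-weighted and single Grant model) in the
      original-baseline block;
    * ``same_aic_vs_grant_max``: the largest |AIC - Grant| difference in the
      same-baseline block;
    * ``same_bic_vs_grant_max``: the largest |BIC - Grant| difference in the
      same-baseline block.
    """
    df = load_method_estimates(estimates if estimates is not None
                               else published_estimates_path())
    points = df.set_index(["method", "sex", "mission"])["point"]

    def diffs(method_a: str, method_b: str) -> np.ndarray:
        a = points.loc[method_a]
        b = points.loc[method_b]
        joined = pd.concat([a, b], axis=1, keys=["a", "b"]).dropna()
        if joined.empty:
            raise DataError(f"no overlapping contexts for {method_a}/{method_b}")
        return np.abs(joined["a"] - joined["b"]).to_numpy()

    original = np.concatenate([
        diffs("aic_original", "bic_original"),
        diffs("aic_original", "grant_original"),
    ])
    return {
        "original_aic_vs_others_min": float(np.round(original.min(), 10)),
        "original_aic_vs_others_max": float(np.round(original.max(), 10)),
        "same_aic_vs_grant_max": float(np.round(
            diffs("aic_same", "grant_same").max(), 10)),
        "same_bic_vs_grant_max": float(np.round(
            diffs("bic_same", "grant_same").max(), 10)),
    }
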