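"""Configuration loading, validation and object construction.

A run is described by a nested mapping (YAML or JSON on disk) with five
blocks: ``demographics``, ``epidemiology``, ``costs``, ``budget`` and
``sensitivity``. :func:`default_config` returns the base case; a user file
only needs the keys it overrides. All rates are decimals; values quoted per
100,000 are accepted via an explicit ``per_100k: true`` flag next to the
value to avoid unit mistakes.
"""

from __future__ import annotations

import copy
import json
from pathlib import Path

import yaml

from .budget_impact import BIASettings
from .cost_model import AdverseEvent, AEProfile, DrugCostParams, GradeBin
from .demographics import (
    DEFAULT_ADULT_RATIO,
    DEFAULT_GROWTH_RATE,
    DemographicsSeries,
    calibrate_population,
    generate_series,
    series_from_csv,
)
from .epi_model import DEFAULT_PROGRESSION_PROB, EpiParams
from .sensitivity import PARAMETER_SETTERS, SensitivityRange

__all__ = [
    "default_config",
    "load_config",
    "validate_config",
    "dump_config",
    "build_epi_params",
    "build_demographics",
    "build_drugs",
    "build_ae_profile",
    "build_bia_settings",
    "build_sensitivity_ranges",
    "ConfigError",
]


class ConfigError(ValueError):
    """Raised when a run configuration is malformed."""


def default_config() -> dict:
    """Base-case configuration reproducing the published analysis."""
    return {
        "demographics": {
            # null -> calibrated from the epidemiology block and the target below
            "base_pop40plus": None,
            "anchor_year": 2013,
            "growth_rate": DEFAULT_GROWTH_RATE,
            "adult_ratio": DEFAULT_ADULT_RATIO,
            "start_year": 2003,
            "end_year": 2015,
            "calibration_target": {"incident_advanced": 854, "year": 2013},
            "series_csv": None,
        },
        "epidemiology": {
            "kidney_incidence_40plus": {"value": 19.8, "per_100k": True},
            "rcc_fraction": 0.90,
            "advanced_at_diagnosis_fraction": 0.20,
            "localized_mortality": 0.0166,
            "progression_prob": list(DEFAULT_PROGRESSION_PROB),
            "fav_int_risk_fraction": 0.89,
            "to_post_advanced_prob": 1.0,
            "same_cycle_first_risk": False,
            "prevalence_includes_advanced": False,
        },
        "costs": {
            "drugs": {
                "pazopanib": {"cost_per_cycle": 4046.0, "cycles_per_year": 8,
                              "time_on_treatment_fraction": 0.57},
                "sunitinib": {"cost_per_cycle": 4904.0, "cycles_per_year": 8,
                              "time_on_treatment_fraction": 0.57},
            },
            # null -> use the bundled default adverse-event profile
            "adverse_events": None,
        },
        "budget": {
            "horizon_years": [2013, 2014, 2015],
            "discount_rate": 0.03,
            "reference_year": 2013,
            "share_step": 0.01,
            "new_arm": "pazopanib",
            "ref_arm": "sunitinib",
        },
        "sensitivity": {
            "output_year": 2013,
            "share": 1.0,
            "ranges": [
                {"parameter": "kidney_incidence_40plus",
                 "lower": 17.82, "upper": 21.78, "per_100k": True},
                {"parameter": "rcc_fraction", "lower": 0.85, "upper": 0.95},
                {"parameter": "advanced_at_diagnosis_fraction",
                 "lower": 0.15, "upper": 0.25},
                {"parameter": "localized_mortality", "lower": 0.0149, "upper": 0.0183},
                {"parameter": "progression_year1", "lower": 0.1186, "upper": 0.1449},
                {"parameter": "progression_years2_3", "lower": 0.0411, "upper": 0.0502},
                {"parameter": "progression_years4_5", "lower": 0.0173, "upper": 0.0211},
                {"parameter": "progression_years6_7", "lower": 0.0148, "upper": 0.0181},
                {"parameter": "progression_years8_10", "lower": 0.0113, "upper": 0.0138},
                {"parameter": "fav_int_risk_fraction", "lower": 0.801, "upper": 0.979},
            ],
        },
    }


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path=None) -> dict:
    """Load a YAML/JSON config file merged over the defaults; validate."""
    cfg = default_config()
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, user)
    validate_config(cfg)
    return cfg


def dump_config(cfg: dict, path=None) -> str:
    """Serialize a config mapping to YAML (optionally to a file)."""
    text = yaml.safe_dump(cfg, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def _rate(node, name: str) -> float:
    """Read a rate that may carry an explicit per-100k flag."""
    if isinstance(node, dict):
        unknown = set(node) - {"value", "per_100k"}
        if unknown or "value" not in node:
            raise ConfigError(f"{name}: expected {{value, per_100k}} mapping")
        value = float(node["value"])
        return value * 1e-5 if node.get("per_100k") else value
    return float(node)


def validate_config(cfg: dict) -> None:
    """Structural validation with actionable error messages."""
    for block in ("demographics", "epidemiology", "costs", "budget", "sensitivity"):
        if block not in cfg or not isinstance(cfg[block], dict):
            raise ConfigError(f"missing or malformed config block {block!r}")
    demo = cfg["demographics"]
    if demo.get("series_csv") is None and demo.get("base_pop40plus") is None:
        target = demo.get("calibration_target") or {}
        if "incident_advanced" not in target or "year" not in target:
            raise ConfigError(
                "demographics: either base_pop40plus, series_csv or a "
                "calibration_target {incident_advanced, year} is required"
            )
    if int(demo.get("end_year", 0)) < int(demo.get("start_year", 0)):
        raise ConfigError("demographics: end_year before start_year")
    drugs = cfg["costs"].get("drugs") or {}
    budget = cfg["budget"]
    for arm_key in ("new_arm", "ref_arm"):
        arm = budget.get(arm_key)
        if arm not in drugs:
            raise ConfigError(f"budget: {arm_key}={arm!r} has no entry in costs.drugs")
    for rng in cfg["sensitivity"].get("ranges") or []:
        if rng.get("parameter") not in PARAMETER_SETTERS:
            raise ConfigError(
                f"sensitivity: unknown parameter {rng.get('parameter')!r}"
            )
    # construction performs the numeric range checks
    build_epi_params(cfg)
    build_drugs(cfg)
    build_ae_profile(cfg)
    build_bia_settings(cfg)
    build_sensitivity_ranges(cfg)


def build_epi_params(cfg: dict) -> EpiParams:
    epi = cfg["epidemiology"]
    try:
        return EpiParams(
            kidney_incidence_40plus=_rate(epi["kidney_incidence_40plus"],
                                          "kidney_incidence_40plus"),
            rcc_fraction=float(epi["rcc_fraction"]),
            advanced_at_diagnosis_fraction=float(epi["advanced_at_diagnosis_fraction"]),
            localized_mortality=float(epi["localized_mortality"]),
            progression_prob=tuple(epi["progression_prob"]),
            fav_int_risk_fraction=float(epi["fav_int_risk_fraction"]),
            to_post_advanced_prob=float(epi["to_post_advanced_prob"]),
            same_cycle_first_risk=bool(epi["same_cycle_first_risk"]),
            prevalence_includes_advanced=bool(epi["prevalence_includes_advanced"]),
        )
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"epidemiology block: {exc}") from exc


def build_demographics(cfg: dict, epi: EpiParams | None = None) -> DemographicsSeries:
    demo = cfg["demographics"]
    if demo.get("series_csv"):
        return series_from_csv(demo["series_csv"])
    if epi is None:
        epi = build_epi_params(cfg)
    base = demo.get("base_pop40plus")
    if base is None:
        target = demo["calibration_target"]
        base = calibrate_population(epi, float(target["incident_advanced"]),
                                    int(target["year"]))
        anchor = int(target["year"])
    else:
        base = float(base)
        anchor = int(demo.get("anchor_year", demo["start_year"]))
    start, end = int(demo["start_year"]), int(demo["end_year"])
    return generate_series(
        base_pop40plus=base,
        adult_ratio=float(demo["adult_ratio"]),
        growth_rate=float(demo["growth_rate"]),
        start_year=start,
        n_years=end - start + 1,
        anchor_year=anchor,
    )


def build_drugs(cfg: dict) -> dict:
    out = {}
    for name, block in cfg["costs"]["drugs"].items():
        try:
            out[name] = DrugCostParams(
                name=name,
                cost_per_cycle=float(block["cost_per_cycle"]),
                cycles_per_year=int(block.get("cycles_per_year", 8)),
                time_on_treatment_fraction=float(
                    block.get("time_on_treatment_fraction", 0.57)),
            )
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"costs.drugs.{name}: {exc}") from exc
    return out


def build_ae_profile(cfg: dict) -> AEProfile:
    spec = cfg["costs"].get("adverse_events")
    if spec is None:
        from .cost_model import default_ae_profile
        return default_ae_profile()
    arms = list(cfg["costs"]["drugs"])
    events = []
    for entry in spec:
        bins = []
        for b in entry.get("bins", []):
            if "unit_cost" not in b and any(b.get(f"incidence_{a}", 0) for a in arms):
                raise ConfigError(
                    f"adverse_events.{entry.get('name')}: incidence without unit cost"
                )
            bins.append(GradeBin(
                grade=str(b.get("grade", "")),
                unit_cost=float(b.get("unit_cost", 0.0)),
                incidence={a: float(b.get(f"incidence_{a}", 0.0)) for a in arms},
            ))
        events.append(AdverseEvent(label=str(entry["name"]), bins=tuple(bins)))
    return AEProfile(tuple(events))


def build_bia_settings(cfg: dict) -> BIASettings:
    b = cfg["budget"]
    step = float(b.get("share_step", 0.01))
    if not 0 < step <= 1:
        raise ConfigError("budget.share_step must be in (0, 1]")
    n = int(round(1.0 / step))
    grid = tuple(round(i * step, 10) for i in range(n)) + (1.0,)
    return BIASettings(
        horizon_years=tuple(int(y) for y in b["horizon_years"]),
        discount_rate=float(b["discount_rate"]),
        reference_year=int(b["reference_year"]),
        share_grid=grid,
    )


def build_sensitivity_ranges(cfg: dict) -> list:
    ranges = []
    for rng in cfg["sensitivity"].get("ranges") or []:
        scale = 1e-5 if rng.get("per_100k") else 1.0
        ranges.append(SensitivityRange(
            parameter=rng["parameter"],
            lower=float(rng["lower"]) * scale,
            upper=float(rng["upper"]) * scale,
        ))
    return ranges


def config_to_json(cfg: dict) -> str:
    return json.dumps(cfg, indent=2, sort_keys=True)
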