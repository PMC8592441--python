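"""Configuration schema, validation and typed accessors.

The whole analysis is driven by a single structured (YAML) configuration
with sections ``model``, ``patient``, ``comparison``, ``survival``,
``costs``, ``regimens``, ``utilities``, ``dsa`` and ``psa``. All monetary
values are 2020 USD. :func:`load_config` validates every section — range
violations and unknown keys are rejected with the offending key named —
and the validated mapping is then translated into the domain objects of the
other modules through the accessor functions below.

Sensitivity-analysis parameters are addressed by dotted paths into the
configuration (e.g. ``costs.prices_per_mg.pembrolizumab``).
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .costs import DoseRule, PatientProfile, Regimen, RegimenComponent
from .markov import ModelConfig
from .survival import SurvivalParams
from .utilities import UtilityBands

ARMS = ("pembro_ep", "placebo_ep")
_ENDPOINTS = ("os", "pfs")

_MODEL_KEYS = {
    "cycle_length_days",
    "horizon_years",
    "days_per_year",
    "annual_discount",
    "wtp",
    "half_cycle",
    "rate_transform",
    "utility_weighting",
}
_COST_KEYS = {
    "prices_per_mg",
    "infusion_first_hour",
    "infusion_additional_hour",
    "carboplatin_share",
    "admin_bundle",
    "ae_first_line",
    "subsequent_bundle",
    "ae_second_line_multiplier",
    "subsequent_uptake",
    "subsequent_drug_mode",
    "subsequent_drug_per_cycle",
    "outpatient_visit_per_cycle",
    "supportive_care_per_month",
    "death_cost",
    "pembro_duration_policy",
    "pembro_median_cycles",
}
_COMPONENT_KEYS = {"drug", "kind", "amount", "days_per_cycle", "max_cycles", "weight_key"}


class ConfigError(ValueError):
    pass


def _require(mapping: dict, keys: set, section: str):
    if not isinstance(mapping, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    missing = keys - mapping.keys()
    if missing:
        raise ConfigError(f"missing key(s) {sorted(missing)} in section {section!r}")
    unknown = mapping.keys() - keys
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")


def _check_number(value, key: str, low=None, high=None, strict_low=False):
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ConfigError(f"{key} must be a number, got {value!r}")
    if low is not None and (value <= low if strict_low else value < low):
        raise ConfigError(f"{key} = {value} below allowed minimum {low}")
    if high is not None and value > high:
        raise ConfigError(f"{key} = {value} above allowed maximum {high}")


def _per_arm(mapping, key):
    _require(mapping, set(ARMS), key)
    for arm in ARMS:
        _check_number(mapping[arm], f"{key}.{arm}", low=0.0)


def validate_config(cfg: dict) -> dict:
    """Validate a raw configuration mapping; returns it unchanged on success."""
    _require(
        cfg,
        {"model", "patient", "comparison", "survival", "costs", "regimens", "utilities", "dsa", "psa"},
        "<root>",
    )
    _require(cfg["model"], _MODEL_KEYS, "model")
    # constructor enforces discount/wtp/half_cycle ranges
    model_config(cfg)
    if cfg["model"]["rate_transform"] not in ("identity", "exp"):
        raise ConfigError("model.rate_transform must be 'identity' or 'exp'")
    if cfg["model"]["utility_weighting"] not in ("baseline", "conditional"):
        raise ConfigError("model.utility_weighting must be 'baseline' or 'conditional'")

    _require(cfg["patient"], {"weight_kg", "bsa_m2", "crcl_ml_min"}, "patient")
    patient_profile(cfg)

    _require(cfg["comparison"], {"intervention", "comparator"}, "comparison")
    for role in ("intervention", "comparator"):
        if cfg["comparison"][role] not in ARMS:
            raise ConfigError(f"comparison.{role} must be one of {ARMS}")

    _require(cfg["survival"], set(ARMS), "survival")
    for arm in ARMS:
        _require(cfg["survival"][arm], set(_ENDPOINTS), f"survival.{arm}")
        for ep in _ENDPOINTS:
            survival_params(cfg, arm, ep)  # raises on invalid family/params

    costs = cfg["costs"]
    _require(costs, _COST_KEYS, "costs")
    for drug, price in costs["prices_per_mg"].items():
        _check_number(price, f"costs.prices_per_mg.{drug}", low=0.0)
    for key in ("infusion_first_hour", "infusion_additional_hour", "outpatient_visit_per_cycle",
                "supportive_care_per_month", "death_cost"):
        _check_number(costs[key], f"costs.{key}", low=0.0)
    _check_number(costs["carboplatin_share"], "costs.carboplatin_share", low=0.0, high=1.0)
    for key in ("admin_bundle", "ae_first_line", "subsequent_bundle",
                "ae_second_line_multiplier", "subsequent_drug_per_cycle"):
        _per_arm(costs[key], f"costs.{key}")
    _require(costs["subsequent_uptake"], set(ARMS), "costs.subsequent_uptake")
    for arm in ARMS:
        _check_number(costs["subsequent_uptake"][arm], f"costs.subsequent_uptake.{arm}", 0.0, 1.0)
    if costs["subsequent_drug_mode"] not in ("calibrated", "nccn"):
        raise ConfigError("costs.subsequent_drug_mode must be 'calibrated' or 'nccn'")
    if costs["pembro_duration_policy"] not in ("pfs_occupancy_max35", "fixed_median7"):
        raise ConfigError(
            "costs.pembro_duration_policy must be 'pfs_occupancy_max35' or 'fixed_median7'"
        )
    _check_number(costs["pembro_median_cycles"], "costs.pembro_median_cycles", low=1)

    _require(cfg["regimens"], {"first_line", "subsequent"}, "regimens")
    _require(cfg["regimens"]["first_line"], set(ARMS), "regimens.first_line")
    for arm in ARMS:
        first_line_regimen(cfg, arm)
    subsequent_regimens(cfg)

    _require(cfg["utilities"], {"bands", "edges_months"}, "utilities")
    if not utility_bands(cfg).ordered:
        raise ConfigError("utilities.bands must be non-increasing as death approaches")

    _require(cfg["dsa"], {"ranges"}, "dsa")
    for path, bounds in cfg["dsa"]["ranges"].items():
        base = get_param(cfg, path)
        if not (isinstance(bounds, (list, tuple)) and len(bounds) == 2):
            raise ConfigError(f"dsa.ranges.{path} must be a [low, high] pair")
        low, high = bounds
        if not low <= base <= high:
            raise ConfigError(
                f"dsa.ranges.{path}: base value {base} outside [{low}, {high}]"
            )

    _require(cfg["psa"], {"n_iterations", "distributions"}, "psa")
    _check_number(cfg["psa"]["n_iterations"], "psa.n_iterations", low=1)
    for path, dist in cfg["psa"]["distributions"].items():
        base = get_param(cfg, path)
        allowed = {"family", "shape", "rate", "b"}
        if not isinstance(dist, dict) or "family" not in dist or "shape" not in dist:
            raise ConfigError(f"psa.distributions.{path} needs 'family' and 'shape'")
        unknown = dist.keys() - allowed
        if unknown:
            raise ConfigError(f"unknown key(s) {sorted(unknown)} in psa.distributions.{path}")
        if dist["family"] not in ("gamma", "beta"):
            raise ConfigError(f"psa.distributions.{path}.family must be gamma or beta")
        _check_number(dist["shape"], f"psa.distributions.{path}.shape", low=0.0, strict_low=True)
        if dist["family"] == "beta" and not 0.0 < base < 1.0:
            raise ConfigError(f"psa.distributions.{path}: beta requires base in (0, 1)")
        mean = _distribution_mean(dist, base)
        if base > 0 and abs(mean - base) / base > 0.05:
            raise ConfigError(
                f"psa.distributions.{path}: distribution mean {mean:.4g} drifts "
                f">5% from base value {base:.4g}"
            )
    return cfg


def _distribution_mean(dist: dict, base: float) -> float:
    if dist["family"] == "gamma":
        rate = dist.get("rate")
        return dist["shape"] / rate if rate else base
    a = dist["shape"]
    b = dist.get("b")
    return a / (a + b) if b else base


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg)


def save_config(cfg: dict, path):
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Dotted-path parameter access (used by DSA/PSA)


def get_param(cfg: dict, path: str):
    node = cfg
    for part in path.split("."):
        try:
            node = node[part]
        except (KeyError, TypeError):
            raise ConfigError(f"unknown parameter path {path!r}")
    return node


def set_param(cfg: dict, path: str, value):
    parts = path.split(".")
    node = cfg
    for part in parts[:-1]:
        node = node[part]
    if parts[-1] not in node:
        raise ConfigError(f"unknown parameter path {path!r}")
    node[parts[-1]] = value


def with_param(cfg: dict, path: str, value) -> dict:
    out = copy.deepcopy(cfg)
    set_param(out, path, value)
    return out


def config_hash(cfg: dict) -> str:
    """Stable digest of the configuration, independent of key order."""
    return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


# ---------------------------------------------------------------------------
# Typed accessors


def model_config(cfg: dict) -> ModelConfig:
    m = cfg["model"]
    return ModelConfig(
        cycle_length_days=m["cycle_length_days"],
        horizon_years=m["horizon_years"],
        days_per_year=m["days_per_year"],
        annual_discount=m["annual_discount"],
        wtp=m["wtp"],
        half_cycle=m["half_cycle"],
    )


def patient_profile(cfg: dict) -> PatientProfile:
    p = cfg["patient"]
    return PatientProfile(p["weight_kg"], p["bsa_m2"], p["crcl_ml_min"])


def survival_params(cfg: dict, arm: str, endpoint: str) -> SurvivalParams:
    node = cfg["survival"][arm][endpoint]
    extra = node.keys() - {"family", "theta", "gamma", "rate", "mu", "sigma"}
    if extra:
        raise ConfigError(f"unknown key(s) {sorted(extra)} in survival.{arm}.{endpoint}")
    family = node["family"]
    if family == "exponential":
        params = (node["rate"],)
    elif family == "lognormal":
        params = (node["mu"], node["sigma"])
    else:
        params = (node["theta"], node["gamma"])
    return SurvivalParams(family, params, rate_transform=cfg["model"]["rate_transform"])


def utility_bands(cfg: dict) -> UtilityBands:
    u = cfg["utilities"]
    _require(u["bands"], {"le1m", "m1_6", "m6_12", "gt12m"}, "utilities.bands")
    return UtilityBands(
        le1m=u["bands"]["le1m"],
        m1_6=u["bands"]["m1_6"],
        m6_12=u["bands"]["m6_12"],
        gt12m=u["bands"]["gt12m"],
        edges_months=tuple(u["edges_months"]),
    )


def _component(node: dict, carbo_share: float, where: str) -> RegimenComponent:
    unknown = node.keys() - _COMPONENT_KEYS
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")
    weight = 1.0
    wk = node.get("weight_key")
    if wk == "carboplatin_share":
        weight = carbo_share
    elif wk == "cisplatin_share":
        weight = 1.0 - carbo_share
    elif wk is not None:
        raise ConfigError(f"unknown weight_key {wk!r} in {where}")
    return RegimenComponent(
        drug=node["drug"],
        rule=DoseRule(node["kind"], node["amount"], node.get("days_per_cycle", 1)),
        weight=weight,
        max_cycles=node.get("max_cycles"),
    )


def first_line_regimen(cfg: dict, arm: str) -> Regimen:
    share = cfg["costs"]["carboplatin_share"]
    comps = tuple(
        _component(c, share, f"regimens.first_line.{arm}")
        for c in cfg["regimens"]["first_line"][arm]
    )
    return Regimen(name=arm, components=comps)


def subsequent_regimens(cfg: dict) -> list[tuple[float, Regimen, float]]:
    """(share, regimen, infusion_hours) triples for the bottom-up costing mode."""
    out = []
    total_share = 0.0
    for node in cfg["regimens"]["subsequent"]:
        _require(node, {"name", "share", "infusion_hours", "components"}, "regimens.subsequent[]")
        _check_number(node["share"], "regimens.subsequent[].share", low=0.0, high=1.0)
        comps = tuple(
            _component(c, cfg["costs"]["carboplatin_share"], f"regimens.subsequent.{node['name']}")
            for c in node["components"]
        )
        total_share += node["share"]
        out.append((node["share"], Regimen(node["name"], comps), float(node["infusion_hours"])))
    if out and abs(total_share - 1.0) > 1e-9:
        raise ConfigError("regimens.subsequent shares must sum to 1")
    return out


# ---------------------------------------------------------------------------
# Run manifest


@dataclass
class RunManifest:
    config_hash: str
    seed: int | None
    package_version: str
    timestamp: str
    outputs: list = field(default_factory=list)

    def write(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")
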