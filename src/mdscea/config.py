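"""Configuration schema with the reference analysis' defaults.

A run is configured by a YAML (or JSON) mapping; every key is optional
and an empty file yields the full default configuration: 35-day cycles,
3% annual discounting of costs and effects, per-cycle AML mortality
0.135, MDS utilities 0.67 (0.66 for the standard-dose chemotherapy arm)
and AML utility 0.52, trial treatment-pattern weights 110/79/38/20 and a
€50,000/QALY willingness-to-pay threshold. Unknown keys and out-of-range
values raise :class:`ConfigError` naming the offending key.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Mapping

import yaml

from .cea import WeightSet
from .markov import ModelConfig
from .simulate import ArmScenario, TrialScenario, default_scenario

__all__ = ["Config", "ConfigError", "load_config", "save_config", "DEFAULTS"]


class ConfigError(ValueError):
    """Invalid configuration; the message names the key at fault."""


DEFAULTS: dict[str, Any] = {
    "model": {
        "cycle_days": 35.0,
        "discount_rate": 0.03,
        "aml_mortality_per_cycle": 0.135,
        "horizon_epsilon": 1e-6,
        "max_cycles": 520,
        "half_cycle_correction": False,
        "days_per_year": 365.25,
    },
    "utilities": {
        "mds": {"AZA": 0.67, "BSC": 0.67, "LDC": 0.67, "SDC": 0.66},
        "aml": 0.52,
    },
    "weights": {"AZA": 110, "BSC": 79, "LDC": 38, "SDC": 20},
    "single_session": {"AZA": False, "BSC": False, "LDC": False, "SDC": True},
    "intervention": "AZA",
    "comparators": ["BSC", "LDC", "SDC"],
    "wtp_per_qaly": 50000.0,
    "wtp_grid": {"start": 0.0, "stop": 150000.0, "step": 1000.0},
    "selection_criterion": "aic",
    "psa": {"n_draws": 50000, "dispersion_scale": 1.0, "cost_rel_range": 0.30},
    # null -> the packaged default trial scenario (see simulate.default_scenario)
    "scenario": None,
}


def _merge(defaults: Mapping[str, Any], overrides: Mapping[str, Any], path: str = "") -> dict:
    out = copy.deepcopy(dict(defaults))
    for key, value in overrides.items():
        full = f"{path}{key}"
        if key not in defaults:
            raise ConfigError(f"unknown configuration key: {full!r}")
        base = defaults[key]
        if isinstance(base, Mapping) and isinstance(value, Mapping):
            out[key] = _merge(base, value, path=f"{full}.")
        else:
            out[key] = copy.deepcopy(value)
    return out


@dataclass(frozen=True)
class Config:
    """A validated, fully-resolved configuration."""

    data: dict[str, Any] = field(default_factory=lambda: copy.deepcopy(DEFAULTS))

    def __post_init__(self):
        d = self.data
        try:
            self.model_config()  # delegates the model-block range checks
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"model: {exc}") from exc
        for arm, u in d["utilities"]["mds"].items():
            if not 0.0 <= u <= 1.0:
                raise ConfigError(f"utilities.mds.{arm}: must be in [0, 1], got {u}")
        if not 0.0 <= d["utilities"]["aml"] <= 1.0:
            raise ConfigError(f"utilities.aml: must be in [0, 1], got {d['utilities']['aml']}")
        for arm, w in d["weights"].items():
            if w < 0:
                raise ConfigError(f"weights.{arm}: must be >= 0, got {w}")
        if d["wtp_per_qaly"] < 0:
            raise ConfigError(f"wtp_per_qaly: must be >= 0, got {d['wtp_per_qaly']}")
        if d["selection_criterion"] not in ("aic", "bic"):
            raise ConfigError(
                f"selection_criterion: must be 'aic' or 'bic', got {d['selection_criterion']!r}"
            )
        if d["psa"]["n_draws"] < 1:
            raise ConfigError(f"psa.n_draws: must be >= 1, got {d['psa']['n_draws']}")
        grid = d["wtp_grid"]
        if grid["step"] <= 0 or grid["stop"] < grid["start"]:
            raise ConfigError(f"wtp_grid: invalid range {grid!r}")

    # -- typed views -------------------------------------------------------
    def model_config(self) -> ModelConfig:
        return ModelConfig(**self.data["model"])

    def weight_set(self) -> WeightSet:
        return WeightSet(counts={k: float(v) for k, v in self.data["weights"].items()})

    def utility_mds(self, arm: str) -> float:
        return float(self.data["utilities"]["mds"][arm])

    @property
    def utility_aml(self) -> float:
        return float(self.data["utilities"]["aml"])

    def single_session(self, arm: str) -> bool:
        return bool(self.data["single_session"].get(arm, False))

    @property
    def intervention(self) -> str:
        return self.data["intervention"]

    @property
    def comparators(self) -> tuple[str, ...]:
        return tuple(self.data["comparators"])

    @property
    def wtp_per_qaly(self) -> float:
        return float(self.data["wtp_per_qaly"])

    def wtp_grid(self):
        import numpy as np

        g = self.data["wtp_grid"]
        return np.arange(g["start"], g["stop"] + g["step"] / 2, g["step"])

    def scenario(self, seed: int = 0) -> TrialScenario:
        raw = self.data["scenario"]
        if raw is None:
            return default_scenario(seed=seed)
        try:
            arms = tuple(ArmScenario(**a) for a in raw["arms"])
            return TrialScenario(
                arms=arms, censor_days=float(raw.get("censor_days", 730.0)), seed=seed
            )
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"scenario: {exc}") from exc


def load_config(path=None, overrides: Mapping[str, Any] | None = None) -> Config:
    """Load, merge with defaults, and validate a YAML/JSON configuration.

    ``path=None`` or an empty file returns the default configuration.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, Mapping):
            raise ConfigError(f"configuration root must be a mapping, got {type(loaded).__name__}")
        raw = dict(loaded)
    if overrides:
        raw = _merge(_merge(DEFAULTS, raw), overrides)
    else:
        raw = _merge(DEFAULTS, raw)
    return Config(data=raw)


def save_config(config: Config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.data, fh, sort_keys=False)
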