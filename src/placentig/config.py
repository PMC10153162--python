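"""Run configuration: YAML/JSON loading, validation, and packaged presets.

A run config names a pipeline stage and carries the seed, solver tolerances,
and parameter overrides for any of the three models.  Unknown keys are
rejected with the offending key path so typos fail loudly rather than being
silently ignored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .parameters import (
    HuvecParameters,
    ImmunizationParameters,
    TransferParameters,
    DELTA_AB_HALF_LIFE,
    table1_midpoint,
)

logger = logging.getLogger("placentig")


class ConfigError(ValueError):
    """Raised for malformed configuration with the offending key path."""


STAGES = ("simulate", "calibrate", "sens", "huvec", "vaccinate", "synth")

_TOP_KEYS = {"stage", "seed", "out", "rtol", "atol",
             "transfer", "huvec", "immunization", "scenario"}

_SCENARIO_KEYS = {"t_vax_weeks", "gestational_length_weeks", "dose_scale",
                  "kd_scale_fcrn", "kd_scale_fcgr2b", "fcrn_stb_factor",
                  "fcgr2b_ec_factor", "fcrn_ec_factor"}


@dataclass
class RunConfig:
    """Validated configuration for one pipeline run."""

    stage: str = "simulate"
    seed: int = 0
    out: str | None = None
    rtol: float = 1e-8
    atol: float = 1e-12
    transfer: dict = field(default_factory=dict)
    huvec: dict = field(default_factory=dict)
    immunization: dict = field(default_factory=dict)
    scenario: dict = field(default_factory=dict)

    def transfer_params(self) -> TransferParameters:
        base = table1_midpoint()
        if not self.transfer:
            return base
        for key, value in self.transfer.items():
            if key == "fcgr2b_ec_end" and value == 0:
                logger.warning("FcγRIIb EC endpoint overridden to zero")
            if key == "fcrn_ec_end" and value == 0:
                logger.warning("FcRn EC endpoint overridden to zero")
        merged = {**_params_dict(base), **self.transfer}
        try:
            return TransferParameters.from_dict(merged)
        except (KeyError, ValueError) as exc:
            raise ConfigError(f"transfer: {exc}") from exc

    def huvec_params(self) -> HuvecParameters:
        try:
            return HuvecParameters(**self.huvec)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"huvec: {exc}") from exc

    def immunization_params(self) -> ImmunizationParameters:
        try:
            return ImmunizationParameters(**self.immunization)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"immunization: {exc}") from exc

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def _params_dict(p: TransferParameters) -> dict:
    d = asdict(p)
    for key, val in d.items():
        if isinstance(val, np.ndarray):
            d[key] = val.tolist()
    return d


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    An empty file yields all defaults (Table 1 midpoints, Table 2, Table 3).
    """
    path = Path(path)
    text = path.read_text()
    raw = (json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
    if "stage" in raw and raw["stage"] not in STAGES:
        raise ConfigError(f"stage: must be one of {STAGES}")
    if "scenario" in raw:
        bad = set(raw["scenario"]) - _SCENARIO_KEYS
        if bad:
            raise ConfigError(f"scenario: unknown key(s): {sorted(bad)}")
    cfg = RunConfig(**{k: raw.get(k, getattr(RunConfig, "__dataclass_fields__")[k].default)
                       for k in ("stage", "seed", "out", "rtol", "atol")},
                    transfer=raw.get("transfer", {}) or {},
                    huvec=raw.get("huvec", {}) or {},
                    immunization=raw.get("immunization", {}) or {})
    cfg.scenario = raw.get("scenario", {}) or {}
    # validate the parameter sections eagerly so errors carry the key path
    cfg.transfer_params()
    cfg.huvec_params()
    cfg.immunization_params()
    logger.info("loaded config: stage=%s seed=%d", cfg.stage, cfg.seed)
    return cfg


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------


def preset(name: str):
    """Packaged parameter presets.

    ``table1``            transfer parameters at the optimized-range midpoints
    ``table1_delta_hl``   same, with the 31-day-half-life fetal decay rate
    ``table2``            HUVEC transcytosis parameters
    ``table3``            Tdap immunization parameters
    """
    if name == "table1":
        return table1_midpoint()
    if name == "table1_delta_hl":
        return table1_midpoint().replace(delta_ab=DELTA_AB_HALF_LIFE)
    if name == "table2":
        return HuvecParameters()
    if name == "table3":
        return ImmunizationParameters()
    raise KeyError(f"unknown preset {name!r}")
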