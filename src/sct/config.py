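"""Configuration resolution: defaults, YAML file, CLI overrides.

Internally everything is SI; the configuration surface accepts the bench
units (mm, um, mL) through unit-suffixed keys.  Each physical quantity has
one canonical key plus accepted aliases, e.g. ``v1_ml: 3.1`` and
``v1_m3: 3.1e-6`` resolve identically.  Unknown keys and non-physical
values are rejected with the offending key named.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import yaml

from .capillary_physics import CapillarySystem, FluidProperties
from .errors import ConfigError, GeometryError

__all__ = ["ResolvedConfig", "load_config", "resolve", "DEFAULTS"]

# canonical key -> default (in the canonical key's own unit)
DEFAULTS: dict[str, float] = {
    "gamma_j_m2": 0.0728,      # surface tension
    "beta_deg": 32.3,          # contact angle
    "rho_kg_m3": 997.0,        # fluid density
    "g_m_s2": 9.81,
    "barrel_id_mm": 1.12,      # barrel inner diameter (radius 0.56 mm)
    "tip_id_um": 2.0,          # tip inner diameter (radius 1.0 um)
    "theta_deg": 45.0,         # insertion angle
    "n_coef": 1.0 / 3.0,       # tip-volume modification coefficient
    "v1_ml": 3.1,              # sealed headspace volume
    "p1_pa": 1.01e5,           # ambient pressure
}

# alias key -> (canonical key, factor converting alias value to canonical)
_ALIASES: dict[str, tuple[str, float]] = {
    "v1_m3": ("v1_ml", 1e6),
    "v1_ul": ("v1_ml", 1e-3),
    "barrel_id_m": ("barrel_id_mm", 1e3),
    "barrel_id_um": ("barrel_id_mm", 1e-3),
    "tip_id_m": ("tip_id_um", 1e6),
    "tip_id_mm": ("tip_id_um", 1e3),
    "p1_kpa": ("p1_pa", 1e3),
    "gamma_n_m": ("gamma_j_m2", 1.0),
}

_OPTIONAL_KEYS = ("dp_override_pa",)

# keys whose value must be strictly positive
_POSITIVE = {"gamma_j_m2", "rho_kg_m3", "g_m_s2", "barrel_id_mm",
             "tip_id_um", "theta_deg", "n_coef", "v1_ml", "p1_pa"}


@dataclass(frozen=True)
class ResolvedConfig:
    """Fully resolved parameter set plus per-key provenance
    (``default`` / ``file`` / ``cli``)."""

    fluid: FluidProperties
    system: CapillarySystem
    dp_override_pa: Optional[float]
    values: dict  #: canonical key -> value (canonical units)
    provenance: dict  #: canonical key -> source string


def _canonicalize(items: Mapping[str, float], source: str,
                  values: dict, provenance: dict) -> None:
    for key, raw in items.items():
        if raw is None:
            continue
        if key in _ALIASES:
            canon, factor = _ALIASES[key]
            value = float(raw) * factor
        elif key in DEFAULTS or key in _OPTIONAL_KEYS:
            canon, value = key, float(raw)
        else:
            raise ConfigError(f"unknown configuration key '{key}'")
        if canon in _POSITIVE and value <= 0:
            raise ConfigError(
                f"key '{key}': value must be positive, got {raw}")
        values[canon] = value
        provenance[canon] = source


def resolve(file_values: Optional[Mapping[str, float]] = None,
            cli_values: Optional[Mapping[str, float]] = None
            ) -> ResolvedConfig:
    """Overlay defaults <- file <- CLI and build the physical objects."""
    values = dict(DEFAULTS)
    provenance = {k: "default" for k in DEFAULTS}
    if file_values:
        _canonicalize(file_values, "file", values, provenance)
    if cli_values:
        _canonicalize(cli_values, "cli", values, provenance)

    try:
        fluid = FluidProperties(
            surface_tension=values["gamma_j_m2"],
            density=values["rho_kg_m3"],
            contact_angle_deg=values["beta_deg"],
            gravity=values["g_m_s2"],
        )
        system = CapillarySystem(
            barrel_inner_radius=values["barrel_id_mm"] * 1e-3 / 2.0,
            tip_inner_radius=values["tip_id_um"] * 1e-6 / 2.0,
            insertion_angle_deg=values["theta_deg"],
            headspace_volume=values["v1_ml"] * 1e-6,
            ambient_pressure=values["p1_pa"],
            tip_volume_coefficient=values["n_coef"],
        )
    except GeometryError as exc:
        raise ConfigError(str(exc)) from exc
    return ResolvedConfig(
        fluid=fluid,
        system=system,
        dp_override_pa=values.get("dp_override_pa"),
        values=values,
        provenance=provenance,
    )


def load_config(path=None,
                cli_values: Optional[Mapping[str, float]] = None
                ) -> ResolvedConfig:
    """Load a YAML key-value file (optional) and resolve it against the
    defaults and any CLI overrides."""
    file_values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"config file {path} must be a key-value map")
        file_values = loaded
    return resolve(file_values, cli_values)
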