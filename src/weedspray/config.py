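"""Run configuration, physical constants, and logging.

All quantities are SI internally (m, s, Pa, kg); configuration files and
reports may use the field-convention units (mm, MPa) via the helpers in
:mod:`weedspray.io`.  Every random procedure in the package takes an explicit
seed; the default seed is fixed, never time-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import yaml

log = logging.getLogger("weedspray")

#: Gravitational acceleration (m/s^2).
GRAVITY = 9.8
#: Density of aqueous herbicide (kg/m^3).
HERBICIDE_DENSITY = 1000.0
#: Density of air (kg/m^3).
AIR_DENSITY = 1.225
#: Dynamic viscosity of air (kg/(m s)).
AIR_VISCOSITY = 1.7894e-5
#: Self-weight of a discretized spray parcel (N).
DROPLET_SELF_WEIGHT = 3.0e-4
#: Droplet radius of the discretized spray (m).
DROPLET_RADIUS = 1.0e-3
#: Elastic modulus of weed leaves, in-text value (Pa).
E_LEAF_TEXT = 272.5e6
#: Elastic modulus of weed leaves, tabulated value (Pa).  The source material
#: quotes both values without reconciling them; the in-text value is the
#: default for the static deflection model, the tabulated one for the plant
#: template.
E_LEAF_TABLE = 222.85e6
#: Leaf tissue density (kg/m^3).
LEAF_DENSITY = 700.0


def _from_dict(cls, data: dict[str, Any], path: str = ""):
    """Build a dataclass from a dict, rejecting unknown keys."""
    import typing

    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)} at '{path or cls.__name__}'")
    hints = typing.get_type_hints(cls)
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        ftype = hints.get(f.name, f.type)
        if dataclasses.is_dataclass(ftype) and isinstance(value, dict):
            value = _from_dict(ftype, value, f"{path}.{f.name}" if path else f.name)
        kwargs[f.name] = value
    return cls(**kwargs)


class ConfigError(ValueError):
    """Raised for malformed or unknown configuration input."""


@dataclass
class NozzleConfig:
    outlet_radius: float = 5.0e-4   # m
    discharge_coeff: float = 0.6
    clearance: float = 0.3          # m, nozzle height above ground
    lateral_range: float = 0.2      # m, spray reach to either side
    rounding_step: float = 5.0      # degrees, cone-angle rounding granularity


@dataclass
class LeafConfig:
    length: float = 0.035           # m
    width: float = 0.015            # m
    thickness: float = 4.0e-4       # m
    beta_deg: float = 33.222        # leaf angle above horizontal


@dataclass
class MaterialConfig:
    elastic_modulus: float = E_LEAF_TEXT   # Pa
    density: float = LEAF_DENSITY          # kg/m^3


@dataclass
class SimulationConfig:
    dt: float = 1.0e-3              # s
    duration: float = 0.5           # s
    domain: tuple = (0.1, 0.1, 0.3)  # m, box (x, y, z)
    restitution: float = 0.3
    splash_threshold: float = 15.0  # m/s normal impact speed
    stick_speed: float = 2.0        # m/s; rebound speed below which droplets adhere
    damping_ratio: float = 0.05
    stage_window: float = 0.05      # s, trailing mean used by the stage classifier
    xi_mapping: str = "rotation"    # 'rotation' (bounded) or 'small_angle'


@dataclass
class RunConfig:
    """Top-level configuration shared by the CLI subcommands."""

    gravity: float = GRAVITY
    herbicide_density: float = HERBICIDE_DENSITY
    air_density: float = AIR_DENSITY
    air_viscosity: float = AIR_VISCOSITY
    droplet_radius: float = DROPLET_RADIUS
    droplet_self_weight: float = DROPLET_SELF_WEIGHT
    pressure: float = 0.4e6         # Pa, operating spraying pressure
    deflection_mode: str = "literal"
    volume_mode: str = "aggregate"  # volume convention for the solve chain
    aggregation_window: float = 1.0  # s, spray time aggregated into one parcel
    seed: int = 0
    nozzle: NozzleConfig = field(default_factory=NozzleConfig)
    leaf: LeafConfig = field(default_factory=LeafConfig)
    material: MaterialConfig = field(default_factory=MaterialConfig)
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.deflection_mode not in ("literal", "beam"):
            raise ConfigError(f"deflection_mode must be 'literal' or 'beam', got {self.deflection_mode!r}")
        if self.volume_mode not in ("single_droplet", "aggregate"):
            raise ConfigError(f"volume_mode must be 'single_droplet' or 'aggregate', got {self.volume_mode!r}")
        if self.sim.xi_mapping not in ("rotation", "small_angle"):
            raise ConfigError(f"xi_mapping must be 'rotation' or 'small_angle', got {self.sim.xi_mapping!r}")

    # -- serialisation -------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        return _from_dict(cls, data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} does not contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["sim"]["domain"] = list(d["sim"]["domain"])
        return d

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True, default_flow_style=False)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def echo(self) -> None:
        """Log the effective configuration verbatim."""
        log.info("effective config (hash %s):\n%s", self.hash(),
                 yaml.safe_dump(self.to_dict(), sort_keys=True))


def setup_logging(level: int = logging.INFO) -> None:
    logging.basicConfig(level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s")
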