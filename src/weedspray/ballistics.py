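"""Droplet kinematics from nozzle exit to leaf arrival, and the impact force.

Atomized herbicide leaves the nozzle at speed ``v0`` and travels to the weed
as an oblique projectile (drag-free over the short flight; drag acts only
inside the dynamic simulation).  The nozzle tilt ``theta_d`` is measured from
the downward vertical, so the vertical speed component is
``v0*cos(theta_d) + g*t`` and the arrival speed obeys the energy identity
``v1**2 = v0**2 + 2*g*drop_height``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from .config import DROPLET_SELF_WEIGHT, GRAVITY, HERBICIDE_DENSITY

__all__ = [
    "DropletSpec",
    "LaunchState",
    "ImpactKinematics",
    "impact_velocity",
    "travel_distance",
    "drop_height",
    "time_to_distance",
    "impact_force",
    "fly_to",
]


@dataclass(frozen=True)
class DropletSpec:
    """Physical constants of a discretized spray parcel.

    ``volume_mode='single_droplet'`` takes the parcel to be one spherical
    droplet (V = 4/3 pi R^3); ``'aggregate'`` takes it to be the liquid mass
    discharged over an aggregation window, V = Q*dt/rho.
    """

    radius: float                       # m
    density: float = HERBICIDE_DENSITY  # kg/m^3
    volume: float = None                # m^3; derived for single_droplet mode
    self_weight: float = DROPLET_SELF_WEIGHT  # N
    volume_mode: str = "single_droplet"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("droplet radius must be positive")
        if self.density <= 0:
            raise ValueError("droplet density must be positive")
        if self.self_weight < 0:
            raise ValueError("self weight must be nonnegative")
        if self.volume_mode not in ("single_droplet", "aggregate"):
            raise ValueError(f"unknown volume_mode {self.volume_mode!r}")
        if self.volume is None:
            if self.volume_mode == "aggregate":
                raise ValueError("aggregate volume_mode requires an explicit volume")
            object.__setattr__(self, "volume", 4.0 / 3.0 * math.pi * self.radius**3)
        if self.volume <= 0:
            raise ValueError("droplet volume must be positive")
        if self.volume_mode == "single_droplet":
            sphere = 4.0 / 3.0 * math.pi * self.radius**3
            if abs(self.volume - sphere) > 1e-12 * sphere:
                raise ValueError("single_droplet volume must equal (4/3) pi R^3")

    @classmethod
    def aggregate(cls, radius: float, mass_flow: float, window: float,
                  density: float = HERBICIDE_DENSITY,
                  self_weight: float = DROPLET_SELF_WEIGHT) -> "DropletSpec":
        """Parcel holding the liquid discharged at ``mass_flow`` over ``window`` s."""
        if window <= 0:
            raise ValueError("aggregation window must be positive")
        return cls(radius=radius, density=density,
                   volume=mass_flow * window / density,
                   self_weight=self_weight, volume_mode="aggregate")

    @property
    def mass(self) -> float:
        return self.density * self.volume


@dataclass(frozen=True)
class LaunchState:
    """Nozzle-exit state: speed, tilt from the downward vertical, gravity."""

    v0: float                 # m/s
    tilt_deg: float = 0.0     # degrees from the downward vertical
    g: float = GRAVITY        # m/s^2

    def __post_init__(self):
        if self.v0 < 0:
            raise ValueError("v0 must be nonnegative")
        if not 0.0 <= self.tilt_deg < 90.0:
            raise ValueError("tilt angle must lie in [0, 90) degrees")
        if self.g <= 0:
            raise ValueError("g must be positive")


@dataclass(frozen=True)
class ImpactKinematics:
    """State of the spray parcel on arrival at the leaf."""

    t: float            # s, flight time
    v1: float           # m/s, arrival speed
    lw: float           # m, straight-line distance from the nozzle
    drop_height: float  # m, vertical descent during flight
    force: float = field(default=float("nan"))  # N, impact force if a spec was given


def impact_velocity(launch: LaunchState, t: float) -> float:
    """Arrival speed after flight time ``t`` (oblique projectile motion)."""
    if t < 0:
        raise ValueError("flight time must be nonnegative")
    th = math.radians(launch.tilt_deg)
    return math.hypot(launch.v0 * math.sin(th), launch.v0 * math.cos(th) + launch.g * t)


def travel_distance(launch: LaunchState, t: float) -> float:
    """Straight-line nozzle-to-droplet distance after flight time ``t``."""
    if t < 0:
        raise ValueError("flight time must be nonnegative")
    th = math.radians(launch.tilt_deg)
    return math.hypot(launch.v0 * t * math.sin(th),
                      launch.v0 * t * math.cos(th) + 0.5 * launch.g * t * t)


def drop_height(launch: LaunchState, t: float) -> float:
    """Vertical descent during flight time ``t``."""
    if t < 0:
        raise ValueError("flight time must be nonnegative")
    th = math.radians(launch.tilt_deg)
    return launch.v0 * t * math.cos(th) + 0.5 * launch.g * t * t


def time_to_distance(launch: LaunchState, lw_target: float) -> float:
    """Flight time at which the travel distance reaches ``lw_target``.

    The distance is strictly increasing in t whenever v0 > 0 or g > 0, so the
    inverse is unique; solved by bracketed root finding to 1e-12 s.
    """
    if lw_target < 0:
        raise ValueError("target distance must be nonnegative")
    if lw_target == 0:
        return 0.0
    if launch.v0 == 0 and launch.g == 0:
        raise ValueError("distance unreachable: v0 = 0 and g = 0")
    hi = 1.0
    while travel_distance(launch, hi) < lw_target:
        hi *= 2.0
        if hi > 1e9:  # pragma: no cover - defensive
            raise ValueError("target distance unreachable")
    return brentq(lambda t: travel_distance(launch, t) - lw_target, 0.0, hi,
                  xtol=1e-12, rtol=8.9e-16)


def impact_force(spec: DropletSpec, v1: float) -> float:
    """Impact force of the spray parcel arriving at speed ``v1``.

    F0 = pi * rho * R * v1^2 * V / 2 — quadratic in the arrival speed,
    linear in the parcel volume.
    """
    if v1 < 0:
        raise ValueError("arrival speed must be nonnegative")
    return math.pi * spec.density * spec.radius * v1**2 * spec.volume / 2.0


def fly_to(launch: LaunchState, lw_target: float,
           spec: DropletSpec | None = None) -> ImpactKinematics:
    """Full kinematic chain to the weed position ``lw_target`` from the nozzle."""
    t = time_to_distance(launch, lw_target)
    v1 = impact_velocity(launch, t)
    f = impact_force(spec, v1) if spec is not None else float("nan")
    return ImpactKinematics(t=t, v1=v1, lw=travel_distance(launch, t),
                            drop_height=drop_height(launch, t), force=f)
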