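"""Nozzle geometry, orifice hydraulics, and the operating-pressure solver.

The nozzle hangs at clearance ``h1`` above the ground, mid-row, and must
cover a lateral range ``d`` to either side; the spray cone half-angle is
``gamma = arctan(d / h1)``, rounded up to the next 5 degrees for nozzle
selection.  The Bernoulli relation converts spraying pressure to exit speed,
and the orifice law ``Q = Cd A1 sqrt(2 dP / rho)`` gives the discharge; Q is
volumetric there and multiplied by rho to report the field-convention mass
flow in kg/s.

The solver walks the full chain P -> v0 -> flight time -> v1 -> F0 ->
tip drop and brackets, by bisection on log P, the pressure at which the leaf
is deflected exactly to the parallel-to-ground optimum; doing so at both
reach endpoints (directly beneath the nozzle, and the slant edge of the
cone) spans the admissible pressure window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.optimize import brentq

from . import ballistics, leafmech
from .config import HERBICIDE_DENSITY

__all__ = [
    "NozzleSpec",
    "OperatingPoint",
    "DesignEnvelope",
    "SolveResult",
    "NoSolutionError",
    "cone_angle",
    "round_cone_angle",
    "reach_range",
    "incidence_range",
    "pressure_to_velocity",
    "flow_rate",
    "design_envelope",
    "solve_operating_pressure",
]

#: Reference operating window printed for this nozzle/leaf system (Pa) and
#: (kg/s): used only to report deviations, never to steer the solver.
REFERENCE_P_WINDOW = (0.383e6, 0.389e6)
REFERENCE_Q_WINDOW = (0.011, 0.0113)


class NoSolutionError(RuntimeError):
    """The parallel-to-ground criterion is unreachable in the pressure bracket."""


@dataclass(frozen=True)
class NozzleSpec:
    outlet_radius: float = 5.0e-4    # m, R1
    discharge_coeff: float = 0.6     # Cd
    clearance: float = 0.3           # m, h1
    lateral_range: float = 0.2       # m, d
    rounding_step: float = 5.0       # degrees

    def __post_init__(self):
        if self.outlet_radius <= 0:
            raise ValueError("outlet radius must be positive")
        if not 0.0 < self.discharge_coeff <= 1.0:
            raise ValueError("discharge coefficient must lie in (0, 1]")
        if self.clearance <= 0 or self.lateral_range <= 0:
            raise ValueError("clearance and lateral range must be positive")

    @property
    def outlet_area(self) -> float:
        return math.pi * self.outlet_radius**2

    @property
    def cone_angle_deg(self) -> float:
        return cone_angle(self.lateral_range, self.clearance)

    @property
    def cone_angle_rounded_deg(self) -> float:
        return round_cone_angle(self.cone_angle_deg, self.rounding_step)


@dataclass(frozen=True)
class OperatingPoint:
    """Nozzle operating parameters at a given spraying pressure."""

    pressure: float                 # Pa
    v0: float                       # m/s
    mass_flow: float                # kg/s
    spec: NozzleSpec = field(default_factory=NozzleSpec)

    @classmethod
    def at_pressure(cls, pressure: float, spec: NozzleSpec | None = None,
                    density: float = HERBICIDE_DENSITY) -> "OperatingPoint":
        spec = spec or NozzleSpec()
        return cls(pressure=pressure,
                   v0=pressure_to_velocity(pressure, density),
                   mass_flow=flow_rate(spec, pressure, density),
                   spec=spec)


@dataclass(frozen=True)
class DesignEnvelope:
    """Geometric envelope of the spray: reach and incidence-angle intervals."""

    gamma_deg: float
    gamma_rounded_deg: float
    lw_range: tuple        # m, (min, max) nozzle-to-target distance
    theta_t_range: tuple   # degrees, droplet incidence interval


@dataclass(frozen=True)
class SolveResult:
    """Solved operating window and the intermediate chain quantities."""

    p_range: tuple                  # Pa, (min, max)
    q_range: tuple                  # kg/s at the window endpoints
    envelope: DesignEnvelope
    endpoints: tuple                # per-endpoint dicts of chain intermediates
    deflection_mode: str
    volume_mode: str
    reference_p_window: tuple = REFERENCE_P_WINDOW
    reference_q_window: tuple = REFERENCE_Q_WINDOW

    @property
    def p_deviation_factor(self) -> float:
        """Ratio of the solved window midpoint to the reference midpoint."""
        return (sum(self.p_range) / 2.0) / (sum(self.reference_p_window) / 2.0)


def cone_angle(d: float, h1: float) -> float:
    """Spray cone half-angle gamma = arctan(d / h1), in degrees."""
    if d <= 0 or h1 <= 0:
        raise ValueError("lateral range and clearance must be positive")
    return math.degrees(math.atan(d / h1))


def round_cone_angle(gamma_deg: float, step: float = 5.0) -> float:
    """Round the cone angle up to the next multiple of ``step`` degrees."""
    return math.ceil(gamma_deg / step - 1e-12) * step


def reach_range(h1: float, gamma_rounded_deg: float) -> tuple:
    """Nozzle-to-target distance interval (m).

    Minimum directly beneath the nozzle (= h1); maximum the slant distance to
    the cone edge at ground level (= h1 / cos gamma).
    """
    if h1 <= 0:
        raise ValueError("clearance must be positive")
    if not 0.0 <= gamma_rounded_deg < 90.0:
        raise ValueError("cone angle must lie in [0, 90) degrees")
    return (h1, h1 / math.cos(math.radians(gamma_rounded_deg)))


def incidence_range(beta_deg: float, gamma_rounded_deg: float) -> tuple:
    """Droplet incidence-angle interval (beta, beta + gamma) in degrees."""
    if not 0.0 < beta_deg < 90.0:
        raise ValueError("leaf angle must lie in (0, 90) degrees")
    return (beta_deg, beta_deg + gamma_rounded_deg)


def pressure_to_velocity(pressure: float, density: float = HERBICIDE_DENSITY) -> float:
    """Bernoulli exit speed v0 = sqrt(2 P / rho)."""
    if pressure < 0:
        raise ValueError("pressure must be nonnegative")
    if density <= 0:
        raise ValueError("density must be positive")
    return math.sqrt(2.0 * pressure / density)


def flow_rate(spec: NozzleSpec, delta_p: float,
              density: float = HERBICIDE_DENSITY) -> float:
    """Orifice mass flow Q = rho Cd A1 sqrt(2 dP / rho) (kg/s)."""
    if delta_p < 0:
        raise ValueError("pressure difference must be nonnegative")
    return density * spec.discharge_coeff * spec.outlet_area * math.sqrt(2.0 * delta_p / density)


def design_envelope(spec: NozzleSpec, beta_deg: float) -> DesignEnvelope:
    gamma = spec.cone_angle_deg
    gamma_r = spec.cone_angle_rounded_deg
    return DesignEnvelope(
        gamma_deg=gamma,
        gamma_rounded_deg=gamma_r,
        lw_range=reach_range(spec.clearance, gamma_r),
        theta_t_range=incidence_range(beta_deg, gamma_r),
    )


def _chain_tip_drop(pressure: float, geom: leafmech.LeafGeometry,
                    mat: leafmech.LeafMaterial, spec: NozzleSpec,
                    droplet: ballistics.DropletSpec, lw: float,
                    tilt_deg: float, theta_t_deg: float, mode: str,
                    volume_mode: str, window: float, density: float):
    """P -> v0 -> t -> v1 -> F0 -> tip drop, returning intermediates."""
    v0 = pressure_to_velocity(pressure, density)
    launch = ballistics.LaunchState(v0=v0, tilt_deg=tilt_deg)
    t = ballistics.time_to_distance(launch, lw)
    v1 = ballistics.impact_velocity(launch, t)
    if volume_mode == "aggregate":
        q_mass = flow_rate(spec, pressure, density)
        parcel = ballistics.DropletSpec.aggregate(
            droplet.radius, q_mass, window, density=droplet.density,
            self_weight=droplet.self_weight)
    else:
        parcel = ballistics.DropletSpec(radius=droplet.radius, density=droplet.density,
                                        self_weight=droplet.self_weight)
    f0 = ballistics.impact_force(parcel, v1)
    drop = leafmech.tip_drop(geom, mat, f0, theta_t_deg, G=parcel.self_weight, mode=mode)
    return drop, {"pressure": pressure, "v0": v0, "t": t, "v1": v1, "F0": f0,
                  "lw": lw, "tilt_deg": tilt_deg, "theta_t_deg": theta_t_deg,
                  "tip_drop": drop}


def solve_operating_pressure(geom: leafmech.LeafGeometry,
                             mat: leafmech.LeafMaterial,
                             spec: NozzleSpec,
                             droplet: ballistics.DropletSpec,
                             mode: str = "literal",
                             volume_mode: str = "aggregate",
                             aggregation_window: float = 1.0,
                             density: float = HERBICIDE_DENSITY,
                             bracket: tuple = (1e2, 1e9),
                             tol: float = 1.0) -> SolveResult:
    """Pressure window deflecting the leaf exactly to the parallel optimum.

    For each matched (reach, incidence) endpoint of the design envelope —
    (lw_min, straight down, theta_t = beta) and (lw_max, tilt = gamma,
    theta_t = beta + gamma) — the pressure at which the predicted tip descent
    equals ``parallel_ground_threshold`` is found by bisection on log P
    within ``bracket`` to a residual below ``tol`` Pa.  The returned window
    spans the two roots.  Deterministic: identical inputs give identical
    windows.

    Raises :class:`NoSolutionError`, naming the unreachable endpoint, if the
    criterion cannot be met inside the bracket (e.g. a rigid leaf, or the
    per-droplet volume convention, under which the required pressures are
    astronomically large).
    """
    env = design_envelope(spec, geom.beta_deg)
    threshold = leafmech.parallel_ground_threshold(geom)
    endpoints = (
        {"name": "beneath_nozzle", "lw": env.lw_range[0], "tilt_deg": 0.0,
         "theta_t_deg": env.theta_t_range[0]},
        {"name": "cone_edge", "lw": env.lw_range[1], "tilt_deg": env.gamma_rounded_deg,
         "theta_t_deg": env.theta_t_range[1]},
    )
    lo, hi = bracket

    roots, details = [], []
    for ep in endpoints:
        def residual(log_p: float) -> float:
            drop, _ = _chain_tip_drop(math.exp(log_p), geom, mat, spec, droplet,
                                      ep["lw"], ep["tilt_deg"], ep["theta_t_deg"],
                                      mode, volume_mode, aggregation_window, density)
            return drop - threshold

        f_lo, f_hi = residual(math.log(lo)), residual(math.log(hi))
        if f_lo * f_hi > 0:
            raise NoSolutionError(
                f"parallel-to-ground criterion unreachable at endpoint "
                f"'{ep['name']}' (lw = {ep['lw'] * 1e3:.1f} mm) for pressures in "
                f"({lo:.0f}, {hi:.0f}] Pa with volume_mode={volume_mode!r}")
        # bisect until the pressure interval is below tol (in Pa)
        a, b = math.log(lo), math.log(hi)
        while math.exp(b) - math.exp(a) > tol:
            m = 0.5 * (a + b)
            if residual(a) * residual(m) <= 0:
                b = m
            else:
                a = m
        p_root = math.exp(0.5 * (a + b))
        drop, detail = _chain_tip_drop(p_root, geom, mat, spec, droplet,
                                       ep["lw"], ep["tilt_deg"], ep["theta_t_deg"],
                                       mode, volume_mode, aggregation_window, density)
        detail["name"] = ep["name"]
        detail["residual"] = drop - threshold
        roots.append(p_root)
        details.append(detail)

    p_range = (min(roots), max(roots))
    q_range = tuple(flow_rate(spec, p, density) for p in p_range)
    return SolveResult(p_range=p_range, q_range=q_range, envelope=env,
                       endpoints=tuple(details), deflection_mode=mode,
                       volume_mode=volume_mode)
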