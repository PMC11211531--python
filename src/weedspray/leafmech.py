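"""Static cantilever mechanics of a weed leaf under spray impact.

A leaf is idealized as a uniform rectangular-section cantilever clamped at
the stem, inclined at the leaf angle ``beta`` above horizontal.  Two
deflection models are provided:

``literal``
    The source model's closed-form deflection with its divergent double
    integral read as "integrand at full leaf dimensions times leaf area"
    (the engineering shorthand consistent with its use of total leaf area):

        y(x) = (2 F0 sin(theta) cos(theta_t) x^4 + G cos(beta) x^2)
               / (4 E b h^3 cos^2(theta))  +  theta x

``beam``
    Textbook Euler-Bernoulli cantilever under the uniformly distributed
    transverse surface load q (N/m^2) of :func:`load_intensity`, line load
    w = q b, deflection w x^2 (6 l^2 - 4 l x + x^2) / (24 E I), tip
    deflection w l^4 / (8 E I), plus the same rigid-rotation term theta x.

Angles are accepted in degrees at the API surface and converted centrally;
the rigid-rotation term uses theta in radians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import E_LEAF_TEXT, LEAF_DENSITY

__all__ = [
    "LeafGeometry",
    "LeafMaterial",
    "DeflectionProfile",
    "DeformationRecord",
    "section_inertia",
    "load_intensity",
    "deflection_profile",
    "tip_drop",
    "parallel_ground_threshold",
    "deformation_index",
    "xi_parallel",
    "xi_from_tip_displacement",
]


@dataclass(frozen=True)
class LeafGeometry:
    """Cantilever-beam idealization of a leaf."""

    length: float         # m, l
    width: float          # m, b (maximum width)
    thickness: float      # m, h_l
    beta_deg: float       # degrees, leaf angle above horizontal

    def __post_init__(self):
        if min(self.length, self.width, self.thickness) <= 0:
            raise ValueError("leaf dimensions must be positive")
        if not 0.0 < self.beta_deg < 90.0:
            raise ValueError("leaf angle must lie in (0, 90) degrees")

    @property
    def stem_angle_deg(self) -> float:
        """Angle between leaf and stem, theta = 90 - beta."""
        return 90.0 - self.beta_deg

    @property
    def area(self) -> float:
        """Leaf area A = b l."""
        return self.width * self.length


@dataclass(frozen=True)
class LeafMaterial:
    elastic_modulus: float = E_LEAF_TEXT  # Pa
    density: float = LEAF_DENSITY         # kg/m^3

    def __post_init__(self):
        if self.elastic_modulus <= 0 or self.density <= 0:
            raise ValueError("material constants must be positive")


@dataclass(frozen=True)
class DeflectionProfile:
    """Sampled deflection y(x) in the leaf's small-angle frame."""

    x: np.ndarray          # m, along-leaf coordinate
    y: np.ndarray          # m, transverse deflection incl. rigid rotation
    y_load: np.ndarray     # m, load-induced part only
    c1: float              # slope boundary constant (= theta, radians)
    c2: float              # offset boundary constant (= 0)
    tip_drop: float        # m, vertical descent of the tip under load
    mode: str


@dataclass(frozen=True)
class DeformationRecord:
    """Leaf deformation index from horizontal leaf extents."""

    xi_initial: float      # m, x-extent of the undeformed leaf
    xd: float              # m, x-extent of the deformed leaf

    def __post_init__(self):
        if self.xi_initial <= 0:
            raise ValueError("initial extent must be positive")

    @property
    def delta_x(self) -> float:
        return self.xd - self.xi_initial

    @property
    def xi(self) -> float:
        return self.delta_x / self.xi_initial


def section_inertia(geom: LeafGeometry) -> float:
    """Cross-sectional moment of inertia I = b h^3 / 12."""
    return geom.width * geom.thickness**3 / 12.0


def _angles(geom: LeafGeometry, theta_t_deg: float):
    theta = math.radians(geom.stem_angle_deg)
    beta = math.radians(geom.beta_deg)
    theta_t = math.radians(theta_t_deg)
    if abs(math.cos(theta)) < 1e-12:
        raise ValueError("singular configuration: leaf perpendicular to stem frame (cos theta = 0)")
    return theta, beta, theta_t


def load_intensity(F0: float, geom: LeafGeometry, theta_t_deg: float,
                   G: float = 0.0) -> float:
    """Effective transverse surface load q (N/m^2).

    Combines the impact force (projected by sin(theta) and the incidence
    factor cos(theta_t)) with the parcel self-weight (projected by
    cos(beta)), spread over the leaf area with the 1/(2 A cos^2 theta)
    divisor of the bending-moment integrand.
    """
    theta, beta, theta_t = _angles(geom, theta_t_deg)
    return (F0 * math.sin(theta) * math.cos(theta_t) + G * math.cos(beta)) / (
        2.0 * geom.area * math.cos(theta) ** 2)


def deflection_profile(geom: LeafGeometry, mat: LeafMaterial, F0: float,
                       theta_t_deg: float, G: float = 0.0,
                       mode: str = "literal", n: int = 201) -> DeflectionProfile:
    """Deflection profile of the loaded leaf in its small-angle frame.

    ``y`` includes the rigid inclination term theta*x (boundary conditions
    y(0) = 0, y'(0) = theta); ``y_load`` is the elastic part only.  The
    reported ``tip_drop`` is the vertical descent of the tip, i.e. the
    transverse tip deflection projected onto the vertical: y_load(l) cos(beta).
    """
    if F0 < 0:
        raise ValueError("impact force must be nonnegative")
    theta, beta, theta_t = _angles(geom, theta_t_deg)
    x = np.linspace(0.0, geom.length, n)
    E = mat.elastic_modulus
    if mode == "literal":
        denom = 4.0 * E * geom.width * geom.thickness**3 * math.cos(theta) ** 2
        y_load = (2.0 * F0 * math.sin(theta) * math.cos(theta_t) * x**4
                  + G * math.cos(beta) * x**2) / denom
    elif mode == "beam":
        q = load_intensity(F0, geom, theta_t_deg, G)
        w = q * geom.width  # line load, N/m
        EI = E * section_inertia(geom)
        y_load = w * x**2 * (6.0 * geom.length**2 - 4.0 * geom.length * x + x**2) / (24.0 * EI)
    else:
        raise ValueError(f"unknown deflection mode {mode!r}")
    y = theta * x + y_load
    return DeflectionProfile(x=x, y=y, y_load=y_load, c1=theta, c2=0.0,
                             tip_drop=float(y_load[-1]) * math.cos(beta), mode=mode)


def tip_drop(geom: LeafGeometry, mat: LeafMaterial, F0: float,
             theta_t_deg: float, G: float = 0.0, mode: str = "literal") -> float:
    """Vertical descent of the leaf tip under load (m)."""
    return deflection_profile(geom, mat, F0, theta_t_deg, G, mode=mode, n=2).tip_drop


def parallel_ground_threshold(geom: LeafGeometry) -> float:
    """Tip descent that brings a straight leaf from inclination beta to horizontal.

    This is the deformation at which retained herbicide is maximal; beyond it
    the leaf sheds liquid to the soil (strong impact and drainage).
    """
    return geom.length * math.sin(math.radians(geom.beta_deg))


def deformation_index(xi: float, xd: float) -> float:
    """Leaf deformation index  xi_def = (xd - xi) / xi."""
    if xi <= 0:
        raise ValueError("initial leaf extent must be positive")
    return (xd - xi) / xi


def xi_parallel(geom: LeafGeometry, mapping: str = "rotation") -> float:
    """Deformation index of a leaf deflected exactly to horizontal.

    ``rotation`` treats the leaf as inextensible and rigidly rotated
    (1/cos(beta) - 1); ``small_angle`` uses the transverse-deflection frame
    in which the extent grows linearly with tip displacement (tan^2(beta)).
    """
    beta = math.radians(geom.beta_deg)
    if mapping == "rotation":
        return 1.0 / math.cos(beta) - 1.0
    if mapping == "small_angle":
        return math.tan(beta) ** 2
    raise ValueError(f"unknown xi mapping {mapping!r}")


def xi_from_tip_displacement(s: float, geom: LeafGeometry,
                             mapping: str = "rotation") -> float:
    """Deformation index implied by a transverse tip displacement ``s`` (m).

    ``rotation``: the leaf pivots rigidly by s/l radians, so the horizontal
    extent is l cos(beta - s/l) — bounded, and shrinking again once the leaf
    passes horizontal.  ``small_angle``: the tip translates transversely,
    xd = l cos(beta) + s sin(beta), unbounded in s.
    """
    beta = math.radians(geom.beta_deg)
    length = geom.length
    if mapping == "rotation":
        xd = length * math.cos(beta - s / length)
    elif mapping == "small_angle":
        xd = length * math.cos(beta) + s * math.sin(beta)
    else:
        raise ValueError(f"unknown xi mapping {mapping!r}")
    return deformation_index(length * math.cos(beta), xd)
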