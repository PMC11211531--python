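"""Synthetic inputs: parameterized weed plants, droplet streams, stain images.

Everything the pipeline consumes can be generated here with no external
data.  The plant template is an *Amaranthus retroflexus*-like rosette: two
leaf layers whose growth directions are offset by 45 degrees, twelve leaves
in total, all geometric and mechanical parameters from the measured-template
defaults.  Droplet streams realize a target mass flow as equal spherical
droplets launched from the nozzle uniformly inside the spray cone.  Stain
images emulate water-sensitive paper: binary grids stamped with circular
stains, either from simulated deposit events or driven to target coverages
with the ground truth stored alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import coverage as _cov
from . import leafmech, nozzle, simulate
from .config import DROPLET_RADIUS, E_LEAF_TABLE, HERBICIDE_DENSITY, LEAF_DENSITY

__all__ = [
    "PlantTemplate",
    "Plant",
    "DropletStream",
    "build_plant",
    "sample_droplets",
    "render_paper",
]


@dataclass(frozen=True)
class PlantTemplate:
    """Measured geometry/material template of the model weed (SI units)."""

    height: float = 0.035
    n_leaves: int = 12
    n_top: int = 4                      # top layer; remainder in bottom layer
    layer_offset_deg: float = 45.0      # azimuthal offset between layers
    beta_deg: float = 33.222
    thickness: float = 4.0e-4
    bottom_length: float = 0.035
    bottom_width: float = 0.015
    top_length: float = 0.020
    top_width: float = 0.008
    stem_diameter: float = 0.003
    leaf_density: float = LEAF_DENSITY
    elastic_modulus: float = E_LEAF_TABLE

    def __post_init__(self):
        values = (self.height, self.thickness, self.bottom_length,
                  self.bottom_width, self.top_length, self.top_width,
                  self.stem_diameter, self.leaf_density, self.elastic_modulus)
        if min(values) <= 0 or self.n_leaves <= 0:
            raise ValueError("template parameters must be positive")
        if not 0 < self.n_top < self.n_leaves:
            raise ValueError("per-layer leaf counts must sum to n_leaves")


@dataclass
class Plant:
    """A built plant: positioned leaf geometries plus modal-leaf parameters."""

    template: PlantTemplate
    modal_leaves: list
    droplet_radius: float = DROPLET_RADIUS

    @property
    def leaves(self):
        return [leaf.geom for leaf in self.modal_leaves]


@dataclass
class DropletStream:
    """Emission schedule of a droplet stream (arrays indexed per droplet)."""

    times: np.ndarray       # s
    positions: np.ndarray   # m, (n, 3) at emission
    velocities: np.ndarray  # m/s, (n, 3)
    radii: np.ndarray       # m
    masses: np.ndarray      # kg
    seed: int = 0

    def __len__(self) -> int:
        return len(self.times)

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())


def build_plant(template: PlantTemplate | None = None, jitter: float = 0.0,
                seed: int = 0, damping_ratio: float = 0.05) -> Plant:
    """Build a two-layer plant from the template.

    ``jitter`` applies uniform multiplicative noise of relative half-width
    ``jitter`` to every leaf's length and width (zero jitter reproduces the
    template exactly); deterministic for a fixed seed.
    """
    template = template or PlantTemplate()
    if not 0.0 <= jitter < 0.5:
        raise ValueError("jitter fraction must lie in [0, 0.5)")
    rng = np.random.default_rng(seed)
    mat = leafmech.LeafMaterial(elastic_modulus=template.elastic_modulus,
                                density=template.leaf_density)
    n_bottom = template.n_leaves - template.n_top
    layers = (
        # (count, length, width, attach height, azimuth offset)
        (n_bottom, template.bottom_length, template.bottom_width,
         0.4 * template.height, 0.0),
        (template.n_top, template.top_length, template.top_width,
         template.height, template.layer_offset_deg),
    )
    modal = []
    index = 0
    r_stem = template.stem_diameter / 2.0
    for count, length, width, z, offset in layers:
        for k in range(count):
            az = offset + 360.0 * k / count
            scale_l = 1.0 + jitter * rng.uniform(-1.0, 1.0) if jitter else 1.0
            scale_w = 1.0 + jitter * rng.uniform(-1.0, 1.0) if jitter else 1.0
            geom = leafmech.LeafGeometry(length=length * scale_l,
                                         width=width * scale_w,
                                         thickness=template.thickness,
                                         beta_deg=template.beta_deg)
            root = np.array([r_stem * math.cos(math.radians(az)),
                             r_stem * math.sin(math.radians(az)), z])
            modal.append(simulate.ModalLeaf.from_leaf(
                index, geom, mat, root, az, damping_ratio=damping_ratio))
            index += 1
    return Plant(template=template, modal_leaves=modal)


def sample_droplets(op: nozzle.OperatingPoint, radius: float = DROPLET_RADIUS,
                    gamma_deg: float | None = None, duration: float = 1.0,
                    seed: int = 0, nozzle_height: float | None = None,
                    density: float = HERBICIDE_DENSITY) -> DropletStream:
    """Sample a droplet stream consistent with the operating point.

    The droplet count realizes the target mass flow with equal spherical
    droplets (count = round(Q * duration / droplet mass)); emission times are
    uniform over the duration, directions uniform in solid angle inside the
    cone, and every droplet leaves the nozzle at the Bernoulli exit speed.
    """
    if duration < 0:
        raise ValueError("duration must be nonnegative")
    rng = np.random.default_rng(seed)
    gamma = math.radians(op.spec.cone_angle_rounded_deg if gamma_deg is None
                         else gamma_deg)
    h = op.spec.clearance if nozzle_height is None else nozzle_height
    m_drop = density * 4.0 / 3.0 * math.pi * radius**3
    n = int(round(op.mass_flow * duration / m_drop))
    if n == 0:
        empty = np.empty((0, 3))
        return DropletStream(times=np.empty(0), positions=empty,
                             velocities=empty, radii=np.empty(0),
                             masses=np.empty(0), seed=seed)
    times = np.sort(rng.uniform(0.0, duration, n))
    # uniform in solid angle within the cone about the downward axis
    cos_a = rng.uniform(math.cos(gamma), 1.0, n)
    sin_a = np.sqrt(1.0 - cos_a**2)
    phi = rng.uniform(0.0, 2.0 * math.pi, n)
    directions = np.column_stack([sin_a * np.cos(phi), sin_a * np.sin(phi),
                                  -cos_a])
    velocities = op.v0 * directions
    positions = np.tile([0.0, 0.0, h], (n, 1))
    return DropletStream(times=times, positions=positions,
                         velocities=velocities,
                         radii=np.full(n, radius),
                         masses=np.full(n, m_drop), seed=seed)


def _stamp_disk(pixels: np.ndarray, cx: float, cy: float, r: float,
                origin, resolution: float) -> None:
    """Mark pixels within radius r of (cx, cy) (ground coordinates, m)."""
    nrow, ncol = pixels.shape
    c = (cx - origin[0]) / resolution
    rr = (cy - origin[1]) / resolution
    rad = max(r / resolution, 0.5)
    c0 = max(int(c - rad) - 1, 0)
    c1 = min(int(c + rad) + 2, ncol)
    r0 = max(int(rr - rad) - 1, 0)
    r1 = min(int(rr + rad) + 2, nrow)
    if c0 >= c1 or r0 >= r1:
        return
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    dist2 = (cols[None, :] - c) ** 2 + (rows[:, None] - rr) ** 2
    pixels[r0:r1, c0:c1] |= dist2 <= rad**2


def render_paper(deposits=None, target_coverages=None,
                 layout: _cov.AreaLayout | None = None,
                 resolution: float = 2.0e-4, seed: int = 0,
                 spread_factor: float = 2.0,
                 droplet_radius: float = DROPLET_RADIUS):
    """Render a synthetic water-sensitive-paper stain image.

    Either stamps circular stains (radius = ``spread_factor`` times the
    droplet radius) at given deposit positions, or — when driven by
    ``target_coverages`` for (test, control_left, control_right) — places
    stains in each area, shrinking the stain radius as the remaining deficit
    shrinks, until each measured coverage is within 0.01 of its target.

    Returns ``(StainImage, ground_truth)`` where the ground truth maps area
    names to the measured coverages of the rendered image.
    """
    layout = layout or _cov.AreaLayout()
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rects = list(layout.rects.values())
    pad = 2.0 * spread_factor * droplet_radius
    x0 = min(r.x0 for r in rects) - pad
    x1 = max(r.x1 for r in rects) + pad
    y0 = min(r.y0 for r in rects) - pad
    y1 = max(r.y1 for r in rects) + pad
    # snap the origin to the resolution grid so rect edges fall on pixels
    x0 = math.floor(x0 / resolution) * resolution
    y0 = math.floor(y0 / resolution) * resolution
    ncol = int(math.ceil((x1 - x0) / resolution))
    nrow = int(math.ceil((y1 - y0) / resolution))
    pixels = np.zeros((nrow, ncol), dtype=bool)
    img = _cov.StainImage(pixels=pixels, resolution=resolution,
                          origin=(x0, y0), layout=layout)
    rng = np.random.default_rng(seed)
    stain_r = spread_factor * droplet_radius

    if deposits is not None:
        for row in np.atleast_2d(np.asarray(deposits, dtype=float)):
            x, y = row[0], row[1]
            r = stain_r if row.size < 3 else spread_factor * row[2]
            _stamp_disk(pixels, x, y, r, (x0, y0), resolution)
    elif target_coverages is not None:
        targets = dict(zip(("test", "control_left", "control_right"),
                           target_coverages))
        for name, target in targets.items():
            if not 0.0 <= target <= 1.0:
                raise ValueError(f"target coverage for {name} must lie in [0, 1]")
            rect = layout.rects[name]
            area = rect.width * rect.height
            for _ in range(100000):
                measured = _cov.pixel_coverage(img, rect)
                deficit = target - measured
                if deficit <= 0.005:
                    break
                # stain no larger than the remaining deficit can absorb, and
                # kept inside the rectangle so areas do not bleed into each
                # other
                r = min(stain_r, math.sqrt(deficit * area / math.pi))
                r = min(r, rect.width / 2.0 - resolution, rect.height / 2.0 - resolution)
                cx = rng.uniform(rect.x0 + r, rect.x1 - r)
                cy = rng.uniform(rect.y0 + r, rect.y1 - r)
                _stamp_disk(pixels, cx, cy, r, (x0, y0), resolution)
            else:  # pragma: no cover - defensive
                raise RuntimeError(f"coverage target for {name} not reached")
    truth = {name: _cov.pixel_coverage(img, rect)
             for name, rect in layout.rects.items()}
    return img, truth
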