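"""Spray-coverage evaluation statistics.

Coverage is the stained (or film-covered) fraction of an assessed area.  On
the ground beneath the weed, three coplanar rectangles are assessed: the
test area sheltered under the leaves and one control area on either side,
each 15 mm x 30 mm.  High coverage in the controls with low coverage in the
sheltered test area means the leaves retained the spray.

Coverages are fractions in [0, 1] internally and percentages only at I/O.
The inter-area variance is the population (divide-by-3) variance exactly;
the NMAE normalizes each absolute deviation by the *simulated* value (the
asymmetry is inherited from the metric's definition and kept as is).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Rect",
    "AreaLayout",
    "StainImage",
    "CoverageReport",
    "film_coverage",
    "pixel_coverage",
    "coverage_variance",
    "nmae",
    "NMAE_PREDICTIVE_THRESHOLD",
    "report_for_image",
]

#: NMAE below which a model is deemed able to predict the test data.
NMAE_PREDICTIVE_THRESHOLD = 0.30


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle on the ground plane (m)."""

    x0: float
    y0: float
    width: float
    height: float

    def __post_init__(self):
        if self.width <= 0 or self.height <= 0:
            raise ValueError("rectangle must have positive extent")

    @property
    def x1(self) -> float:
        return self.x0 + self.width

    @property
    def y1(self) -> float:
        return self.y0 + self.height

    def overlaps(self, other: "Rect") -> bool:
        return not (self.x1 <= other.x0 or other.x1 <= self.x0
                    or self.y1 <= other.y0 or other.y1 <= self.y0)


def _default_rects():
    # three adjacent 15 mm x 30 mm areas: control left, test, control right
    w, h = 0.015, 0.030
    return (Rect(-0.0225, -0.015, w, h), Rect(-0.0075, -0.015, w, h),
            Rect(0.0075, -0.015, w, h))


@dataclass(frozen=True)
class AreaLayout:
    """Test area sheltered under the leaves flanked by two control areas."""

    control_left: Rect = field(default_factory=lambda: _default_rects()[0])
    test: Rect = field(default_factory=lambda: _default_rects()[1])
    control_right: Rect = field(default_factory=lambda: _default_rects()[2])

    def __post_init__(self):
        rects = (self.control_left, self.test, self.control_right)
        for i, a in enumerate(rects):
            for b in rects[i + 1:]:
                if a.overlaps(b):
                    raise ValueError("layout rectangles must not overlap")
        areas = [r.width * r.height for r in rects]
        if max(areas) - min(areas) > 1e-12 * max(areas):
            raise ValueError("layout rectangles must have equal areas")

    @property
    def rects(self):
        return {"test": self.test, "control_left": self.control_left,
                "control_right": self.control_right}


@dataclass
class StainImage:
    """Binary stain grid over the layout's bounding region.

    ``pixels[row, col]`` is True where stained; row 0 is the minimum-y edge.
    ``origin`` is the ground-plane position (m) of the grid corner and
    ``resolution`` the pixel pitch in m/pixel.
    """

    pixels: np.ndarray
    resolution: float
    origin: tuple = (0.0, 0.0)
    layout: AreaLayout = field(default_factory=AreaLayout)

    def __post_init__(self):
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        self.pixels = np.asarray(self.pixels, dtype=bool)

    def rect_slice(self, rect: Rect):
        c0 = int(round((rect.x0 - self.origin[0]) / self.resolution))
        c1 = int(round((rect.x1 - self.origin[0]) / self.resolution))
        r0 = int(round((rect.y0 - self.origin[1]) / self.resolution))
        r1 = int(round((rect.y1 - self.origin[1]) / self.resolution))
        if (c0 < 0 or r0 < 0 or c1 > self.pixels.shape[1]
                or r1 > self.pixels.shape[0] or c1 <= c0 or r1 <= r0):
            raise ValueError("rectangle does not lie on the image grid")
        return self.pixels[r0:r1, c0:c1]


@dataclass(frozen=True)
class CoverageReport:
    """Per-area coverages and their deviation statistics (fractions)."""

    eta_test: float
    eta_control_left: float
    eta_control_right: float
    nmae_value: float = None

    def __post_init__(self):
        for eta in (self.eta_test, self.eta_control_left, self.eta_control_right):
            if not 0.0 <= eta <= 1.0:
                raise ValueError("coverages must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return (self.eta_test + self.eta_control_left + self.eta_control_right) / 3.0

    @property
    def variance(self) -> float:
        return coverage_variance(self.eta_test, self.eta_control_left,
                                 self.eta_control_right)

    @property
    def predictive(self) -> bool | None:
        if self.nmae_value is None:
            return None
        return bool(self.nmae_value < NMAE_PREDICTIVE_THRESHOLD)

    def to_dict(self) -> dict:
        d = {"eta_test": self.eta_test,
             "eta_control_left": self.eta_control_left,
             "eta_control_right": self.eta_control_right,
             "eta_mean": self.mean,
             "variance": self.variance}
        if self.nmae_value is not None:
            d["nmae"] = self.nmae_value
            d["predictive"] = self.predictive
        return d


def film_coverage(film_area: float, total_area: float) -> float:
    """Coverage fraction eta = A_liquid / A_total."""
    if total_area <= 0:
        raise ValueError("total area must be positive")
    if film_area < 0 or film_area > total_area:
        raise ValueError("film area must lie in [0, total area]")
    return film_area / total_area


def pixel_coverage(img: StainImage, rect: Rect) -> float:
    """Stained-pixel fraction of the rectangle on the stain image."""
    window = img.rect_slice(rect)
    if window.size == 0:
        raise ValueError("empty assessment area")
    return float(window.sum()) / window.size


def coverage_variance(eta_t: float, eta_cl: float, eta_cr: float) -> float:
    """Population variance of the three area coverages.

    sigma = 1/3 [(eta_t - mean)^2 + (eta_cl - mean)^2 + (eta_cr - mean)^2];
    zero iff all three coverages are equal, invariant under permutation.
    """
    for eta in (eta_t, eta_cl, eta_cr):
        if not 0.0 <= eta <= 1.0:
            raise ValueError("coverages must lie in [0, 1]")
    if eta_t == eta_cl == eta_cr:  # exact zero, not rounding residue
        return 0.0
    return float(np.var([eta_t, eta_cl, eta_cr]))


def nmae(test_values, simulated_values) -> float:
    """Normalized mean absolute error, mean of |y_test - y_sim| / y_sim."""
    yt = np.asarray(test_values, dtype=float)
    ys = np.asarray(simulated_values, dtype=float)
    if yt.shape != ys.shape or yt.ndim != 1 or yt.size < 1:
        raise ValueError("inputs must be equal-length 1-d vectors with n >= 1")
    if np.any(ys == 0.0):
        raise ValueError("simulated values must be nonzero")
    return float(np.mean(np.abs(yt - ys) / np.abs(ys)))


def report_for_image(img: StainImage, reference=None) -> CoverageReport:
    """Coverage report for the three layout areas of a stain image.

    ``reference`` may give per-area reference coverages (test, left, right)
    against which the NMAE is computed.
    """
    etas = {name: pixel_coverage(img, rect) for name, rect in img.layout.rects.items()}
    nm = None
    if reference is not None:
        nm = nmae([etas["test"], etas["control_left"], etas["control_right"]],
                  list(reference))
    return CoverageReport(eta_test=etas["test"],
                          eta_control_left=etas["control_left"],
                          eta_control_right=etas["control_right"],
                          nmae_value=nm)
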