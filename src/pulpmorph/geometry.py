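"""Parametric cell contours and exact polygon measures.

Fibroblast outlines are modelled by two closed parametric families:

* ``star`` — a radial cosine profile ``r(theta) = R * (1 + a*cos(k*theta))``
  with ``k`` lobes of relative amplitude ``a``; at ``a = 0`` it degenerates
  to a circle.  Star-like outlines describe young (cap-stage) fibroblasts.
* ``fusiform`` — an ellipse with aspect ratio ``q >= 1`` and semi-axes
  ``R*sqrt(q)`` and ``R/sqrt(q)``, so the enclosed area is ``pi*R**2``
  independently of the elongation.  Fusiform outlines describe the
  elongated, spindle-shaped cells of the bell stages.

The analytic area / perimeter of the discretised polygon serve as the
ground-truth oracle against which pixel-level measurements are checked.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

__all__ = [
    "ShapeSpec",
    "generate_contour",
    "polygon_area_perimeter",
    "polygon_form_factor",
    "star_amplitude_for_ff",
    "aspect_ratio_for_ff",
]


@dataclass(frozen=True)
class ShapeSpec:
    """Parametric description of one cell outline.

    ``base_radius`` is the equivalent-circle radius in microns: for both
    families the analytic area is close to ``pi * base_radius**2`` (exact in
    the fusiform limit of infinitely many vertices, approximate for stars
    with nonzero lobe amplitude).
    """

    family: str
    base_radius: float
    lobe_amplitude: float = 0.0
    lobe_count: int = 5
    aspect_ratio: float = 1.0
    rotation: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)
    vertex_count: int = 128

    def __post_init__(self) -> None:
        if self.family not in ("star", "fusiform"):
            raise ValueError(f"unknown shape family {self.family!r}")
        if not self.base_radius > 0:
            raise ValueError("base_radius must be positive")
        if self.vertex_count < 32:
            raise ValueError("vertex_count must be at least 32")
        if self.family == "star":
            if not 0.0 <= self.lobe_amplitude < 1.0:
                raise ValueError(
                    "lobe_amplitude must lie in [0, 1); values >= 1 risk a "
                    "self-intersecting contour"
                )
            if self.lobe_count < 3:
                raise ValueError("lobe_count must be >= 3")
        else:
            if not self.aspect_ratio >= 1.0:
                raise ValueError("aspect_ratio must be >= 1")


def generate_contour(spec: ShapeSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """Return the (vertex_count, 2) closed polygon for ``spec`` in microns.

    The polygon is simple (non-self-intersecting) for every valid spec.
    ``rng`` is accepted for interface symmetry with the stochastic
    generators; the contour itself is a deterministic function of the spec.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, spec.vertex_count, endpoint=False)
    if spec.family == "star":
        r = spec.base_radius * (1.0 + spec.lobe_amplitude * np.cos(spec.lobe_count * theta))
        x = r * np.cos(theta)
        y = r * np.sin(theta)
    else:
        x = spec.base_radius * np.sqrt(spec.aspect_ratio) * np.cos(theta)
        y = spec.base_radius / np.sqrt(spec.aspect_ratio) * np.sin(theta)
    if spec.rotation:
        c, s = np.cos(spec.rotation), np.sin(spec.rotation)
        x, y = c * x - s * y, s * x + c * y
    return np.column_stack([x + spec.center[0], y + spec.center[1]])


def polygon_area_perimeter(polygon: np.ndarray) -> tuple[float, float]:
    """Shoelace area (absolute) and summed edge length of a closed polygon.

    The vertex order (clockwise or counter-clockwise) is irrelevant.
    Raises ``ValueError`` for fewer than 3 vertices or a degenerate
    (zero-area) polygon.
    """
    polygon = np.asarray(polygon, dtype=float)
    if polygon.ndim != 2 or polygon.shape[1] != 2 or polygon.shape[0] < 3:
        raise ValueError("polygon must be an (n >= 3, 2) vertex array")
    x, y = polygon[:, 0], polygon[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area == 0.0:
        raise ValueError("degenerate polygon with zero area")
    perimeter = float(np.hypot(np.diff(x, append=x[0]), np.diff(y, append=y[0])).sum())
    return float(area), perimeter


def polygon_form_factor(polygon: np.ndarray) -> float:
    """Analytic form factor 4*pi*A/P**2 of a closed polygon."""
    area, perimeter = polygon_area_perimeter(polygon)
    return 4.0 * np.pi * area / perimeter**2


# ---------------------------------------------------------------------------
# Inverse solvers: shape parameter producing a target form factor.
#
# Both families have a form factor that is scale invariant and strictly
# monotone in the elongation parameter, so a cached forward grid inverted
# with linear interpolation is accurate to well below the polygonal
# discretisation error.
# ---------------------------------------------------------------------------

_MAX_STAR_AMPLITUDE = 0.95


@lru_cache(maxsize=None)
def _star_ff_grid(lobe_count: int, vertex_count: int) -> tuple[tuple[float, ...], tuple[float, ...]]:
    amps = np.linspace(0.0, _MAX_STAR_AMPLITUDE, 200)
    ffs = [
        polygon_form_factor(
            generate_contour(
                ShapeSpec("star", 1.0, lobe_amplitude=a, lobe_count=lobe_count, vertex_count=vertex_count)
            )
        )
        for a in amps
    ]
    return tuple(amps), tuple(ffs)


def star_amplitude_for_ff(ff: float, lobe_count: int = 5, vertex_count: int = 128) -> float:
    """Lobe amplitude whose star contour has form factor ``ff``.

    FF decreases monotonically with amplitude; targets below the family's
    minimum (about 0.13 at five lobes) clamp to the maximum amplitude and
    targets above 1 clamp to a circle.
    """
    if not 0 < ff:
        raise ValueError("target form factor must be positive")
    amps, ffs = (np.asarray(g) for g in _star_ff_grid(lobe_count, vertex_count))
    # np.interp needs increasing x: FF grid is decreasing in amplitude.
    return float(np.interp(ff, ffs[::-1], amps[::-1], left=amps[-1], right=0.0))


@lru_cache(maxsize=None)
def _ellipse_ff_grid(vertex_count: int, max_aspect: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    aspects = np.geomspace(1.0, max_aspect, 300)
    ffs = [
        polygon_form_factor(
            generate_contour(ShapeSpec("fusiform", 1.0, aspect_ratio=q, vertex_count=vertex_count))
        )
        for q in aspects
    ]
    return tuple(aspects), tuple(ffs)


def aspect_ratio_for_ff(ff: float, vertex_count: int = 128, max_aspect: float = 60.0) -> float:
    """Ellipse aspect ratio whose contour has form factor ``ff`` (clamped)."""
    if not 0 < ff:
        raise ValueError("target form factor must be positive")
    aspects, ffs = (np.asarray(g) for g in _ellipse_ff_grid(vertex_count, max_aspect))
    return float(np.interp(ff, ffs[::-1], aspects[::-1], left=aspects[-1], right=1.0))
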