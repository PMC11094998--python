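"""Per-vertebra transverse-plane morphometry.

Three markers define the measurement at each vertebral level: m1 at the
centre of the vertebral body, m2 at the end tip of the spinous process (or
its in-plane projection), and m3 where the straight line through m1 and m2
crosses the nearest outer body contour beyond the spinous tip.  From these
the transverse distances L12 = |m1−m2| and L13 = |m1−m3| follow directly
from the pixel positions and known pixel spacings.  The body-contour area
is additionally split into four quadrants by the two axis-parallel lines
through m1; the normalized quadrant areas yield the back-to-front and
left-to-right area aspects used for cross-patient comparison.

Quadrant labels (in the +x = patient-left, +y = posterior frame):
a1 anterior-right, a2 anterior-left, a3 posterior-left, a4 posterior-right;
f_back = (a3+a4)/total, f_left = (a2+a3)/total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .contour import ContourPolygon
from .io import VolumeSlice

__all__ = [
    "MarkerTriplet",
    "QuadrantAreas",
    "AspectPair",
    "VertebraMeasurement",
    "MarkerGeometryError",
    "euclidean_mm",
    "px_to_mm",
    "skin_crossing",
    "polygon_area",
    "quadrant_areas",
    "area_aspects",
    "measure_vertebra",
]

VERTEBRAL_LEVELS = ("C7", "T1", "T2", "T3", "T4", "T5", "T6", "T7", "T8", "T9",
                    "T10", "T11", "T12", "L1", "L2", "L3", "L4", "L5")

_SLIVER_AREA_MM2 = 1e-9  # degenerate clip slivers treated as zero


class MarkerGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class MarkerTriplet:
    """Manually set markers for one vertebra on one axial slice.

    m1/m2 are (row, col) pixel positions; m2 may be None when no clear
    spinous-process end tip could be identified.  m3 is computed, never
    user-set.
    """

    level: str
    slice_index: int
    m1_px: tuple[float, float]
    m2_px: tuple[float, float] | None = None

    def __post_init__(self):
        if self.level not in VERTEBRAL_LEVELS:
            raise ValueError(f"unknown vertebral level {self.level!r}")
        if self.m2_px is not None and np.allclose(self.m1_px, self.m2_px):
            raise MarkerGeometryError("m1 and m2 must differ")


@dataclass(frozen=True)
class QuadrantAreas:
    """Areas (mm²) of the four contour quadrants about m1, plus total."""

    a1: float
    a2: float
    a3: float
    a4: float
    total: float

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.a1 / self.total, self.a2 / self.total,
                self.a3 / self.total, self.a4 / self.total)


@dataclass(frozen=True)
class AspectPair:
    """Back-to-front and left-to-right area aspects, each in (0, 1)."""

    f_back: float
    f_left: float


@dataclass(frozen=True)
class VertebraMeasurement:
    level: str
    L12_mm: float | None
    L13_mm: float | None
    m3_mm: tuple[float, float] | None
    quadrants: QuadrantAreas
    aspects: AspectPair
    ellipse_pos: object | None = None  # EllipsePosition, filled by ellipse_map


def px_to_mm(p_px, spacing_mm) -> np.ndarray:
    """(row, col) pixel position → (x, y) mm (x = col·col_sp, y = row·row_sp)."""
    r, c = float(p_px[0]), float(p_px[1])
    sr, sc = spacing_mm
    return np.array([c * sc, r * sr])


def euclidean_mm(p_px, q_px, spacing_mm) -> float:
    """Euclidean distance in mm between two pixel positions."""
    sr, sc = spacing_mm
    if sr <= 0 or sc <= 0:
        raise ValueError("spacing components must be positive")
    dr = (float(p_px[0]) - float(q_px[0])) * sr
    dc = (float(p_px[1]) - float(q_px[1])) * sc
    return math.hypot(dr, dc)


def skin_crossing(m1_mm, m2_mm, contour: ContourPolygon) -> np.ndarray:
    """First contour crossing of the ray m1→m2 beyond the spinous tip.

    The ray p(t) = m1 + t·(m2−m1) is intersected with every polygon edge;
    the intersection with the smallest t > 1 is returned (the nearest
    outer-contour crossing on the posterior side of m2).
    """
    m1 = np.asarray(m1_mm, dtype=np.float64)
    m2 = np.asarray(m2_mm, dtype=np.float64)
    u = m2 - m1
    if not np.any(u):
        raise MarkerGeometryError("m1 and m2 coincide")
    P = contour.vertices
    Q = np.roll(P, -1, axis=0)
    e = Q - P
    w = P - m1
    denom = u[0] * e[:, 1] - u[1] * e[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (w[:, 0] * e[:, 1] - w[:, 1] * e[:, 0]) / denom
        s = (w[:, 0] * u[1] - w[:, 1] * u[0]) / denom
    hit = (np.abs(denom) > 0) & (s >= 0.0) & (s < 1.0) & (t > 1.0)
    if not np.any(hit):
        raise MarkerGeometryError("ray m1->m2 does not cross the contour beyond m2")
    t_min = float(np.min(t[hit]))
    return m1 + t_min * u


def polygon_area(contour: ContourPolygon | np.ndarray) -> float:
    """Area of a simple closed polygon by the Surveyor's (shoelace) formula.

    |½ Σ (xᵢ yᵢ₊₁ − xᵢ₊₁ yᵢ)| over the closed vertex cycle.
    """
    v = contour.vertices if isinstance(contour, ContourPolygon) else np.asarray(contour, float)
    if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if np.allclose(v[0], v[-1]) and len(v) > 3:
        v = v[:-1]
    x, y = v[:, 0], v[:, 1]
    return abs(0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def quadrant_areas(contour: ContourPolygon, center_mm) -> QuadrantAreas:
    """Split the contour-enclosed area into quadrants about ``center_mm``.

    The polygon is clipped against the two axis-parallel half-plane pairs
    through the centre; each piece's area comes from the shoelace formula
    (via shapely).  The centre must be strictly interior.
    """
    from shapely.geometry import Point, box

    poly = contour.to_shapely()
    if not poly.is_valid:
        poly = poly.buffer(0)
    cx, cy = float(center_mm[0]), float(center_mm[1])
    if not poly.contains(Point(cx, cy)):
        raise MarkerGeometryError("quadrant centre must be strictly inside the contour")
    minx, miny, maxx, maxy = poly.bounds
    minx -= 1.0
    miny -= 1.0
    maxx += 1.0
    maxy += 1.0
    areas = [
        poly.intersection(box(minx, miny, cx, cy)).area,  # a1 anterior-right
        poly.intersection(box(cx, miny, maxx, cy)).area,  # a2 anterior-left
        poly.intersection(box(cx, cy, maxx, maxy)).area,  # a3 posterior-left
        poly.intersection(box(minx, cy, cx, maxy)).area,  # a4 posterior-right
    ]
    areas = [0.0 if a < _SLIVER_AREA_MM2 else a for a in areas]
    return QuadrantAreas(*areas, total=poly.area)


def area_aspects(q: QuadrantAreas) -> AspectPair:
    """Back-to-front and left-to-right area aspects from quadrant areas."""
    if q.total <= 0:
        raise ValueError("total area must be positive")
    return AspectPair(f_back=(q.a3 + q.a4) / q.total, f_left=(q.a2 + q.a3) / q.total)


def measure_vertebra(slice_: VolumeSlice, markers: MarkerTriplet, contour: ContourPolygon,
                     substitute_direction_mm=None) -> VertebraMeasurement:
    """Compose the per-vertebra measurement from markers and contour.

    L12 is missing when m2 is absent; L13 is then computed only if a
    substitute posterior direction is supplied (otherwise missing too).
    Quadrants and aspects are always computed from m1.
    """
    spacing = slice_.spacing_mm
    m1 = px_to_mm(markers.m1_px, spacing)

    quads = quadrant_areas(contour, m1)
    aspects = area_aspects(quads)

    L12 = L13 = None
    m3 = None
    if markers.m2_px is not None:
        m2 = px_to_mm(markers.m2_px, spacing)
        L12 = euclidean_mm(markers.m1_px, markers.m2_px, spacing)
        m3 = skin_crossing(m1, m2, contour)
        L13 = float(np.linalg.norm(m3 - m1))
    elif substitute_direction_mm is not None:
        d = np.asarray(substitute_direction_mm, dtype=np.float64)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise MarkerGeometryError("substitute direction must be non-zero")
        m3 = skin_crossing(m1, m1 + d / norm, contour)
        L13 = float(np.linalg.norm(m3 - m1))

    return VertebraMeasurement(
        level=markers.level,
        L12_mm=L12,
        L13_mm=L13,
        m3_mm=None if m3 is None else (float(m3[0]), float(m3[1])),
        quadrants=quads,
        aspects=aspects,
    )
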