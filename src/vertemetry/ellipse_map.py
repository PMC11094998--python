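"""Equal-area mapping of area aspects into a generalized ellipse.

A vertebra's position relative to its own body contour is summarized by
two area aspects (posterior-half and left-half fractions).  To compare
patients with different body shapes, each aspect is converted into a chord
position inside a fixed generalized ellipse such that the partial area
beyond the chord equals the aspect.  The crossing point of the two chords
is the normalized vertebral position (u, v), with +u patient-left and +v
posterior.  Because area *fractions* of an ellipse are invariant under
axis scaling, the construction is independent of the ellipse's semi-axes —
no ellipse needs to be fitted to any contour.

The area fraction beyond a chord at normalized offset t ∈ [−1, 1] is

    F(t) = 1/2 − (t·√(1−t²) + arcsin t) / π,

strictly decreasing with F(−1) = 1, F(0) = 1/2, F(1) = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .morphometry import AspectPair

__all__ = [
    "EllipsePosition",
    "ellipse_area_fraction",
    "invert_area_fraction",
    "map_to_ellipse",
    "disk_quadrant_fraction",
    "DEFAULT_TOL",
]

DEFAULT_TOL = 1e-10


@dataclass(frozen=True)
class EllipsePosition:
    """Normalized vertebral-body position inside the generalized ellipse.

    u: left–right coordinate (chord offset / semi-axis), +u = patient-left.
    v: back–front coordinate, +v = posterior.  Each lies in (−1, 1); the
    two chords are computed independently, so (u, v) is not constrained to
    the inscribed ellipse.
    """

    u: float
    v: float

    def __post_init__(self):
        if not (-1.0 < self.u < 1.0 and -1.0 < self.v < 1.0):
            raise ValueError("normalized coordinates must lie strictly in (-1, 1)")


def ellipse_area_fraction(t: float) -> float:
    """Fraction of the ellipse area with normalized coordinate ≥ t."""
    t = float(t)
    if not -1.0 <= t <= 1.0:
        raise ValueError("chord offset must satisfy |t| <= 1")
    return 0.5 - (t * math.sqrt(max(0.0, 1.0 - t * t)) + math.asin(t)) / math.pi


def invert_area_fraction(f: float, tol: float = DEFAULT_TOL) -> float:
    """The unique t with ellipse_area_fraction(t) = f, for f in (0, 1).

    F is strictly decreasing on [−1, 1], so a bracketed root finder
    (Brent) converges unconditionally; ``tol`` bounds |t − t*|.
    """
    f = float(f)
    if not 0.0 < f < 1.0:
        raise ValueError("area fraction must lie strictly in (0, 1)")
    return float(brentq(lambda t: ellipse_area_fraction(t) - f, -1.0, 1.0,
                        xtol=tol, rtol=8.9e-16))


def map_to_ellipse(aspects: AspectPair, tol: float = DEFAULT_TOL) -> EllipsePosition:
    """Map area aspects to the normalized position inside the ellipse.

    v is the horizontal chord leaving posterior fraction ``f_back`` beyond
    it; u is the vertical chord leaving patient-left fraction ``f_left``
    beyond it.  A vertebra centred in its contour (aspects 0.5, 0.5) maps
    to the ellipse centre.
    """
    return EllipsePosition(
        u=invert_area_fraction(aspects.f_left, tol),
        v=invert_area_fraction(aspects.f_back, tol),
    )


def _G(x: float) -> float:
    # antiderivative of sqrt(1 - x^2)
    return (x * math.sqrt(max(0.0, 1.0 - x * x)) + math.asin(x)) / 2.0


def disk_quadrant_fraction(u: float, v: float) -> float:
    """Closed-form unit-disk area fraction of {x ≥ u, y ≥ v}, |u|,|v| < 1.

    By affine invariance this equals the ellipse quadrant fraction for a
    point at normalized coordinates (u, v) — the analytic oracle for
    quadrant-area computations on elliptical contours.
    """
    if not (-1.0 < u < 1.0 and -1.0 < v < 1.0):
        raise ValueError("normalized coordinates must lie strictly in (-1, 1)")
    if v < 0.0:
        return ellipse_area_fraction(u) - disk_quadrant_fraction(u, -v)
    s = math.sqrt(1.0 - v * v)
    lo = max(u, -s)
    if lo >= s:
        return 0.0
    return ((_G(s) - _G(lo)) - v * (s - lo)) / math.pi
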