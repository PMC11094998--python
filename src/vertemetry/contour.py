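"""Outer body-contour extraction from an axial CT slice.

The body outline is segmented by running marching squares (with sub-pixel
linear interpolation along cell edges) at a fixed HU iso-level and keeping
the closed contour that encloses the largest area — robust against internal
bone or air contours, which are smaller by construction.  The default
iso-level of −300 HU sits midway between air (≈−1000) and soft tissue
(≈0–60), where the segmentation is insensitive to noise and to the exact
level chosen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import find_contours

from .io import VolumeSlice

__all__ = [
    "ContourPolygon",
    "ContourError",
    "NoBodyContourError",
    "BodyTruncatedError",
    "extract_body_contour",
    "select_center_slice",
    "DEFAULT_THRESHOLD_HU",
]

DEFAULT_THRESHOLD_HU = -300.0


class ContourError(ValueError):
    pass


class NoBodyContourError(ContourError):
    pass


class BodyTruncatedError(ContourError):
    pass


def _signed_area(vertices: np.ndarray) -> float:
    x = vertices[:, 0]
    y = vertices[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass(frozen=True)
class ContourPolygon:
    """Closed simple polygon in mm coordinates, stored counter-clockwise.

    Vertices are (x, y) with +x patient-left and +y posterior; the closing
    edge from the last back to the first vertex is implicit (``closed``).
    """

    vertices: np.ndarray  # (n, 2) float64, first vertex NOT repeated
    closed: bool = True

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=np.float64)
        if v.ndim != 2 or v.shape[1] != 2 or len(v) < 3:
            raise ContourError("polygon needs at least 3 two-dimensional vertices")
        object.__setattr__(self, "vertices", v)

    @classmethod
    def from_vertices(cls, vertices) -> "ContourPolygon":
        """Normalize: drop a repeated closing vertex, enforce CCW orientation."""
        v = np.asarray(vertices, dtype=np.float64)
        if len(v) >= 2 and np.allclose(v[0], v[-1]):
            v = v[:-1]
        if len(v) < 3:
            raise ContourError("polygon needs at least 3 vertices")
        if _signed_area(v) < 0:
            v = v[::-1].copy()
        return cls(v)

    @property
    def signed_area(self) -> float:
        return _signed_area(self.vertices)

    def translated(self, offset) -> "ContourPolygon":
        return ContourPolygon(self.vertices + np.asarray(offset, dtype=np.float64))

    def to_shapely(self):
        from shapely.geometry import Polygon

        return Polygon(self.vertices)


def extract_body_contour(slice_: VolumeSlice, threshold_hu: float = DEFAULT_THRESHOLD_HU
                         ) -> ContourPolygon:
    """Extract the outer body contour at the given iso-level.

    Runs marching squares on the slice, keeps closed contours only, and
    returns the one enclosing the largest area, converted to mm and
    oriented counter-clockwise.

    Raises
    ------
    NoBodyContourError
        If no closed iso-contour exists at the threshold.
    BodyTruncatedError
        If the above-threshold region touches the image border (the body
        is cut by the field of view, so its outline cannot be closed).
    """
    data = np.asarray(slice_.data, dtype=np.float64)
    mask = data >= threshold_hu
    if not mask.any():
        raise NoBodyContourError(f"no body contour at threshold {threshold_hu} HU")
    if mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any():
        raise BodyTruncatedError("body truncated by field of view")

    sr, sc = slice_.spacing_mm
    best = None
    best_area = 0.0
    for c in find_contours(data, level=threshold_hu):
        if not np.allclose(c[0], c[-1]):
            continue  # open contour (should not happen away from the border)
        xy = np.stack([c[:-1, 1] * sc, c[:-1, 0] * sr], axis=1)
        if len(xy) < 3:
            continue
        area = abs(_signed_area(xy))
        if area > best_area:
            best_area = area
            best = xy
    if best is None:
        raise NoBodyContourError(f"no body contour at threshold {threshold_hu} HU")
    return ContourPolygon.from_vertices(best)


def select_center_slice(level_annotation: dict, level: str) -> int:
    """Index of the slice closest to the vertical centre of a vertebra.

    ``level_annotation`` maps level label → (first_slice, last_slice),
    inclusive.  Ties at a half-integer midpoint break toward the smaller
    index.
    """
    if level not in level_annotation:
        raise KeyError(f"level {level!r} absent from annotation")
    first, last = level_annotation[level]
    if last < first:
        raise ValueError(f"invalid slice range for {level}: ({first}, {last})")
    return (int(first) + int(last)) // 2
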