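"""Synthetic axial CT torso phantom with analytic ground truth.

The phantom emulates the geometry the morphometry pipeline consumes: a
closed soft-tissue body contour (an ellipse, optionally with a posterior
Gaussian rib-hump bulge on the convex side), an embedded high-intensity
vertebral body with a posterior spinous process, air background, HU-valued
voxels and anisotropic pixel spacing.  Because the contour is analytic,
every downstream quantity — the marker positions, the body-centre to
spinous-tip and to-skin distances, and the quadrant area fractions — has a
ground truth computed independently of the image-processing path.

HU composition: air −1000, soft tissue +40, bone +1000.  The gap between
air and tissue is large enough that a single threshold (default −300 HU)
separates body from background even with realistic noise; noise is
truncated at ±4 sd so that separation is guaranteed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq

from .io import Volume, VolumeSlice

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "PhantomGeometryError",
    "contour_radius",
    "make_phantom",
    "make_phantom_volume",
    "grid_quadrant_fractions",
    "spec_from_dict",
]

HU_AIR = -1000.0
HU_TISSUE = 40.0
HU_BONE = 1000.0


class PhantomGeometryError(ValueError):
    """Phantom geometry is inconsistent (e.g. bone outside the body contour)."""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and imaging parameters of one axial torso slice.

    All lengths in mm, angles in radians.  The contour is r(θ) in polar
    coordinates about the ellipse centre, θ measured from +x (patient-left)
    towards +y (posterior).  ``process_angle_rad`` is the spinous-axis
    direction, 0 = straight posterior.  ``vertebra_center_mm`` is (x, y)
    relative to the ellipse centre.
    """

    semi_axis_lr_mm: float = 150.0
    semi_axis_ap_mm: float = 100.0
    hump_amplitude_mm: float = 0.0
    hump_center_rad: float = math.pi / 2
    hump_width_rad: float = 0.45
    vertebra_center_mm: tuple[float, float] = (0.0, 25.0)
    vertebra_radius_mm: float = 15.0
    process_length_mm: float = 55.0
    process_angle_rad: float = 0.0
    pixel_spacing_mm: tuple[float, float] = (0.7, 0.7)  # (row, col)
    slice_step_mm: float = 5.0
    noise_sd_hu: float = 20.0
    image_shape: tuple[int, int] = (360, 480)  # (rows, cols); AP margin fits a ~25 mm hump

    def __post_init__(self):
        if self.semi_axis_lr_mm <= 0 or self.semi_axis_ap_mm <= 0:
            raise ValueError("semi-axes must be positive")
        if self.hump_amplitude_mm < 0:
            raise ValueError("hump amplitude must be >= 0")
        if self.hump_amplitude_mm >= self.semi_axis_ap_mm:
            raise PhantomGeometryError("hump amplitude must be smaller than the AP semi-axis")
        if self.hump_width_rad <= 0:
            raise ValueError("hump width must be positive")
        if self.vertebra_radius_mm <= 0 or self.process_length_mm <= 0:
            raise ValueError("vertebra radius and process length must be positive")
        if any(s <= 0 for s in self.pixel_spacing_mm) or self.slice_step_mm <= 0:
            raise ValueError("spacings must be positive")
        if self.noise_sd_hu < 0:
            raise ValueError("noise sd must be >= 0")
        if any(int(n) <= 0 for n in self.image_shape):
            raise ValueError("image shape must be positive")


@dataclass(frozen=True)
class PhantomTruth:
    """Analytic ground truth for one phantom slice.

    All coordinates are absolute image millimetres (same frame the pipeline
    reports in); ``center_mm`` is the contour's ellipse centre.
    """

    contour_mm: np.ndarray  # (n, 2) closed polyline, (x, y) mm, CCW
    center_mm: np.ndarray
    m1_mm: np.ndarray
    m2_mm: np.ndarray
    m3_mm: np.ndarray
    L12_mm: float
    L13_mm: float
    quadrant_fractions: tuple[float, float, float, float]  # (a1..a4)/total
    aspects: tuple[float, float]  # (f_back, f_left)

    def __post_init__(self):
        if not self.L12_mm < self.L13_mm:
            raise PhantomGeometryError("truth violates L12 < L13")
        fr = np.asarray(self.quadrant_fractions)
        if not (np.all(fr > 0) and np.all(fr < 1) and abs(fr.sum() - 1.0) < 1e-9):
            raise PhantomGeometryError("quadrant fractions must be in (0,1) and sum to 1")


def contour_radius(theta, spec: PhantomSpec):
    """Analytic body-contour radius r(θ) about the ellipse centre.

    Ellipse radius for the two semi-axes plus a Gaussian bump of the given
    amplitude centred at ``hump_center_rad`` (wrapped angular distance).
    Smooth, strictly positive and 2π-periodic.
    """
    theta = np.asarray(theta, dtype=np.float64)
    a, b = spec.semi_axis_lr_mm, spec.semi_axis_ap_mm
    r_ell = a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
    d = np.arctan2(np.sin(theta - spec.hump_center_rad), np.cos(theta - spec.hump_center_rad))
    return r_ell + spec.hump_amplitude_mm * np.exp(-(d**2) / (2 * spec.hump_width_rad**2))


def _process_direction(spec: PhantomSpec) -> np.ndarray:
    # 0 rad = straight posterior (+y); positive angles rotate towards +x (patient-left)
    phi = spec.process_angle_rad
    return np.array([math.sin(phi), math.cos(phi)])


def _ray_contour_distance(origin_rel: np.ndarray, direction: np.ndarray, spec: PhantomSpec,
                          start: float = 0.0) -> float:
    """Distance along origin+s·direction (origin relative to centre) to the
    first contour crossing with s > start."""

    def g(s: float) -> float:
        p = origin_rel + s * direction
        rho = math.hypot(p[0], p[1])
        return rho - float(contour_radius(math.atan2(p[1], p[0]), spec))

    s_max = 2.0 * (max(spec.semi_axis_lr_mm, spec.semi_axis_ap_mm) + spec.hump_amplitude_mm) + \
        float(np.linalg.norm(origin_rel))
    # scan for the first sign change beyond `start`
    grid = np.linspace(start, s_max, 2048)
    vals = np.array([g(s) for s in grid])
    idx = np.nonzero((vals[:-1] < 0) & (vals[1:] >= 0))[0]
    if idx.size == 0:
        raise PhantomGeometryError("ray does not cross the contour")
    lo, hi = grid[idx[0]], grid[idx[0] + 1]
    return float(brentq(g, lo, hi, xtol=1e-12))


def _validate_geometry(spec: PhantomSpec, margin_mm: float = 2.0) -> None:
    """Reject specs whose bone (vertebra disk or process bar) is not strictly
    inside the contour."""
    c = np.asarray(spec.vertebra_center_mm, dtype=np.float64)
    d = _process_direction(spec)
    tip = c + spec.process_length_mm * d
    halfwidth = 1.25 * max(spec.pixel_spacing_mm)
    probes = []
    ang = np.linspace(0, 2 * math.pi, 360, endpoint=False)
    probes.append(c + spec.vertebra_radius_mm * np.stack([np.cos(ang), np.sin(ang)], axis=1))
    ts = np.linspace(0.0, 1.0, 64)[:, None]
    axis = c + ts * (tip - c)
    normal = np.array([d[1], -d[0]])
    probes.append(axis + halfwidth * normal)
    probes.append(axis - halfwidth * normal)
    probes.append(tip[None, :] + halfwidth * d[None, :])
    pts = np.concatenate(probes, axis=0)
    rho = np.hypot(pts[:, 0], pts[:, 1])
    r = contour_radius(np.arctan2(pts[:, 1], pts[:, 0]), spec)
    if np.any(rho >= r - margin_mm):
        raise PhantomGeometryError(
            "vertebral body / spinous process does not lie strictly inside the body contour"
        )


def _dense_contour_rel(spec: PhantomSpec, n: int) -> np.ndarray:
    theta = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    r = contour_radius(theta, spec)
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def _truth_quadrant_fractions(spec: PhantomSpec, m1_rel: np.ndarray,
                              n_vertices: int = 50_000) -> tuple[float, ...]:
    """Quadrant area fractions of the analytic contour region about m1.

    Numeric integration of the analytic contour: the region is represented
    by an inscribed polygon sampled at ``n_vertices`` points (relative area
    error ~n⁻², ≈5e−9 at the default) and clipped against the two
    axis-parallel lines through m1.  Labels: a1 anterior-right,
    a2 anterior-left, a3 posterior-left, a4 posterior-right
    (+x patient-left, +y posterior).
    """
    from shapely.geometry import Polygon, box

    verts = _dense_contour_rel(spec, n_vertices)
    poly = Polygon(verts)
    cx, cy = float(m1_rel[0]), float(m1_rel[1])
    minx, miny, maxx, maxy = poly.bounds
    minx -= 1.0
    miny -= 1.0
    maxx += 1.0
    maxy += 1.0
    a1 = poly.intersection(box(minx, miny, cx, cy)).area  # anterior-right
    a2 = poly.intersection(box(cx, miny, maxx, cy)).area  # anterior-left
    a3 = poly.intersection(box(cx, cy, maxx, maxy)).area  # posterior-left
    a4 = poly.intersection(box(minx, cy, cx, maxy)).area  # posterior-right
    total = poly.area
    return tuple(a / total for a in (a1, a2, a3, a4))


def grid_quadrant_fractions(spec: PhantomSpec, m1_rel, step_mm: float = 0.1):
    """Occupancy-grid quadrant fractions of the analytic region (oracle).

    Counts grid cells of side ``step_mm`` whose centres satisfy
    ρ < r(θ), classified by quadrant about ``m1_rel``.  Deliberately
    independent of any polygon-clipping code: used as a cross-check.
    """
    m1 = np.asarray(m1_rel, dtype=np.float64)
    rmax = float(np.max(contour_radius(np.linspace(0, 2 * math.pi, 4096), spec)))
    xs = np.arange(-rmax, rmax + step_mm, step_mm)
    counts = np.zeros(4, dtype=np.int64)
    for block in np.array_split(xs, max(1, xs.size // 256)):
        X, Y = np.meshgrid(block, xs, indexing="ij")
        rho = np.hypot(X, Y)
        inside = rho < contour_radius(np.arctan2(Y, X), spec)
        right = X <= m1[0]
        front = Y <= m1[1]
        counts[0] += np.count_nonzero(inside & right & front)
        counts[1] += np.count_nonzero(inside & ~right & front)
        counts[2] += np.count_nonzero(inside & ~right & ~front)
        counts[3] += np.count_nonzero(inside & ~front & right)
    total = counts.sum()
    return tuple(c / total for c in counts)


def _render(spec: PhantomSpec, rng: np.random.Generator, oversample: int = 4) -> np.ndarray:
    nr, nc = (int(n) for n in spec.image_shape)
    sr, sc = spec.pixel_spacing_mm
    cx = (nc - 1) / 2 * sc
    cy = (nr - 1) / 2 * sr
    ov = oversample
    # sub-pixel sample coordinates (pixel centres at integer indices)
    rows = (np.arange(nr * ov) + 0.5) / ov - 0.5
    cols = (np.arange(nc * ov) + 0.5) / ov - 0.5
    Y = rows[:, None] * sr - cy
    X = cols[None, :] * sc - cx
    rho = np.hypot(X, Y)
    theta = np.arctan2(Y, X)
    inside = rho < contour_radius(theta, spec)

    m1 = np.asarray(spec.vertebra_center_mm, dtype=np.float64)
    d = _process_direction(spec)
    tip = m1 + spec.process_length_mm * d
    dx = X - m1[0]
    dy = Y - m1[1]
    bone = dx**2 + dy**2 < spec.vertebra_radius_mm**2
    # spinous process: bar of half-width ~1.25 px along the axis m1→tip
    halfwidth = 1.25 * max(sr, sc)
    t = np.clip(dx * d[0] + dy * d[1], 0.0, spec.process_length_mm)
    px = m1[0] + t * d[0] - X
    py = m1[1] + t * d[1] - Y
    bone |= px**2 + py**2 < halfwidth**2

    cov_tissue = inside.reshape(nr, ov, nc, ov).mean(axis=(1, 3))
    cov_bone = (inside & bone).reshape(nr, ov, nc, ov).mean(axis=(1, 3))
    img = HU_AIR + (HU_TISSUE - HU_AIR) * cov_tissue + (HU_BONE - HU_TISSUE) * cov_bone
    if spec.noise_sd_hu > 0:
        noise = rng.standard_normal(img.shape)
        np.clip(noise, -4.0, 4.0, out=noise)  # keep air/body separable at threshold
        img = img + spec.noise_sd_hu * noise
    return img


def make_phantom(spec: PhantomSpec, seed: int = 0, *, truth_vertices: int = 3600,
                 oracle_vertices: int = 50_000) -> tuple[VolumeSlice, PhantomTruth]:
    """Render one phantom slice and its analytic ground truth.

    Same seed ⇒ bit-identical image and truth.  Raises
    :class:`PhantomGeometryError` if the vertebra or spinous process would
    not lie strictly inside the contour.
    """
    _validate_geometry(spec)
    rng = np.random.default_rng(seed)
    img = _render(spec, rng)
    nr, nc = (int(n) for n in spec.image_shape)
    sr, sc = spec.pixel_spacing_mm
    center = np.array([(nc - 1) / 2 * sc, (nr - 1) / 2 * sr])

    m1_rel = np.asarray(spec.vertebra_center_mm, dtype=np.float64)
    d = _process_direction(spec)
    m2_rel = m1_rel + spec.process_length_mm * d
    s3 = _ray_contour_distance(m1_rel, d, spec, start=0.0)
    m3_rel = m1_rel + s3 * d
    L12 = float(np.linalg.norm(m2_rel - m1_rel))
    L13 = float(np.linalg.norm(m3_rel - m1_rel))

    fractions = _truth_quadrant_fractions(spec, m1_rel, oracle_vertices)
    f_back = fractions[2] + fractions[3]
    f_left = fractions[1] + fractions[2]
    truth = PhantomTruth(
        contour_mm=_dense_contour_rel(spec, truth_vertices) + center,
        center_mm=center,
        m1_mm=m1_rel + center,
        m2_mm=m2_rel + center,
        m3_mm=m3_rel + center,
        L12_mm=L12,
        L13_mm=L13,
        quadrant_fractions=fractions,
        aspects=(f_back, f_left),
    )
    return VolumeSlice(img, (sr, sc)), truth


def make_phantom_volume(specs: list[PhantomSpec], seed: int = 0,
                        **kwargs) -> tuple[Volume, list[PhantomTruth]]:
    """Stack per-slice phantoms into a volume (slices are independent specs)."""
    if not specs:
        raise ValueError("need at least one slice spec")
    slices, truths = [], []
    for i, spec in enumerate(specs):
        sub = int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31))
        sl, tr = make_phantom(spec, seed=sub, **kwargs)
        slices.append(sl.data)
        truths.append(tr)
    first = specs[0]
    vol = Volume(np.stack(slices), (first.slice_step_mm, *first.pixel_spacing_mm))
    return vol, truths


def spec_from_dict(doc: dict) -> PhantomSpec:
    """Build a spec from a plain mapping (e.g. parsed YAML)."""
    kwargs = dict(doc)
    for key in ("vertebra_center_mm", "pixel_spacing_mm", "image_shape"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return PhantomSpec(**kwargs)


def truth_to_dict(truth: PhantomTruth) -> dict:
    """JSON-serializable view of the ground truth (contour down-sampled)."""
    return {
        "center_mm": truth.center_mm.tolist(),
        "m1_mm": truth.m1_mm.tolist(),
        "m2_mm": truth.m2_mm.tolist(),
        "m3_mm": truth.m3_mm.tolist(),
        "L12_mm": truth.L12_mm,
        "L13_mm": truth.L13_mm,
        "quadrant_fractions": list(truth.quadrant_fractions),
        "aspects": {"f_back": truth.aspects[0], "f_left": truth.aspects[1]},
        "contour_mm": truth.contour_mm[:: max(1, len(truth.contour_mm) // 720)].tolist(),
    }
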