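import math

import numpy as np
import pytest

from vertemetry.contour import ContourPolygon
from vertemetry.cohort import PatientRecord
from vertemetry.morphometry import (
    VERTEBRAL_LEVELS,
    AspectPair,
    QuadrantAreas,
    VertebraMeasurement,
)
from vertemetry.phantom import PhantomSpec


def ellipse_contour(a, b, n=3600, center=(0.0, 0.0)) -> ContourPolygon:
    """Digitized exact ellipse, CCW, used as an analytic reference contour."""
    th = np.linspace(0.0, 2 * math.pi, n, endpoint=False)
    v = np.stack([center[0] + a * np.cos(th), center[1] + b * np.sin(th)], axis=1)
    return ContourPolygon.from_vertices(v)


def circle_spec(**overrides) -> PhantomSpec:
    """Circular torso phantom with the vertebra at the centre (full symmetry)."""
    kwargs = dict(
        semi_axis_lr_mm=100.0,
        semi_axis_ap_mm=100.0,
        hump_amplitude_mm=0.0,
        vertebra_center_mm=(0.0, 0.0),
        process_length_mm=60.0,
        pixel_spacing_mm=(1.0, 1.0),
        noise_sd_hu=0.0,
        image_shape=(256, 256),
    )
    kwargs.update(overrides)
    return PhantomSpec(**kwargs)


def star_polygon(rng, n=None, r_lo=0.5, r_hi=2.0) -> np.ndarray:
    """Random simple polygon, star-shaped about the origin."""
    n = n or int(rng.integers(5, 40))
    # jittered regular angles: gaps stay below pi, so the origin is interior
    th = 2 * math.pi * (np.arange(n) + rng.uniform(0.05, 0.95, n)) / n
    r = rng.uniform(r_lo, r_hi, n)
    return np.stack([r * np.cos(th), r * np.sin(th)], axis=1)


def convex_polygon(rng, n=None) -> np.ndarray:
    from scipy.spatial import ConvexHull

    pts = rng.normal(size=(n or int(rng.integers(6, 30)), 2))
    hull = ConvexHull(pts)
    return pts[hull.vertices]


def make_measurement(level, L12, L13, fractions=(0.25, 0.25, 0.25, 0.25), total=1000.0):
    a1, a2, a3, a4 = (f * total for f in fractions)
    q = QuadrantAreas(a1, a2, a3, a4, total)
    return VertebraMeasurement(
        level=level,
        L12_mm=L12,
        L13_mm=L13,
        m3_mm=None,
        quadrants=q,
        aspects=AspectPair((a3 + a4) / total, (a2 + a3) / total),
    )


def random_cohort(rng, n_patients=None):
    """Random synthetic cohort of patient records for aggregation tests."""
    n_patients = n_patients or int(rng.integers(2, 8))
    genders = ["female", "male"]
    records = []
    for i in range(n_patients):
        levels = rng.choice(len(VERTEBRAL_LEVELS),
                            size=int(rng.integers(3, len(VERTEBRAL_LEVELS))), replace=False)
        ms = []
        for li in sorted(levels):
            L13 = float(rng.uniform(60, 100))
            L12 = None if rng.random() < 0.2 else float(rng.uniform(45, L13 - 1))
            ms.append(make_measurement(VERTEBRAL_LEVELS[li], L12, L13))
        n_curves = int(rng.integers(1, 3))
        curves = tuple(
            (float(rng.uniform(5, 60)), VERTEBRAL_LEVELS[int(rng.integers(2, 18))])
            for _ in range(n_curves)
        )
        records.append(PatientRecord(f"P{i:02d}", genders[int(rng.integers(0, 2))],
                                     curves, tuple(ms)))
    return records


@pytest.fixture(scope="session")
def default_phantom():
    from vertemetry.phantom import make_phantom

    spec = PhantomSpec()
    return spec, *make_phantom(spec, seed=11)
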