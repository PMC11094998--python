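"""Image containers and file readers/writers.

Coordinate convention used across the package (supine LPS orientation):
axial slice arrays are indexed ``(row, col)``, 0-based; ``+col`` points to
the patient's left and ``+row`` posterior.  Millimetre coordinates are
``(x, y) = (col * col_spacing, row * row_spacing)``, i.e. pixel centres sit
at integer indices.  NIfTI volumes are written with the affine
``diag(col_spacing, row_spacing, slice_step, 1)`` and the data transposed
to ``(col, row, slice)`` so that a round trip restores the in-memory
layout exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "VolumeSlice",
    "Volume",
    "read_nifti",
    "write_nifti",
    "read_dicom_series",
    "read_markers",
    "write_markers",
    "read_cohort_csv",
]


@dataclass(frozen=True)
class VolumeSlice:
    """One axial CT image: HU intensities plus per-axis pixel spacing.

    Parameters
    ----------
    data
        2-D array of intensities in Hounsfield units, indexed (row, col).
    spacing_mm
        (row_spacing, col_spacing) in millimetres, both positive.
    """

    data: np.ndarray
    spacing_mm: tuple[float, float]

    def __post_init__(self):
        d = np.asarray(self.data)
        if d.ndim != 2:
            raise ValueError("slice data must be 2-D")
        sr, sc = self.spacing_mm
        if sr <= 0 or sc <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class Volume:
    """Axial CT stack: data indexed (slice, row, col)."""

    data: np.ndarray
    spacing_mm: tuple[float, float, float]  # (slice_step, row, col)

    def __post_init__(self):
        if np.asarray(self.data).ndim != 3:
            raise ValueError("volume data must be 3-D")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacings must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    def get_slice(self, index: int) -> VolumeSlice:
        if not 0 <= index < self.n_slices:
            raise IndexError(f"slice index {index} outside volume (0..{self.n_slices - 1})")
        return VolumeSlice(self.data[index], self.spacing_mm[1:])


def write_nifti(volume: Volume, path: str | Path) -> None:
    import nibabel as nib

    ss, sr, sc = volume.spacing_mm
    affine = np.diag([sc, sr, ss, 1.0])
    arr = np.ascontiguousarray(np.asarray(volume.data, dtype=np.float32).T)
    nib.Nifti1Image(arr, affine).to_filename(str(path))


def read_nifti(path: str | Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    arr = np.asarray(img.dataobj, dtype=np.float64).T
    zooms = img.header.get_zooms()[:3]  # (col, row, slice)
    return Volume(arr, (float(zooms[2]), float(zooms[1]), float(zooms[0])))


def read_dicom_series(directory: str | Path) -> Volume:
    """Read an axial DICOM series, ordered by ImagePositionPatient along z.

    Slice order follows the position along the slice normal, not the file
    names.  Pixel values are rescaled to HU with RescaleSlope/Intercept.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(
        p for p in Path(directory).iterdir() if p.is_file()
    )
    if not files:
        raise FileNotFoundError(f"no DICOM files in {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    first = datasets[0]
    sr, sc = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        zs = [float(ds.ImagePositionPatient[2]) for ds in datasets]
        step = float(np.median(np.diff(zs)))
    else:
        step = float(getattr(first, "SliceThickness", 1.0) or 1.0)
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float64) * slope + intercept)
    return Volume(np.stack(slices), (abs(step), sr, sc))


def read_markers(path: str | Path) -> dict:
    """Read a marker annotation file.

    Format::

        {"patient": "P01",
         "vertebrae": [{"level": "T7", "slice": 12,
                        "m1_px": [row, col], "m2_px": [row, col] | null}]}

    Slice indices are 0-based; pixel positions are (row, col).
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "vertebrae" not in doc:
        raise ValueError("markers file missing 'vertebrae' list")
    for entry in doc["vertebrae"]:
        for key in ("level", "slice", "m1_px"):
            if key not in entry:
                raise ValueError(f"marker entry missing '{key}': {entry}")
    return doc


def write_markers(doc: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_cohort_csv(path: str | Path):
    """Read cohort metadata: patient_id, gender, curves "angle@apex;angle@apex"."""
    import pandas as pd

    df = pd.read_csv(path, dtype={"patient_id": str}, comment="#")
    required = {"patient_id", "gender", "curves"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns {sorted(missing)}")
    records = []
    for _, row in df.iterrows():
        curves = []
        for token in str(row["curves"]).split(";"):
            token = token.strip()
            if not token:
                continue
            angle, apex = token.split("@")
            curves.append((float(angle), apex.strip()))
        records.append(
            {"patient_id": row["patient_id"], "gender": str(row["gender"]), "curves": curves}
        )
    return records
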