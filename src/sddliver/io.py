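"""Readers and writers: image volumes, masks, contours, reports.

Accepted inputs: a directory of PNG/TIFF grayscale slices (sorted
lexicographically), a directory of single-slice DICOM files (sorted by
slice position), or a NIfTI volume (axial iteration along the last
axis).  Physical spacings default to 1.0 mm with a warning when the
source carries none.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np
import pandas as pd
import pydicom

log = logging.getLogger("sddliver")

__all__ = [
    "VolumeData",
    "read_volume",
    "write_masks",
    "read_mask",
    "write_contours",
    "read_contours",
    "write_report",
    "validate_report",
    "REPORT_SCHEMA",
]


@dataclass
class VolumeData:
    """Ordered grayscale slices with physical spacings (mm)."""

    slices: list[np.ndarray]
    pixel_spacing: float = 1.0
    slice_spacing: float = 1.0
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {s.shape for s in self.slices}
        if len(shapes) > 1:
            raise ValueError(f"inconsistent slice shapes: {sorted(shapes)}")


_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}


def read_volume(path: str | Path) -> VolumeData:
    """Read a slice stack from a directory (PNG/TIFF/DICOM) or NIfTI file."""
    path = Path(path)
    if path.is_file() and (path.suffix == ".nii" or path.name.endswith(".nii.gz")):
        return _read_nifti(path)
    if not path.is_dir():
        raise FileNotFoundError(f"no such volume: {path}")
    files = sorted(p for p in path.iterdir() if p.is_file())
    dicoms = [p for p in files if p.suffix.lower() in {".dcm", ".ima"}]
    if dicoms:
        return _read_dicom_series(dicoms)
    images = [p for p in files if p.suffix.lower() in _IMAGE_SUFFIXES]
    if not images:
        raise ValueError(f"no readable slices in {path}")
    slices = [np.asarray(iio.imread(p)) for p in images]
    slices = [s[..., 0] if s.ndim == 3 else s for s in slices]
    warn = "no spacing metadata in image directory; assuming 1.0 mm"
    log.warning(warn)
    return VolumeData(slices=slices, warnings=[warn])


def _read_dicom_series(files: list[Path]) -> VolumeData:
    datasets = [pydicom.dcmread(str(p)) for p in files]

    def sort_key(ds):
        ipp = getattr(ds, "ImagePositionPatient", None)
        if ipp is not None:
            return float(ipp[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slices = [ds.pixel_array.astype(np.int32) for ds in datasets]
    warnings = []
    ps = getattr(datasets[0], "PixelSpacing", None)
    pixel_spacing = float(ps[0]) if ps is not None else 1.0
    if ps is None:
        warnings.append("DICOM PixelSpacing absent; assuming 1.0 mm")
    if len(datasets) > 1 and hasattr(datasets[0], "ImagePositionPatient"):
        z = [float(ds.ImagePositionPatient[2]) for ds in datasets]
        slice_spacing = float(np.median(np.diff(z)))
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    for w in warnings:
        log.warning(w)
    return VolumeData(
        slices=slices,
        pixel_spacing=pixel_spacing,
        slice_spacing=abs(slice_spacing) or 1.0,
        warnings=warnings,
    )


def _read_nifti(path: Path) -> VolumeData:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError("NIfTI volume must be 3D")
    zooms = img.header.get_zooms()[:3]
    slices = [np.asarray(data[:, :, k]) for k in range(data.shape[2])]
    return VolumeData(
        slices=slices, pixel_spacing=float(zooms[0]), slice_spacing=float(zooms[2])
    )


def write_masks(masks: list[np.ndarray | None], out_dir: str | Path, prefix: str = "mask") -> list[Path]:
    """Write binary masks as 0/255 PNGs; ``None`` entries (failed slices) are skipped."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, m in enumerate(masks):
        if m is None:
            continue
        p = out_dir / f"{prefix}_{i:04d}.png"
        iio.imwrite(p, (np.asarray(m).astype(np.uint8) * 255))
        written.append(p)
    return written


def write_masks_nifti(
    masks: list[np.ndarray | None],
    path: str | Path,
    pixel_spacing: float = 1.0,
    slice_spacing: float = 1.0,
) -> Path:
    """Write the mask stack as one uint8 NIfTI label volume (failed slices 0)."""
    shapes = {m.shape for m in masks if m is not None}
    if len(shapes) != 1:
        raise ValueError("need at least one mask and consistent shapes")
    shape = shapes.pop()
    vol = np.zeros((*shape, len(masks)), dtype=np.uint8)
    for i, m in enumerate(masks):
        if m is not None:
            vol[:, :, i] = np.asarray(m).astype(np.uint8)
    affine = np.diag([pixel_spacing, pixel_spacing, slice_spacing, 1.0])
    path = Path(path)
    nib.save(nib.Nifti1Image(vol, affine), str(path))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    arr = np.asarray(iio.imread(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127


def write_contours(contours: dict[int, np.ndarray], path: str | Path) -> Path:
    """Contours as CSV rows (slice_index, vertex_index, row, col)."""
    rows = []
    for slice_index in sorted(contours):
        v = np.asarray(contours[slice_index])
        for j, (r, c) in enumerate(v):
            rows.append((slice_index, j, r, c))
    df = pd.DataFrame(rows, columns=["slice_index", "vertex_index", "row", "col"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_contours(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(Path(path))
    out: dict[int, np.ndarray] = {}
    for idx, grp in df.groupby("slice_index"):
        grp = grp.sort_values("vertex_index")
        out[int(idx)] = grp[["row", "col"]].to_numpy(dtype=np.float64)
    return out


#: minimal schema for evaluation / run reports: key -> required type
REPORT_SCHEMA: dict[str, type] = {
    "n_slices": int,
    "n_failed": int,
    "per_slice": list,
    "summary": dict,
}


def validate_report(report: dict) -> None:
    """Check the report layout against :data:`REPORT_SCHEMA`."""
    for key, typ in REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")


def write_report(report: dict, path: str | Path) -> Path:
    validate_report(report)
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return path
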