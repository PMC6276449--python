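"""Anatomical constraint masks for liver segmentation.

Three constraints restrict the liver threshold T4, which by itself also
admits tissues of liver-like intensity:

* ``curve`` — a quadratic ``col = f(row)`` fitted through the centroids of
  the rib blobs (left flank) and the spine blob; the half of the frame on
  the rib side of the curve is excluded.
* ``ring`` — the body margin: the filtered body minus the body eroded by
  the average rib width ``N_c``; strips away the abdominal wall hugging
  the liver.
* ``stomach`` — the adjacent organ segmented at T3, MRF-denoised, bones
  subtracted, morphologically filtered, restricted to components on the
  spine's organ side, and merged into one blob.

Any constraint may legitimately come out empty (e.g. no adjacent organ in
this slice); an empty mask simply deactivates its term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .morphology import erode, morphological_filter, morphological_merge
from .mrf import GibbsModel, minimize_energy
from .sdd import binarize

__all__ = [
    "Blob",
    "QuadraticCurve",
    "ConstraintMasks",
    "segment_bones",
    "classify_bone_blobs",
    "fit_rib_curve",
    "curve_exclusion_mask",
    "segment_body",
    "estimate_rib_width",
    "ring_constraint",
    "segment_stomach",
]


@dataclass(frozen=True)
class Blob:
    """Connected component summary: area and centroid = mean pixel coordinate."""

    label: int
    area: int
    centroid: tuple[float, float]  # (row, col)


@dataclass(frozen=True)
class QuadraticCurve:
    """Second-order curve ``col = c2*row^2 + c1*row + c0``."""

    c2: float
    c1: float
    c0: float

    def __call__(self, rows: np.ndarray) -> np.ndarray:
        r = np.asarray(rows, dtype=np.float64)
        return self.c2 * r**2 + self.c1 * r + self.c0


@dataclass(frozen=True)
class ConstraintMasks:
    """The three binary constraints entering the liver rule."""

    curve_excluded: np.ndarray
    ring: np.ndarray
    stomach: np.ndarray

    @classmethod
    def none(cls, shape: tuple[int, int]) -> "ConstraintMasks":
        z = np.zeros(shape, dtype=bool)
        return cls(z, z.copy(), z.copy())


def segment_bones(image: np.ndarray, t1: int) -> np.ndarray:
    """Spine and ribs: plain binarisation at the bone threshold T1."""
    return binarize(image, t1)


def _blobs(mask: np.ndarray, min_area: int = 1) -> list[Blob]:
    labels = measure.label(mask, connectivity=2)
    out = []
    for rp in measure.regionprops(labels):
        if rp.area >= min_area:
            out.append(Blob(label=rp.label, area=int(rp.area), centroid=tuple(rp.centroid)))
    return out


def classify_bone_blobs(
    bones: np.ndarray,
    split_col: float | None = None,
    min_area: int = 1,
    central_tolerance: float = 0.05,
) -> tuple[list[Blob], Blob, np.ndarray]:
    """Split bone blobs into flank ribs and the central spine.

    Blobs with centroid column below ``split_col`` (default: the centroid
    column of all bone pixels) form the rib class; blobs on the right *and
    around the centre* — within ``central_tolerance`` of the image width
    left of the split — are spine candidates, of which the largest is the
    spine (the spine straddles the midline, so a strict half-split would
    misfile it whenever the reference centroid drifts a pixel).  Returns
    ``(ribs, spine, labels)`` where ``labels`` is the component image.
    """
    m = np.asarray(bones).astype(bool)
    labels = measure.label(m, connectivity=2)
    blobs = _blobs(m, min_area=min_area)
    if len(blobs) < 2:
        raise ValueError("insufficient bone blobs")
    if split_col is None:
        split_col = float(np.nonzero(m)[1].mean())
    band = central_tolerance * m.shape[1]
    ribs = [b for b in blobs if b.centroid[1] < split_col - band]
    central = [b for b in blobs if b.centroid[1] >= split_col - band]
    if not central:
        raise ValueError("insufficient bone blobs: no central (spine) candidate")
    if not ribs:
        raise ValueError("insufficient bone blobs: no flank (rib) candidates")
    spine = max(central, key=lambda b: b.area)
    return ribs, spine, labels


def fit_rib_curve(centroids: np.ndarray) -> QuadraticCurve:
    """Least-squares quadratic ``col = f(row)`` through rib + spine centroids."""
    pts = np.asarray(centroids, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (row, col) centroids")
    if np.unique(pts[:, 0]).size < 3:
        raise ValueError("need >= 3 distinct centroid rows")
    c2, c1, c0 = np.polyfit(pts[:, 0], pts[:, 1], 2)
    return QuadraticCurve(float(c2), float(c1), float(c0))


def curve_exclusion_mask(
    curve: QuadraticCurve,
    shape: tuple[int, int],
    interior_point: tuple[float, float],
) -> np.ndarray:
    """Mask of the half-frame on the far side of the curve from ``interior_point``.

    A pixel is excluded when ``col - f(row)`` has the opposite sign to the
    interior reference (pixels exactly on the curve count as interior).
    The liver side is the one containing the reference point, normally the
    body centroid.
    """
    u, v = shape
    rows = np.arange(u, dtype=np.float64)
    f = curve(rows)
    side = np.arange(v, dtype=np.float64)[None, :] - f[:, None]
    ref = float(interior_point[1] - curve(np.array([interior_point[0]]))[0])
    sign = 1.0 if ref >= 0 else -1.0
    return side * sign < 0


def segment_body(
    image: np.ndarray, t2: int, n_f: int = 8, model: GibbsModel = GibbsModel()
) -> np.ndarray:
    """Whole-body mask: binarise at T2, denoise, filter, fill interior holes.

    The body must come out *solid*: the ring constraint is its margin band,
    and any interior noise hole would grow into a spurious ring deep inside
    the body once the erosion by N_c passes over it.  MRF denoising removes
    isolated noise labels and the topological fill closes what remains.
    """
    m = minimize_energy(binarize(image, t2), model)
    m = morphological_filter(m, n_f)
    return ndimage.binary_fill_holes(m)


def estimate_rib_width(bones: np.ndarray, ribs: list[Blob], labels: np.ndarray) -> int:
    """Average rib width ``N_c``.

    A blob's width is twice the maximal Euclidean distance from any of its
    pixels to the background — the diameter of the largest inscribed disk,
    which for a stroke is its perpendicular thickness regardless of
    orientation.  ``N_c`` is the rounded mean over the rib blobs.
    """
    if not ribs:
        raise ValueError("need at least one rib blob")
    m = np.asarray(bones).astype(bool)
    dt = ndimage.distance_transform_edt(m)
    widths = []
    for b in ribs:
        widths.append(2.0 * float(dt[labels == b.label].max()))
    return int(round(float(np.mean(widths))))


def ring_constraint(body: np.ndarray, n_c: int) -> np.ndarray:
    """Body-margin ring: ``body AND NOT erode(body, n_c)``."""
    if n_c < 0:
        raise ValueError("n_c must be >= 0")
    b = np.asarray(body).astype(bool)
    if n_c == 0:
        return np.zeros_like(b)
    return b & ~erode(b, iterations=n_c)


def segment_stomach(
    image: np.ndarray,
    t3: int,
    bones: np.ndarray,
    spine_col: float,
    model: GibbsModel = GibbsModel(),
    n_f: int = 8,
    n_m: int = 16,
) -> np.ndarray:
    """Adjacent-organ constraint mask (stomach in the canonical case).

    Binarise at T3 -> MRF denoise -> subtract bones -> morphological
    filter -> keep components whose centroid column lies beyond the spine
    centroid column (the organ side) -> morphological merge.  An empty
    result at any stage yields the all-zero mask (constraint inactive).
    """
    m = binarize(image, t3)
    if not m.any():
        return np.zeros_like(m)
    m = minimize_energy(m, model)
    m = m & ~np.asarray(bones).astype(bool)
    m = morphological_filter(m, n_f)
    if not m.any():
        return np.zeros_like(m)
    labels = measure.label(m, connectivity=2)
    keep = np.zeros_like(m)
    for rp in measure.regionprops(labels):
        if rp.centroid[1] > spine_col:
            keep |= labels == rp.label
    if not keep.any():
        return np.zeros_like(m)
    return morphological_merge(keep, n_m)
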