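"""Segmentation evaluation: overlap and symmetric surface-distance measures.

Standard liver-challenge definitions are used.  With prediction A and
ground truth B:

* VOE  = 100 * (1 - |A∩B| / |A∪B|)                [%]
* RVD  = 100 * (|A| - |B|) / |B|                  [%]
* Dice = 2|A∩B| / (|A| + |B|)
* ASD / RMSD / MSSD = mean / root-mean-square / maximum of the pooled
  distances from each mask's border voxels to the other mask's border
  voxels, in millimetres under the given physical spacings.

Border voxels are foreground voxels with at least one background
neighbour (mask minus its erosion, background outside the frame), in 2D
or 3D alike.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["MetricsReport", "dice", "volume_metrics", "surface_metrics", "evaluate_masks"]


@dataclass(frozen=True)
class MetricsReport:
    voe_percent: float
    rvd_percent: float
    asd_mm: float
    rmsd_mm: float
    mssd_mm: float
    dice: float

    def as_dict(self) -> dict[str, float]:
        return {
            "voe_percent": self.voe_percent,
            "rvd_percent": self.rvd_percent,
            "asd_mm": self.asd_mm,
            "rmsd_mm": self.rmsd_mm,
            "mssd_mm": self.mssd_mm,
            "dice": self.dice,
        }


def _pair(pred, truth):
    a = np.asarray(pred).astype(bool)
    b = np.asarray(truth).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    return a, b


def dice(pred: np.ndarray, truth: np.ndarray) -> float:
    a, b = _pair(pred, truth)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * float((a & b).sum()) / denom


def volume_metrics(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(VOE %, RVD %); requires a non-empty ground truth."""
    a, b = _pair(pred, truth)
    nb = int(b.sum())
    if nb == 0:
        raise ValueError("empty ground-truth mask")
    inter = int((a & b).sum())
    union = int((a | b).sum())
    voe = 100.0 * (1.0 - inter / union)
    rvd = 100.0 * (int(a.sum()) - nb) / nb
    return voe, rvd


def _border(mask: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return mask & ~eroded


def surface_metrics(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing: tuple[float, ...] | float = 1.0,
) -> tuple[float, float, float]:
    """(ASD, RMSD, MSSD) in mm between the border voxels of two masks."""
    a, b = _pair(pred, truth)
    if not a.any() or not b.any():
        raise ValueError("surface metrics need two non-empty masks")
    if np.isscalar(spacing):
        spacing = (float(spacing),) * a.ndim
    ba, bb = _border(a), _border(b)
    dt_b = ndimage.distance_transform_edt(~bb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~ba, sampling=spacing)
    d = np.concatenate([dt_b[ba], dt_a[bb]])
    return float(d.mean()), float(np.sqrt((d**2).mean())), float(d.max())


def evaluate_masks(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing: tuple[float, ...] | float = 1.0,
) -> MetricsReport:
    """Full report of the five standard measures plus Dice."""
    voe, rvd = volume_metrics(pred, truth)
    asd, rmsd, mssd = surface_metrics(pred, truth, spacing)
    return MetricsReport(
        voe_percent=voe,
        rvd_percent=rvd,
        asd_mm=asd,
        rmsd_mm=rmsd,
        mssd_mm=mssd,
        dice=dice(pred, truth),
    )
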