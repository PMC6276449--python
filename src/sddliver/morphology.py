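"""Binary morphology: repeated-erosion/dilation filtering and merging.

The structuring element is the 4-connected radius-1 "disk" (the 5-pixel
plus/diamond).  ``n`` repeated erosions (or dilations) with it compose to
a single erosion (dilation) by the radius-``n`` diamond, i.e. the L1 ball
— not a Euclidean disk.  The morphological *filter* (N_F erosions then
N_F dilations, an opening) removes every blob whose maximal inscribed
diamond radius is below N_F, including blobs attached to larger ones; the
*merge* (N_M dilations then N_M erosions, a closing) unites parts of one
organ that thresholding split across a small gap.

Pixels outside the image are background for both erosion and dilation;
the merge pads the frame first so that closing remains extensive
(never removes original foreground) even at the image border.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "PLUS",
    "diamond",
    "erode",
    "dilate",
    "morphological_filter",
    "morphological_merge",
    "keep_largest_component",
]

#: radius-1 4-connected structuring element (5-pixel plus shape)
PLUS = ndimage.generate_binary_structure(2, 1)


def diamond(radius: int) -> np.ndarray:
    """Radius-``radius`` diamond (L1 ball) structuring element."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if radius == 0:
        return np.ones((1, 1), dtype=bool)
    r = np.abs(np.arange(-radius, radius + 1))
    return (r[:, None] + r[None, :]) <= radius


def _check(mask: np.ndarray) -> np.ndarray:
    m = np.asarray(mask)
    if m.ndim != 2:
        raise ValueError("mask must be 2D")
    return m.astype(bool)


def erode(mask: np.ndarray, se: np.ndarray = PLUS, iterations: int = 1) -> np.ndarray:
    """Binary erosion ``{z | B_z ⊆ mask}`` with background outside the frame."""
    m = _check(mask)
    if iterations == 0:
        return m.copy()
    return ndimage.binary_erosion(m, structure=se, iterations=iterations, border_value=0)


def dilate(mask: np.ndarray, se: np.ndarray = PLUS, iterations: int = 1) -> np.ndarray:
    """Binary dilation ``{z | B^s_z ∩ mask ≠ ∅}``."""
    m = _check(mask)
    if iterations == 0:
        return m.copy()
    return ndimage.binary_dilation(m, structure=se, iterations=iterations, border_value=0)


def morphological_filter(mask: np.ndarray, n_f: int = 8) -> np.ndarray:
    """``n_f`` erosions then ``n_f`` dilations (opening by the radius-``n_f`` diamond)."""
    if n_f < 0:
        raise ValueError("n_f must be >= 0")
    m = _check(mask)
    if n_f == 0:
        return m.copy()
    return dilate(erode(m, PLUS, n_f), PLUS, n_f)


def morphological_merge(mask: np.ndarray, n_m: int = 16) -> np.ndarray:
    """``n_m`` dilations then ``n_m`` erosions (closing by the radius-``n_m`` diamond).

    The frame is zero-padded by ``n_m + 1`` first, so foreground near the
    image border is treated exactly as it would be on an unbounded canvas
    and the closing never removes original foreground.
    """
    if n_m < 0:
        raise ValueError("n_m must be >= 0")
    m = _check(mask)
    if n_m == 0:
        return m.copy()
    pad = n_m + 1
    padded = np.pad(m, pad)
    closed = erode(dilate(padded, PLUS, n_m), PLUS, n_m)
    return closed[pad:-pad, pad:-pad]


def keep_largest_component(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Keep only the largest 8-connected component (area ties: first in raster order)."""
    m = _check(mask)
    labels = measure.label(m, connectivity=connectivity)
    n = labels.max()
    if n == 0:
        raise ValueError("no component")
    areas = np.bincount(labels.ravel())[1:]
    best = 1 + int(np.argmax(areas))  # lowest label = earliest raster-order seed
    return labels == best
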