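"""Slope-difference-distribution (SDD) multilevel thresholding.

The per-slice segmentation is driven entirely by thresholds found on the
intensity histogram.  The histogram (intensities rescaled to {1,...,255},
bin heights normalised by the *maximum* bin count) is band-limited with a
low-pass DFT filter of bandwidth ``W``.  At every interior intensity ``i``
two lines are fitted by ordinary least squares: one through the ``N``
points ending at ``i`` (left window) and one through the ``N`` points
starting at ``i`` (right window).  The slope difference

    s(i) = a_right(i) - a_left(i),   i = 1+N, ..., 255-N

peaks where the histogram turns upward fastest.  A valley of the
histogram — the dip between two pixel classes — has a falling left arm
and a rising right arm, so it shows up as a *positive local maximum* of
``s``; those positions are the class-separating thresholds.  Four roles are
assigned by rank order: T2 (body/background, lowest), T1 (bones, highest),
T4 (liver) and T3 (adjacent organ) among the interior valleys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "SddParams",
    "SlopeDifference",
    "ThresholdSet",
    "InsufficientClassesError",
    "rescale_intensities",
    "compute_histogram",
    "smooth_histogram",
    "fit_line_slope",
    "slope_difference",
    "find_thresholds",
    "assign_threshold_roles",
    "binarize",
    "calibrate_params",
]

N_BINS = 255  # intensities live on {1, ..., 255}

# positivity floor for slope-difference extrema: histograms are
# max-normalised (O(1) heights), so anything at float-noise scale is flat
_S_EPS = 1e-10


class InsufficientClassesError(ValueError):
    """Raised when too few histogram valleys exist to assign threshold roles."""


@dataclass(frozen=True)
class SddParams:
    """Calibratable parameters of the threshold detector.

    bandwidth_w
        Number of low positive DFT frequencies kept (plus their conjugate
        mirror and the DC bin) when smoothing the histogram.
    window_n
        Number of histogram samples in each one-sided line fit.
    valley_merge_distance
        Valleys closer than this many intensity levels are merged
        (the deeper one is kept) to suppress band-limiting ripple.
    """

    bandwidth_w: int = 12
    window_n: int = 20
    valley_merge_distance: int = 8
    mode_min_height: float = 0.02

    def __post_init__(self) -> None:
        if not 1 <= self.bandwidth_w <= 127:
            raise ValueError(f"bandwidth_w must be in [1, 127], got {self.bandwidth_w}")
        if not 2 <= self.window_n <= 100:
            raise ValueError(f"window_n must be in [2, 100], got {self.window_n}")
        if self.valley_merge_distance < 0:
            raise ValueError("valley_merge_distance must be >= 0")
        if not 0.0 <= self.mode_min_height < 1.0:
            raise ValueError("mode_min_height must be in [0, 1)")


@dataclass(frozen=True)
class SlopeDifference:
    """Slope-difference signal defined on intensities ``1+N ... 255-N``."""

    values: np.ndarray
    window_n: int

    @property
    def first_intensity(self) -> int:
        return 1 + self.window_n

    @property
    def last_intensity(self) -> int:
        return N_BINS - self.window_n

    def intensities(self) -> np.ndarray:
        return np.arange(self.first_intensity, self.last_intensity + 1)


@dataclass(frozen=True)
class ThresholdSet:
    """Ascending valley positions with optional anatomical roles.

    Roles: ``T1`` bones (spine/ribs), ``T2`` whole body, ``T3`` adjacent
    organ (stomach/kidney/heart), ``T4`` liver.
    """

    thresholds: tuple[int, ...]
    roles: dict[str, int] | None = field(default=None)

    def __post_init__(self) -> None:
        ts = self.thresholds
        if any(ts[i] >= ts[i + 1] for i in range(len(ts) - 1)):
            raise ValueError("thresholds must be strictly ascending")
        if any(not 1 < t < N_BINS for t in ts):
            raise ValueError("thresholds must lie strictly inside (1, 255)")

    def __len__(self) -> int:
        return len(self.thresholds)

    def role(self, name: str) -> int:
        if self.roles is None:
            raise ValueError("threshold roles have not been assigned")
        return self.roles[name]


def rescale_intensities(image: np.ndarray) -> np.ndarray:
    """Affinely rescale an intensity raster to the interval {1, ..., 255}.

    ``round(1 + 254 * (v - min) / (max - min))`` per pixel.  A constant
    image (degenerate range) maps every pixel to 255; callers should treat
    such a slice as unsegmentable.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.size == 0:
        raise ValueError("cannot rescale an empty image")
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.full(img.shape, 255, dtype=np.int32)
    out = np.rint(1.0 + 254.0 * (img - lo) / (hi - lo)).astype(np.int32)
    return out


def compute_histogram(image: np.ndarray) -> np.ndarray:
    """255-bin histogram normalised by the maximum bin count.

    ``values[x-1] = F_x / max_j F_j`` for intensities ``x`` in {1,...,255};
    the tallest bin is exactly 1.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if img.min() < 1 or img.max() > N_BINS:
        raise ValueError("image intensities must lie in {1, ..., 255}")
    counts = np.bincount(img.ravel(), minlength=N_BINS + 1)[1:].astype(np.float64)
    return counts / counts.max()


def histogram_counts(image: np.ndarray) -> np.ndarray:
    """Raw 255-bin pixel counts (used for class-mass bookkeeping)."""
    img = np.asarray(image)
    return np.bincount(img.ravel(), minlength=N_BINS + 1)[1:]


def smooth_histogram(hist: np.ndarray, bandwidth_w: int) -> np.ndarray:
    """Low-pass the histogram with a length-255 DFT band limit.

    The DC bin, the ``W`` lowest positive frequencies and their conjugate
    mirror are kept; everything else is zeroed.  The operation is a
    projection, hence idempotent, and preserves the histogram mean.
    """
    if not 1 <= bandwidth_w <= 127:
        raise ValueError(f"bandwidth_w must be in [1, 127], got {bandwidth_w}")
    h = np.asarray(hist, dtype=np.float64)
    if h.shape != (N_BINS,):
        raise ValueError(f"histogram must have {N_BINS} bins")
    spectrum = np.fft.fft(h)
    k = np.arange(N_BINS)
    keep = np.minimum(k, N_BINS - k) <= bandwidth_w
    return np.fft.ifft(spectrum * keep).real


def fit_line_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Ordinary-least-squares line fit ``y = a x + b``; returns ``(a, b)``."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least two points with distinct x")
    a, b = np.polyfit(x, y, 1)
    return float(a), float(b)


def _window_slopes(values: np.ndarray, n: int) -> np.ndarray:
    """Slope of the OLS line through each length-``n`` contiguous window.

    For unit-spaced abscissae the slope is a fixed linear functional of the
    window, ``sum_j w_j y_j`` with ``w_j = (j - (n-1)/2) / sum_k (k - (n-1)/2)^2``.
    """
    j = np.arange(n, dtype=np.float64)
    w = (j - (n - 1) / 2.0)
    w /= (w**2).sum()
    return sliding_window_view(values, n) @ w


def slope_difference(smoothed: np.ndarray, window_n: int) -> SlopeDifference:
    """Slope-difference signal ``s(i) = a_r(i) - a_l(i)``.

    At intensity ``i`` the left window covers ``i-N+1 ... i`` and the right
    window covers ``i ... i+N-1`` (both include ``i``); ``s`` is defined for
    ``i`` in ``1+N ... 255-N``.
    """
    if not 2 <= window_n <= 100:
        raise ValueError(f"window_n must be in [2, 100], got {window_n}")
    h = np.asarray(smoothed, dtype=np.float64)
    if h.shape != (N_BINS,):
        raise ValueError(f"histogram must have {N_BINS} bins")
    n = window_n
    slopes = _window_slopes(h, n)  # slopes[k] = slope over bins k .. k+n-1 (0-based)
    i = np.arange(1 + n, N_BINS - n + 1)  # 1-based intensities
    left = slopes[i - n]       # window i-N+1 ... i  ->  0-based start i-n
    right = slopes[i - 1]      # window i ... i+N-1  ->  0-based start i-1
    return SlopeDifference(values=right - left, window_n=n)


def _plateau_extrema(v: np.ndarray, kind: str) -> list[int]:
    """Interior local extrema of a 1D signal, plateaus collapsed to their
    central index (floor of the midpoint).  ``kind`` is 'max' or 'min'."""
    if v.size < 3:
        return []
    if kind == "max":
        ok_l = v[1:] >= v[:-1]
        ok_r = v[:-1] >= v[1:]
    else:
        ok_l = v[1:] <= v[:-1]
        ok_r = v[:-1] <= v[1:]
    flag = np.zeros(v.size, dtype=bool)
    flag[1:-1] = ok_l[:-1] & ok_r[1:]
    cand = np.flatnonzero(flag)
    out: list[int] = []
    run: list[int] = []
    for idx in cand:
        if run and idx == run[-1] + 1 and v[idx] == v[run[-1]]:
            run.append(idx)
        else:
            if run:
                out.append(run[(len(run) - 1) // 2])
            run = [idx]
    if run:
        out.append(run[(len(run) - 1) // 2])
    return out


def slope_maxima(s: SlopeDifference) -> tuple[int, ...]:
    """Intensity positions of the positive local maxima of ``s`` (raw
    valley candidates, before mode pairing); plateau midpoints."""
    v = s.values
    if v.size == 0:
        raise ValueError("empty slope-difference signal")
    first = s.first_intensity
    return tuple(int(i) + first for i in _plateau_extrema(v, "max") if v[i] > _S_EPS)


def histogram_modes(smoothed: np.ndarray, min_height: float = 0.02) -> tuple[int, ...]:
    """Intensities of the smoothed histogram's local maxima above ``min_height``.

    The bin heights are max-normalised, so ``min_height`` is a fraction of
    the tallest mode; the cutoff rejects band-limiting ripple in empty
    histogram regions.  The first and last bin count as modes when they
    dominate their inward neighbour (a class clipped at the range edge).
    """
    h = np.asarray(smoothed, dtype=np.float64)
    idx = [i for i in _plateau_extrema(h, "max") if h[i] >= min_height]
    if h[0] >= max(h[1], min_height) and 0 not in idx:
        idx = [0] + idx
    if h[-1] >= max(h[-2], min_height) and (h.size - 1) not in idx:
        idx = idx + [h.size - 1]
    return tuple(int(i) + 1 for i in sorted(idx))


def find_thresholds(
    s: SlopeDifference,
    smoothed: np.ndarray | None = None,
    valley_merge_distance: int = 8,
    mode_min_height: float = 0.02,
) -> tuple[int, ...]:
    """Histogram-valley positions separating adjacent pixel classes.

    A class-separating valley (falling left arm, rising right arm)
    appears in the slope difference ``s = a_r - a_l`` as a region of
    positive values between two histogram modes.  When ``smoothed`` is
    given, one threshold is produced per adjacent mode pair whose
    inter-mode interval contains positive ``s``: the ``s``-weighted
    centroid of that positive region (rounded), which reduces to the
    single ``s`` maximum for a sharp valley and stays centred when band
    limiting flattens a wide valley into twin curvature bumps.  Without
    ``smoothed``, the raw positive maxima of ``s`` are returned.

    Detections closer than ``valley_merge_distance`` intensity levels are
    merged, keeping the deeper one (larger ``s``).  Returns an ascending
    tuple; empty when no valley exists (e.g. a monotone histogram).
    """
    v = s.values
    if v.size == 0:
        raise ValueError("empty slope-difference signal")
    first = s.first_intensity
    if smoothed is None:
        found = [(p, float(v[p - first])) for p in slope_maxima(s)]
    else:
        modes = histogram_modes(smoothed, mode_min_height)
        found = []
        for lo, hi in zip(modes[:-1], modes[1:]):
            a = max(lo + 1, first)
            b = min(hi - 1, s.last_intensity)
            if a > b:
                continue
            seg = v[a - first : b - first + 1]
            w = np.clip(seg, 0.0, None)
            total = float(w.sum())
            if total <= _S_EPS:
                continue
            pos = float((np.arange(a, b + 1) * w).sum() / total)
            found.append((int(round(pos)), float(w.max())))

    merged: list[tuple[int, float]] = []
    for idx, height in found:
        if merged and idx - merged[-1][0] < valley_merge_distance:
            if height > merged[-1][1]:
                merged[-1] = (idx, height)
        else:
            merged.append((idx, height))
    return tuple(idx for idx, _ in merged)


def assign_threshold_roles(
    thresholds: tuple[int, ...] | ThresholdSet,
    histogram: np.ndarray | None = None,
    case: str | None = None,
) -> ThresholdSet:
    """Map detected valleys to the anatomical thresholds T1-T4 by rank order.

    T2 (body) is the lowest valley and T1 (bones) the highest.  Among the
    interior valleys, T4 (liver) is the valley bounding the most-populated
    interior intensity class from below and T3 (adjacent organ) is the next
    valley above it.  Fallbacks: three valleys -> T3 := T1; two valleys ->
    T3 = T4 = T2 (single soft-tissue class).

    ``histogram`` (raw counts or max-normalised heights over bins 1..255)
    supplies the class masses; without it the lowest interior valley is
    taken for T4.  ``case`` is recorded only; the rank rule is identical
    for the stomach/kidney/heart adjacency cases.
    """
    ts = thresholds.thresholds if isinstance(thresholds, ThresholdSet) else tuple(thresholds)
    ts = tuple(sorted(int(t) for t in ts))
    if len(ts) < 2:
        raise InsufficientClassesError(
            f"insufficient pixel classes: need >= 2 thresholds, got {len(ts)}"
        )
    t2, t1 = ts[0], ts[-1]
    if len(ts) == 2:
        t3 = t4 = t2
    elif len(ts) == 3:
        t4 = ts[1]
        t3 = t1
    else:
        # interior classes bounded below by an interior valley: [ts[j], ts[j+1])
        if histogram is not None:
            h = np.asarray(histogram, dtype=np.float64)
            masses = [h[ts[j] - 1 : ts[j + 1] - 1].sum() for j in range(1, len(ts) - 1)]
            jstar = 1 + int(np.argmax(masses))
        else:
            jstar = 1
        t4 = ts[jstar]
        t3 = ts[jstar + 1] if jstar + 1 <= len(ts) - 2 else t1
    return ThresholdSet(thresholds=ts, roles={"T1": t1, "T2": t2, "T3": t3, "T4": t4})


def sdd_table(image: np.ndarray, params: SddParams = SddParams()):
    """Per-intensity diagnostic table: x, P(x), smoothed P'(x) and s(x).

    ``s`` is NaN outside its defined range ``1+N ... 255-N``.  Intended for
    CSV export when debugging threshold placement on a slice.
    """
    import pandas as pd

    hist = compute_histogram(image)
    smoothed = smooth_histogram(hist, params.bandwidth_w)
    s = slope_difference(smoothed, params.window_n)
    full = np.full(N_BINS, np.nan)
    full[s.first_intensity - 1 : s.last_intensity] = s.values
    return pd.DataFrame(
        {"x": np.arange(1, N_BINS + 1), "P": hist, "P_smooth": smoothed, "s": full}
    )


def binarize(image: np.ndarray, threshold: int) -> np.ndarray:
    """Boolean mask, 1 where the intensity is >= ``threshold``."""
    if not 1 <= threshold <= N_BINS:
        raise ValueError(f"threshold must be in [1, 255], got {threshold}")
    return np.asarray(image) >= threshold


def calibrate_params(
    images,
    liver_truths,
    w_grid,
    n_grid,
    config=None,
):
    """Grid search (W, N) maximising mean liver Dice of the full pipeline.

    Deterministic: ties are broken by grid order (W outer, N inner).
    Returns the winning :class:`SddParams`.
    """
    from .config import RunConfig
    from .metrics import dice
    from .pipeline import process_slice

    images = list(images)
    liver_truths = list(liver_truths)
    if not images or len(images) != len(liver_truths):
        raise ValueError("need a non-empty, equal-length set of images and liver masks")
    base = config if config is not None else RunConfig()
    best: tuple[float, SddParams] | None = None
    for w in w_grid:
        for n in n_grid:
            cfg = base.with_sdd(bandwidth_w=int(w), window_n=int(n))
            scores = []
            for img, truth in zip(images, liver_truths):
                res = process_slice(img, cfg)
                if res.empty or res.liver_mask is None:
                    scores.append(0.0)
                else:
                    scores.append(dice(res.liver_mask, truth))
            mean = float(np.mean(scores))
            if best is None or mean > best[0]:
                best = (mean, cfg.sdd)
    assert best is not None
    return best[1]
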