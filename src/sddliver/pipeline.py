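"""Per-slice liver segmentation: thresholds + constraints -> mask -> boundary.

The liver rule keeps a pixel iff its intensity reaches the liver
threshold T4 *and* it lies on the liver side of the rib curve, outside
the body-margin ring, and outside the merged adjacent-organ mask.  The
raw mask is then MRF-denoised, opened, reduced to its largest blob, and
its traced boundary is smoothed with a periodic discrete smoothing
spline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import eye as speye
from scipy.sparse import diags
from scipy.sparse.linalg import spsolve

from .anatomy import (
    ConstraintMasks,
    classify_bone_blobs,
    curve_exclusion_mask,
    estimate_rib_width,
    fit_rib_curve,
    ring_constraint,
    segment_body,
    segment_bones,
    segment_stomach,
)
from .config import RunConfig
from .morphology import keep_largest_component, morphological_filter
from .mrf import minimize_energy
from .sdd import (
    ThresholdSet,
    assign_threshold_roles,
    binarize,
    compute_histogram,
    find_thresholds,
    histogram_counts,
    rescale_intensities,
    slope_difference,
    smooth_histogram,
)

__all__ = [
    "Contour",
    "SliceResult",
    "NoLiverError",
    "segment_liver",
    "clean_liver",
    "extract_boundary",
    "spline_smooth",
    "process_slice",
]


class NoLiverError(RuntimeError):
    """Raised when a slice contains no liver candidate after cleaning."""


@dataclass(frozen=True)
class Contour:
    """Closed boundary polyline; vertices are (row, col), no repeated endpoint."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=np.float64)
        object.__setattr__(self, "vertices", v)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 1:
            raise ValueError("contour needs an (n, 2) vertex array")

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def perimeter(self) -> float:
        v = self.vertices
        nxt = np.roll(v, -1, axis=0) if self.closed else v[1:]
        cur = v if self.closed else v[:-1]
        return float(np.linalg.norm(nxt - cur, axis=1).sum())


@dataclass
class SliceResult:
    """Outcome of one slice: liver mask + smoothed boundary, or a flagged gap."""

    liver_mask: np.ndarray | None
    boundary: Contour | None
    raw_boundary: Contour | None = None
    thresholds: ThresholdSet | None = None
    case: str = "auto"
    empty: bool = False
    message: str = ""
    debug: dict = field(default_factory=dict)


def segment_liver(image: np.ndarray, t4: int, constraints: ConstraintMasks) -> np.ndarray:
    """Liver rule: intensity >= T4 AND all three constraint masks are 0."""
    m = binarize(image, t4)
    for c in (constraints.curve_excluded, constraints.ring, constraints.stomach):
        c = np.asarray(c).astype(bool)
        if c.shape != m.shape:
            raise ValueError("constraint mask shape mismatch")
        m = m & ~c
    return m


def clean_liver(mask: np.ndarray, config: RunConfig = RunConfig()) -> np.ndarray:
    """MRF denoise -> morphological filter -> keep the largest blob."""
    m = minimize_energy(mask, config.mrf.to_model())
    m = morphological_filter(m, config.morph.n_f)
    if not m.any():
        raise NoLiverError("no liver found in slice")
    return keep_largest_component(m)


# Moore neighbourhood in clockwise order starting from west (row, col offsets)
_MOORE = [(0, -1), (-1, -1), (-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1)]


def extract_boundary(mask: np.ndarray) -> Contour:
    """Outer boundary of the mask's single component by Moore-neighbour tracing.

    Vertices are foreground boundary pixels in order; orientation is
    normalised to counter-clockwise in (col, row) axes (negative shoelace
    area in image coordinates).  A single pixel gives a degenerate
    one-vertex closed contour.
    """
    m = np.asarray(mask).astype(bool)
    if not m.any():
        raise ValueError("empty mask has no boundary")
    pad = np.pad(m, 1)
    rs, cs = np.nonzero(pad)
    start = (int(rs[0]), int(cs[0]))  # topmost-leftmost foreground pixel
    if m.sum() == 1:
        return Contour(np.array([[start[0] - 1, start[1] - 1]], dtype=np.float64))

    # state = (current boundary pixel, backtrack background pixel); the walk
    # is deterministic, so recurrence of the initial state closes the loop
    b0 = (start[0], start[1] - 1)  # west of start is background by raster order
    cur, back = start, b0
    path: list[tuple[int, int]] = []
    limit = 4 * int(pad.sum()) + 8
    for _ in range(limit):
        start_idx = _MOORE.index((back[0] - cur[0], back[1] - cur[1]))
        found = None
        prev_bg = back
        for k in range(1, 9):  # clockwise scan, skipping the backtrack itself
            dr, dc = _MOORE[(start_idx + k) % 8]
            nb = (cur[0] + dr, cur[1] + dc)
            if pad[nb]:
                found = nb
                break
            prev_bg = nb
        path.append(cur)
        if found is None:  # isolated start pixel (mask was not one component)
            break
        cur, back = found, prev_bg
        if cur == start and back == b0:
            break
    else:
        raise RuntimeError("boundary tracing failed to terminate")
    verts = np.array(path, dtype=np.float64) - 1.0  # undo padding offset

    # orientation: counter-clockwise w.r.t. x=col, y=row axes
    x, y = verts[:, 1], verts[:, 0]
    area2 = float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    if area2 > 0:
        verts = verts[::-1].copy()
    return Contour(verts)


def _second_difference(n: int, periodic: bool):
    """Sparse second-difference operator D with D f ~ f''."""
    if periodic:
        main = -2.0 * np.ones(n)
        off = np.ones(n - 1)
        d = diags([main, off, off, [1.0], [1.0]], [0, 1, -1, n - 1, -(n - 1)], format="csc")
        return d
    main = np.ones(n - 2)
    return diags(
        [main, -2.0 * main, main], [0, 1, 2], shape=(n - 2, n), format="csc"
    )


def spline_smooth(contour: Contour, alpha: float = 0.5) -> Contour:
    """Smooth a closed contour by a discrete periodic smoothing spline.

    Minimises ``(1 - alpha) * sum_j |B_s(j) - B(j)|^2 + alpha * sum_j
    |B_s(j-1) - 2 B_s(j) + B_s(j+1)|^2`` per coordinate with periodic
    boundary conditions — the standard discretisation of a fidelity term
    plus integrated squared second derivative.  ``alpha = 0`` returns the
    input exactly; ``alpha`` is restricted below 1 because the pure
    curvature objective collapses closed curves.
    """
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    v = contour.vertices
    if alpha == 0.0 or len(contour) < 4:
        return Contour(v.copy(), closed=contour.closed)
    n = v.shape[0]
    d = _second_difference(n, periodic=contour.closed)
    a = (1.0 - alpha) * speye(d.shape[1], format="csc") + alpha * (d.T @ d)
    out = np.column_stack(
        [spsolve(a, (1.0 - alpha) * v[:, k]) for k in range(2)]
    )
    return Contour(out, closed=contour.closed)


def _empty_result(message: str, thresholds: ThresholdSet | None = None, case: str = "auto") -> SliceResult:
    return SliceResult(
        liver_mask=None,
        boundary=None,
        thresholds=thresholds,
        case=case,
        empty=True,
        message=message,
    )


def process_slice(image: np.ndarray, config: RunConfig = RunConfig()) -> SliceResult:
    """Full per-slice chain, deterministic; failures yield a flagged empty result.

    rescale -> histogram -> DFT smoothing -> slope difference -> valley
    thresholds -> role assignment -> bone/body/curve/ring/organ
    constraints -> liver rule -> clean -> boundary -> spline smoothing.
    """
    img = np.asarray(image)
    if img.size == 0:
        raise ValueError("empty image")
    if min(img.shape) < 16:
        raise ValueError("image must be at least 16 x 16")
    if config.anatomy.orientation_flip:
        img = img[:, ::-1]
    if img.min() == img.max():
        return _empty_result("degenerate slice: constant intensity", case=config.case)

    g = rescale_intensities(img)
    params = config.sdd
    hist = compute_histogram(g)
    counts = histogram_counts(g)
    smoothed = smooth_histogram(hist, params.bandwidth_w)
    s = slope_difference(smoothed, params.window_n)
    valleys = find_thresholds(
        s, smoothed, params.valley_merge_distance, params.mode_min_height
    )
    if len(valleys) < 2:
        return _empty_result(
            f"insufficient pixel classes: {len(valleys)} valley(s) detected",
            case=config.case,
        )
    ts = assign_threshold_roles(valleys, counts, case=config.case)
    t1, t2, t3, t4 = (ts.role(k) for k in ("T1", "T2", "T3", "T4"))

    body = segment_body(g, t2, config.morph.n_f)
    if not body.any():
        return _empty_result("empty body mask", thresholds=ts, case=config.case)
    body_centroid = tuple(np.mean(np.nonzero(body), axis=1))

    shape = g.shape
    constraints = ConstraintMasks.none(shape)
    bones = segment_bones(g, t1)
    debug: dict = {"body": body, "bones": bones}
    try:
        split = (
            config.anatomy.rib_split
            if config.anatomy.rib_split is not None
            else body_centroid[1]
        )
        ribs, spine, labels = classify_bone_blobs(
            bones, split_col=split, min_area=config.anatomy.min_bone_blob_area
        )
        centroids = np.array([b.centroid for b in ribs] + [spine.centroid])
        curve = fit_rib_curve(centroids)
        curve_mask = curve_exclusion_mask(curve, shape, interior_point=body_centroid)
        n_c = estimate_rib_width(bones, ribs, labels)
        ring = ring_constraint(body, n_c)
        # the organ constraint only discriminates when T3 exceeds T4
        if t3 > t4:
            stomach = segment_stomach(
                g, t3, bones, spine.centroid[1],
                model=config.mrf.to_model(),
                n_f=config.morph.n_f, n_m=config.morph.n_m,
            )
        else:
            stomach = np.zeros(shape, dtype=bool)
        constraints = ConstraintMasks(curve_mask, ring, stomach)
        debug.update(curve=curve, n_c=n_c)
    except ValueError as exc:
        # bone layout unusable: fall back to ring-only constraint
        ring = ring_constraint(body, config.morph.n_f)
        constraints = ConstraintMasks(
            np.zeros(shape, dtype=bool), ring, np.zeros(shape, dtype=bool)
        )
        debug["constraint_warning"] = str(exc)

    liver = segment_liver(g, t4, constraints)
    try:
        liver = clean_liver(liver, config)
    except NoLiverError as exc:
        return _empty_result(str(exc), thresholds=ts, case=config.case)

    raw = extract_boundary(liver)
    smooth = spline_smooth(raw, config.spline_alpha) if len(raw) >= 4 else raw
    if config.anatomy.orientation_flip:
        liver = liver[:, ::-1]
        w = liver.shape[1]
        raw = Contour(np.column_stack([raw.vertices[:, 0], w - 1 - raw.vertices[:, 1]]))
        smooth = Contour(
            np.column_stack([smooth.vertices[:, 0], w - 1 - smooth.vertices[:, 1]])
        )
    debug["constraints"] = constraints
    return SliceResult(
        liver_mask=liver,
        boundary=smooth,
        raw_boundary=raw,
        thresholds=ts,
        case=config.case,
        empty=False,
        debug=debug,
    )
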