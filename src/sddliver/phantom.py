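"""Synthetic abdominal CT phantom with per-structure ground truth.

One slice emulates the structures the segmentation relies on: an
elliptical body on a dark background, rib strokes along the left flank,
a bright spine blob near the posterior centre, a liver occupying the
flank interior, an adjacent organ (stomach, kidney or heart, depending
on the case) on the medial side of the spine, and optionally a band of
abdominal-wall tissue with *liver-equal* intensity hugging the body
margin next to the liver — the situation the rib-curve and ring
constraints exist for.  Gaussian noise is added and the result clipped
to [0, 255].

A stack mode produces a sequence of slices in which a circular liver
cross-section follows a prescribed radius profile along z (cylinder or
sphere), giving an analytic ground-truth volume for reconstruction
tests.

Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["PhantomSpec", "generate_slice", "generate_stack", "CASES"]

CASES = ("stomach", "kidney", "heart")

# organ placement per adjacency case: centre (row, col) and semi-axes (row, col);
# each organ touches the liver's medial boundary
_ORGAN_GEOMETRY = {
    "stomach": ((105.0, 160.0), (34.0, 30.0)),
    "kidney": ((154.0, 132.0), (24.0, 20.0)),
    "heart": ((62.0, 138.0), (26.0, 30.0)),
}

#: rib line as a fraction of the body ellipse axes; the liver reaches it
RIB_INSET = 0.86
#: ground-truth liver is clipped just inside the rib line
LIVER_CLIP = 0.84


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensities and noise of one synthetic abdomen.

    Class mean intensities must be strictly ordered
    background < body < liver < organ < bone; the defaults give
    well-separated histogram modes at a CT-like soft-tissue contrast.
    ``equal_intensity_tissue`` adds the liver-intensity abdominal-wall
    band (on by default: it is the hard case the constraints address).
    """

    case: str = "stomach"
    shape: tuple[int, int] = (256, 256)
    mean_background: float = 25.0
    mean_body: float = 60.0
    mean_liver: float = 120.0
    mean_organ: float = 160.0
    mean_bone: float = 230.0
    noise_sigma: float = 8.0
    rib_count: int = 5
    rib_width: int = 6
    rib_length: float = 26.0
    body_center: tuple[float, float] = (130.0, 128.0)
    body_axes: tuple[float, float] = (92.0, 108.0)
    liver_center: tuple[float, float] = (120.0, 84.0)
    liver_axes: tuple[float, float] = (56.0, 46.0)
    spine_center: tuple[float, float] = (192.0, 128.0)
    spine_radius: float = 13.0
    equal_intensity_tissue: bool = True
    organ_present: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(f"case must be one of {CASES}")
        means = (
            self.mean_background,
            self.mean_body,
            self.mean_liver,
            self.mean_organ,
            self.mean_bone,
        )
        if any(a >= b for a, b in zip(means, means[1:])):
            if not (
                self.mean_organ == self.mean_liver
                and self.mean_background < self.mean_body < self.mean_liver < self.mean_bone
            ):
                raise ValueError(
                    "class means must satisfy background < body < liver <= organ < bone"
                )
        if self.rib_count < 1 or self.rib_width < 1:
            raise ValueError("need at least one rib of positive width")


def _ellipse(shape, center, axes) -> np.ndarray:
    rr, cc = np.indices(shape, dtype=np.float64)
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _body_radial(spec: PhantomSpec) -> np.ndarray:
    """Elliptic radial coordinate of each pixel w.r.t. the body ellipse
    (0 at the centre, 1 on the body boundary)."""
    rr, cc = np.indices(spec.shape, dtype=np.float64)
    cy, cx = spec.body_center
    ar, ac = spec.body_axes
    return np.sqrt(((rr - cy) / ar) ** 2 + ((cc - cx) / ac) ** 2)


def _thick_segment(shape, p0, p1, width) -> np.ndarray:
    """Pixels within perpendicular distance width/2 of segment p0-p1."""
    rr, cc = np.indices(shape, dtype=np.float64)
    p0 = np.asarray(p0, dtype=np.float64)
    d = np.asarray(p1, dtype=np.float64) - p0
    length2 = float(d @ d)
    vr, vc = rr - p0[0], cc - p0[1]
    t = np.clip((vr * d[0] + vc * d[1]) / length2, 0.0, 1.0)
    dist2 = (vr - t * d[0]) ** 2 + (vc - t * d[1]) ** 2
    return dist2 <= (width / 2.0) ** 2


def _rib_masks(spec: PhantomSpec) -> np.ndarray:
    """Union of rib strokes: short thick tangential segments along the left flank."""
    cy, cx = spec.body_center
    ar, ac = spec.body_axes
    inset = RIB_INSET
    ribs = np.zeros(spec.shape, dtype=bool)
    angles = np.linspace(120.0, 240.0, spec.rib_count) * np.pi / 180.0
    for phi in angles:
        center = np.array([cy + inset * ar * np.sin(phi), cx + inset * ac * np.cos(phi)])
        tangent = np.array([ar * np.cos(phi), -ac * np.sin(phi)])
        tangent /= np.linalg.norm(tangent)
        half = 0.5 * spec.rib_length * tangent
        ribs |= _thick_segment(spec.shape, center - half, center + half, spec.rib_width)
    return ribs


def _wall_band(spec: PhantomSpec) -> np.ndarray:
    """Liver-intensity abdominal-wall band along the lower-left body margin.

    The band starts just outside the ground-truth liver clip radius, so it
    *touches* the liver where the liver reaches the rib line: in the raw
    liver-threshold mask the two form one connected component that only
    the rib-curve and ring constraints can sever.
    """
    radial = _body_radial(spec)
    rr, cc = np.indices(spec.shape, dtype=np.float64)
    ang = np.arctan2(rr - spec.body_center[0], cc - spec.body_center[1])  # 0 = +col axis
    lo, hi = np.deg2rad(95.0), np.deg2rad(170.0)  # lower-left sector
    return (radial > LIVER_CLIP) & (radial <= 1.0) & (ang >= lo) & (ang <= hi)


def generate_slice(
    spec: PhantomSpec, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """One noisy phantom slice plus its ground-truth masks.

    Returns ``(image, masks)`` where ``masks`` has keys ``body`` (the full
    body ellipse), ``liver``, ``organ``, ``bones`` and ``wall``; the last
    four are pairwise disjoint subsets of ``body``.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    body = _ellipse(shape, spec.body_center, spec.body_axes)
    # the liver reaches the rib line and is clipped just inside it
    liver = _ellipse(shape, spec.liver_center, spec.liver_axes) & (
        _body_radial(spec) <= LIVER_CLIP
    )
    if spec.organ_present:
        center, axes = _ORGAN_GEOMETRY[spec.case]
        organ = _ellipse(shape, center, axes) & body
    else:
        organ = np.zeros(shape, dtype=bool)
    spine = _ellipse(shape, spec.spine_center, (spec.spine_radius, spec.spine_radius))
    bones = (_rib_masks(spec) | spine) & body
    wall = _wall_band(spec) if spec.equal_intensity_tissue else np.zeros(shape, dtype=bool)

    # priority: bones > organ > liver > wall > body
    organ &= ~bones
    liver &= ~(bones | organ)
    wall &= ~(bones | organ | liver)

    img = np.full(shape, spec.mean_background, dtype=np.float64)
    img[body] = spec.mean_body
    img[wall] = spec.mean_liver
    img[liver] = spec.mean_liver
    img[organ] = spec.mean_organ
    img[bones] = spec.mean_bone
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.int32)
    masks = {"body": body, "liver": liver, "organ": organ, "bones": bones, "wall": wall}
    return img, masks


@dataclass(frozen=True)
class StackResult:
    """Phantom volume: slices, masks, spacings and the analytic liver volume."""

    images: list[np.ndarray]
    masks: list[dict[str, np.ndarray]]
    pixel_spacing: float
    slice_spacing: float
    liver_radii: np.ndarray
    analytic_volume: float = field(default=np.nan)


def generate_stack(
    spec: PhantomSpec,
    n_stack: int = 30,
    profile: str = "sphere",
    radius: float = 50.0,
    pixel_spacing: float = 1.0,
    slice_spacing: float = 1.0,
) -> StackResult:
    """Stack of slices whose circular liver follows a z radius profile.

    ``profile='cylinder'`` keeps a constant radius (analytic volume
    ``pi r^2 h``); ``profile='sphere'`` places the slice planes evenly
    across 98% of a sphere of the given radius (analytic volume
    ``4/3 pi r^3``), overriding ``slice_spacing`` with the resulting
    plane separation.  The liver cross-section in each slice is a disk
    at the spec's liver centre; other structures are held fixed.
    """
    if n_stack < 1:
        raise ValueError("n_stack must be >= 1")
    rng = np.random.default_rng(spec.seed)
    if profile == "cylinder":
        radii = np.full(n_stack, radius)
    elif profile == "sphere":
        zs = np.linspace(-0.98 * radius, 0.98 * radius, n_stack)
        radii = np.sqrt(radius**2 - zs**2)
        if n_stack > 1:
            slice_spacing = float((zs[1] - zs[0]) * pixel_spacing)
    else:
        raise ValueError("profile must be 'cylinder' or 'sphere'")
    images, masks = [], []
    for r in radii:
        s = replace(spec, liver_axes=(float(r), float(r)))
        img, m = generate_slice(s, rng=rng)
        images.append(img)
        masks.append(m)
    if profile == "cylinder":
        vol = np.pi * radius**2 * (n_stack - 1) * slice_spacing * pixel_spacing**2
    else:
        # radius is in pixels; the slice planes were spaced in the same units
        vol = 4.0 / 3.0 * np.pi * radius**3 * pixel_spacing**3
    return StackResult(
        images=images,
        masks=masks,
        pixel_spacing=pixel_spacing,
        slice_spacing=slice_spacing,
        liver_radii=radii,
        analytic_volume=float(vol),
    )
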