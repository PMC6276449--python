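"""3D liver surface reconstruction from stacked per-slice boundaries.

Each slice boundary is resampled to 200 points at equal arc length,
start indices and traversal directions are aligned down the stack, and
the 200 resulting z-direction point trajectories are individually
smoothed with a discrete smoothing spline (weight ``1 - alpha`` on
fidelity, ``alpha`` on the integrated squared second derivative).  The
aligned grid is closed into a triangle mesh (periodic in the in-slice
index, optional end caps) and written as ASCII PLY or OBJ.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from scipy.sparse import eye as speye
from scipy.sparse.linalg import spsolve

from .pipeline import Contour, _second_difference

__all__ = [
    "resample_contour",
    "align_start_indices",
    "stack_to_grid",
    "smooth_z_curves",
    "grid_to_mesh",
    "mesh_volume",
    "export_surface",
]


def resample_contour(contour: Contour | np.ndarray, n_points: int = 200) -> np.ndarray:
    """Resample a closed contour to ``n_points`` vertices at equal arc length."""
    v = contour.vertices if isinstance(contour, Contour) else np.asarray(contour, float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise ValueError("contour must be an (n, 2) array")
    if n_points < 3:
        raise ValueError("need at least 3 sample points")
    loop = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(loop, axis=0), axis=1)
    total = float(seg.sum())
    if total <= 0:
        raise ValueError("degenerate contour: zero perimeter")
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.arange(n_points) * total / n_points
    out = np.column_stack(
        [np.interp(targets, cum, loop[:, k]) for k in range(2)]
    )
    return out


def _signed_area(v: np.ndarray) -> float:
    x, y = v[:, 1], v[:, 0]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))


def align_start_indices(contours: list[np.ndarray]) -> list[np.ndarray]:
    """Make traversal directions consistent and rotate start indices.

    The first contour sets the orientation.  Each subsequent contour is
    (possibly) reversed to match, then cyclically shifted to the offset
    minimising the summed squared distance to the previous aligned
    contour, so that index ``n`` traces a coherent z-curve with no
    spiralling.  All contours must share the same vertex count.
    """
    if len(contours) < 2:
        raise ValueError("need at least two contours to align")
    n = contours[0].shape[0]
    if any(c.shape != (n, 2) for c in contours):
        raise ValueError("all contours must have the same vertex count")
    ref_sign = np.sign(_signed_area(contours[0])) or 1.0
    aligned = [np.asarray(contours[0], dtype=np.float64).copy()]
    for c in contours[1:]:
        c = np.asarray(c, dtype=np.float64)
        if np.sign(_signed_area(c)) not in (0.0, ref_sign):
            c = c[::-1]
        prev = aligned[-1]
        # cost(shift) = sum ||c[(i+shift) % n] - prev[i]||^2; expand: const - 2 corr
        best_shift, best_cost = 0, np.inf
        for shift in range(n):
            rolled = np.roll(c, -shift, axis=0)
            cost = float(((rolled - prev) ** 2).sum())
            if cost < best_cost:
                best_cost, best_shift = cost, shift
        aligned.append(np.roll(c, -best_shift, axis=0))
    return aligned


def stack_to_grid(
    contours: list[np.ndarray],
    pixel_spacing: float = 1.0,
    slice_spacing: float = 1.0,
    z_positions: np.ndarray | None = None,
) -> np.ndarray:
    """(N_stack, n_points, 3) grid of physical (x, y, z) surface points.

    ``x = col * pixel_spacing``, ``y = row * pixel_spacing``,
    ``z = slice_index * slice_spacing`` (or explicit ``z_positions``).
    """
    m = len(contours)
    if z_positions is None:
        z_positions = np.arange(m) * slice_spacing
    z_positions = np.asarray(z_positions, dtype=np.float64)
    if z_positions.shape != (m,):
        raise ValueError("z_positions must have one entry per contour")
    grid = np.empty((m, contours[0].shape[0], 3))
    for i, c in enumerate(contours):
        grid[i, :, 0] = c[:, 1] * pixel_spacing
        grid[i, :, 1] = c[:, 0] * pixel_spacing
        grid[i, :, 2] = z_positions[i]
    return grid


def smooth_z_curves(grid: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Smoothing-spline filter each of the z-direction point trajectories.

    For each in-slice index ``n`` the stacked points form a curve over
    the slice index ``m``; every coordinate of that curve is replaced by
    the minimiser of ``(1 - alpha) * sum (f - p)^2 + alpha * sum (second
    difference of f)^2`` (natural boundary).  ``alpha = 0`` is the exact
    identity; curves already linear in the slice index are unchanged.
    """
    g = np.asarray(grid, dtype=np.float64)
    if g.ndim != 3 or g.shape[2] != 3:
        raise ValueError("grid must be (N_stack, n_points, 3)")
    if not 0.0 <= alpha < 1.0:
        raise ValueError("alpha must be in [0, 1)")
    m = g.shape[0]
    if m < 4:
        raise ValueError("need at least 4 slices to smooth z-curves")
    if alpha == 0.0:
        return g.copy()
    d = _second_difference(m, periodic=False)
    a = (1.0 - alpha) * speye(m, format="csc") + alpha * (d.T @ d)
    flat = g.reshape(m, -1)  # (m, n_points * 3)
    out = spsolve(a, (1.0 - alpha) * flat)
    return np.asarray(out).reshape(g.shape)


def grid_to_mesh(
    grid: np.ndarray, close_caps: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Triangle mesh over the surface grid, periodic in the in-slice index.

    Returns ``(vertices, faces)`` with consistent winding; with
    ``close_caps`` a fan over each end ring's centroid closes the mesh
    watertight so that a signed volume is defined.
    """
    g = np.asarray(grid, dtype=np.float64)
    m, n, _ = g.shape
    if m < 2 or n < 3:
        raise ValueError("grid must be at least 2 slices of 3 points")
    vertices = g.reshape(-1, 3)
    faces = []
    for i in range(m - 1):
        for j in range(n):
            a = i * n + j
            b = i * n + (j + 1) % n
            c = (i + 1) * n + (j + 1) % n
            d = (i + 1) * n + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    if close_caps:
        bottom_center = len(vertices)
        top_center = len(vertices) + 1
        vertices = np.vstack([vertices, g[0].mean(axis=0), g[-1].mean(axis=0)])
        for j in range(n):
            faces.append((bottom_center, (j + 1) % n, j))
            base = (m - 1) * n
            faces.append((top_center, base + j, base + (j + 1) % n))
    return vertices, np.asarray(faces, dtype=np.int64)


def mesh_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    """Enclosed volume of a watertight triangle mesh (divergence theorem)."""
    v = np.asarray(vertices, dtype=np.float64)
    f = np.asarray(faces, dtype=np.int64)
    a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
    return abs(float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def export_surface(grid: np.ndarray, path: str | Path, close_caps: bool = True) -> Path:
    """Write the surface mesh as ASCII PLY or OBJ, chosen by file extension."""
    path = Path(path)
    vertices, faces = grid_to_mesh(grid, close_caps=close_caps)
    if path.suffix.lower() == ".ply":
        lines = [
            "ply",
            "format ascii 1.0",
            f"element vertex {len(vertices)}",
            "property float x",
            "property float y",
            "property float z",
            f"element face {len(faces)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        lines += [f"{x:.6f} {y:.6f} {z:.6f}" for x, y, z in vertices]
        lines += [f"3 {a} {b} {c}" for a, b, c in faces]
        path.write_text("\n".join(lines) + "\n")
    elif path.suffix.lower() == ".obj":
        lines = [f"v {x:.6f} {y:.6f} {z:.6f}" for x, y, z in vertices]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in faces]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError("unsupported mesh format: use .ply or .obj")
    return path
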