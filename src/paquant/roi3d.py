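"""Tumour and peri-tumoral region geometry.

The tumour boundary is given as a stack of physician-drawn 2-D contours, one
set per sweep slice.  From it this module builds

* the voxelized tumour mask (centre-inclusion rasterization),
* the least-volume (minimum-volume) enclosing ellipsoid (LVE/MVEE) of the
  boundary vertices,
* the "extension" ellipsoid with every semi-axis scaled by a factor
  (default 1.2) and the surrounding-region mask (inside the extension,
  outside the tumour),
* the mirrored ROI used to probe the symmetric location in the contralateral
  volume.

Coordinate convention: world coordinates are (z, y, x) in mm aligned with the
array axes (slice, row, col); the origin sits at the first voxel's centre and
voxel *i, j, k* is centred at ``(i*dz, j*dy, k*dx)``.  The row axis is depth
below the probe face.  Voxel membership is decided by centre inclusion, with
boundary points counted as inside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import shapely

from .exceptions import ConfigurationError, DataError, DegenerateGeometryError, GeometryError

logger = logging.getLogger(__name__)

__all__ = [
    "Ellipsoid",
    "ContourStack",
    "VoxelMask",
    "rasterize_contours",
    "mvee",
    "extend_ellipsoid",
    "surrounding_mask",
    "mirror_roi",
]


@dataclass(frozen=True)
class Ellipsoid:
    """An ellipsoid in world (z, y, x) mm coordinates.

    ``semi_axes`` are sorted descending; ``orientation`` is a right-handed
    rotation whose columns are the axis directions, so a point *p* is inside
    iff ``|| diag(1/a) R^T (p - c) || <= 1``.
    """

    center: np.ndarray
    semi_axes: np.ndarray
    orientation: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(3)
        a = np.asarray(self.semi_axes, dtype=float).reshape(3)
        R = np.asarray(self.orientation, dtype=float).reshape(3, 3)
        if np.any(a <= 0):
            raise GeometryError("semi-axes must be positive")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise GeometryError("orientation must be orthonormal")
        if np.linalg.det(R) < 0:
            raise GeometryError("orientation must be right-handed (det +1)")
        # canonical form: axes descending, permuting columns accordingly
        order = np.argsort(-a)
        a = a[order]
        R = R[:, order]
        if np.linalg.det(R) < 0:  # permutation may flip handedness
            R = R.copy()
            R[:, 2] = -R[:, 2]
        object.__setattr__(self, "center", c)
        object.__setattr__(self, "semi_axes", a)
        object.__setattr__(self, "orientation", R)

    @property
    def volume(self) -> float:
        """4/3 pi abc, in mm^3."""
        return float(4.0 / 3.0 * np.pi * np.prod(self.semi_axes))

    def mahalanobis(self, points: np.ndarray) -> np.ndarray:
        """Ellipsoidal norm of ``points - center``; <= 1 means inside."""
        p = np.asarray(points, dtype=float)
        body = (p - self.center) @ self.orientation / self.semi_axes
        return np.sqrt(np.sum(body * body, axis=-1))

    def contains(self, points: np.ndarray, rtol: float = 0.0) -> np.ndarray:
        return self.mahalanobis(points) <= 1.0 + rtol

    def scaled(self, factor: float) -> "Ellipsoid":
        return Ellipsoid(self.center, self.semi_axes * factor, self.orientation)

    @property
    def quadratic_form(self) -> np.ndarray:
        """Matrix A with inside test (p-c)^T A (p-c) <= 1."""
        return self.orientation @ np.diag(1.0 / self.semi_axes**2) @ self.orientation.T

    def cross_section(self, z: float, n_vertices: int = 64):
        """Boundary polygon of the slice-plane intersection at slice position *z*.

        Returns an (n, 2) array of (x, y) vertices in mm, or None if the
        plane misses the ellipsoid.
        """
        A = self.quadratic_form
        u = z - self.center[0]
        M = A[1:, 1:]
        b = A[1:, 0]
        Minv_b = np.linalg.solve(M, b)
        rhs = 1.0 - A[0, 0] * u * u + u * u * b @ Minv_b
        if rhs <= 1e-12:
            return None
        w0 = self.center[1:] - u * Minv_b  # (y, x) centre of the ellipse
        evals, evecs = np.linalg.eigh(M / rhs)
        radii = 1.0 / np.sqrt(evals)
        theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        circ = np.stack([np.cos(theta), np.sin(theta)])
        w = w0[:, None] + evecs @ (radii[:, None] * circ)  # (y, x) rows
        return np.stack([w[1], w[0]], axis=1)  # -> (x, y)

    def to_dict(self) -> dict:
        return {
            "center_mm": self.center.tolist(),
            "semi_axes_mm": self.semi_axes.tolist(),
            "orientation": self.orientation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Ellipsoid":
        return cls(
            np.asarray(d["center_mm"]),
            np.asarray(d["semi_axes_mm"]),
            np.asarray(d["orientation"]),
        )


@dataclass
class SliceContours:
    """Closed polygons on one sweep slice; vertices are (x, y) in mm."""

    position: float
    polygons: list

    def __post_init__(self):
        checked = []
        for poly in self.polygons:
            v = np.asarray(poly, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                raise DataError("each contour needs >= 3 (x, y) vertices")
            if not shapely.Polygon(v).is_valid:
                raise DataError(
                    f"contour at slice {self.position} mm is not a simple polygon"
                )
            checked.append(v)
        self.polygons = checked


@dataclass
class ContourStack:
    """Per-slice closed tumour contours at strictly increasing slice positions."""

    slices: list  # list[SliceContours]

    def __post_init__(self):
        pos = [s.position for s in self.slices]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise DataError("slice positions must be strictly increasing")

    def __len__(self) -> int:
        return len(self.slices)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.slices])

    def points3d(self) -> np.ndarray:
        """All contour vertices as (n, 3) world (z, y, x) points."""
        pts = []
        for s in self.slices:
            for poly in s.polygons:
                z = np.full(len(poly), s.position)
                pts.append(np.stack([z, poly[:, 1], poly[:, 0]], axis=1))
        if not pts:
            return np.empty((0, 3))
        return np.concatenate(pts)


@dataclass
class VoxelMask:
    """Boolean voxel grid sharing the geometry of the volume it selects from."""

    data: np.ndarray
    voxel_size: tuple
    origin: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 3:
            raise GeometryError("mask must be 3-D")

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.count * float(np.prod(self.voxel_size))

    def matches(self, other_shape, other_voxel_size) -> bool:
        return self.data.shape == tuple(other_shape) and np.allclose(
            self.voxel_size, other_voxel_size
        )


def _voxel_centers_1d(n: int, step: float, origin: float = 0.0) -> np.ndarray:
    return origin + np.arange(n) * step


def rasterize_contours(
    stack: ContourStack, grid_shape: tuple, voxel_size: tuple
) -> VoxelMask:
    """Voxelize a contour stack: a voxel is in-mask iff its centre lies inside
    (or on) a polygon of the matching slice.

    Each contour's slice position must land within half a slice step of a
    grid slice.  Slices without a contour contribute nothing.
    """
    S, R, C = grid_shape
    dz, dy, dx = voxel_size
    mask = np.zeros(grid_shape, dtype=bool)
    if len(stack) == 0:
        logger.warning("rasterize_contours: empty contour stack -> empty mask")
        return VoxelMask(mask, tuple(voxel_size))

    ys = _voxel_centers_1d(R, dy)
    xs = _voxel_centers_1d(C, dx)
    for sl in stack.slices:
        k = int(round(sl.position / dz))
        if not (0 <= k < S) or abs(sl.position - k * dz) > dz / 2 + 1e-9:
            raise GeometryError(
                f"contour at {sl.position} mm does not match any slice of the "
                f"volume (step {dz} mm, {S} slices)"
            )
        for poly in sl.polygons:
            geom = shapely.Polygon(poly)
            x0, y0, x1, y1 = geom.bounds
            j = np.nonzero((ys >= y0 - dy) & (ys <= y1 + dy))[0]
            i = np.nonzero((xs >= x0 - dx) & (xs <= x1 + dx))[0]
            if j.size == 0 or i.size == 0:
                continue
            X, Y = np.meshgrid(xs[i], ys[j])
            # intersects == inside-or-on-boundary for points
            inside = shapely.intersects_xy(geom, X.ravel(), Y.ravel())
            mask[k, j[0] : j[-1] + 1, i[0] : i[-1] + 1] |= inside.reshape(
                j.size, i.size
            )
    return VoxelMask(mask, tuple(voxel_size))


def mvee(
    points: np.ndarray,
    tolerance: float = 1e-6,
    max_iter: int = 10_000,
    initial_weights: np.ndarray | None = None,
) -> Ellipsoid:
    """Minimum-volume enclosing ellipsoid of a 3-D point set.

    Solves the dual D-optimal design problem by Khachiyan-type iterative
    reweighting with away steps (Wolfe–Atwood), which converges linearly and
    reaches tight tolerances in a few hundred sweeps.  The returned ellipsoid
    is inflated by at most ``1 + tolerance`` so that every input point is
    contained exactly.

    Parameters
    ----------
    points : (n, 3) array
        At least 4 affinely independent points.
    tolerance : float
        Relative duality-gap tolerance; also bounds the inflation applied
        for exact containment.
    max_iter : int
        Hard iteration cap; exceeding it raises rather than returning a
        silently unconverged fit.
    initial_weights : (n,) array, optional
        Starting design weights (positive, summing to 1).  The optimum is
        unique, so different starts agree; the argument exists to verify
        that.

    Raises
    ------
    DegenerateGeometryError
        If the points are affinely rank-deficient (coplanar/collinear).
    GeometryError
        If the iteration cap is reached before convergence.
    """
    P = np.asarray(points, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("points must be an (n, 3) array")
    n, d = P.shape
    if n < d + 1:
        raise DegenerateGeometryError(
            f"need at least {d + 1} points, got {n}", rank=min(n - 1, d)
        )
    rank = np.linalg.matrix_rank(P - P.mean(axis=0), tol=1e-9 * max(1.0, np.abs(P).max()))
    if rank < d:
        raise DegenerateGeometryError(
            f"point set is affinely rank-deficient (rank {rank} < {d}): "
            "coplanar or collinear points admit no full ellipsoid",
            rank=int(rank),
        )

    Q = np.column_stack([P, np.ones(n)])  # lifted points, (n, d+1)
    if initial_weights is None:
        u = np.full(n, 1.0 / n)
    else:
        u = np.asarray(initial_weights, dtype=float)
        if u.shape != (n,) or np.any(u < 0) or not np.isclose(u.sum(), 1.0):
            raise ConfigurationError("initial_weights must be a probability vector")
        u = u / u.sum()

    dp1 = d + 1
    for _ in range(max_iter):
        X = Q.T @ (Q * u[:, None])  # (d+1, d+1) design matrix
        M = np.einsum("ij,ji->i", Q, np.linalg.solve(X, Q.T))
        j_plus = int(np.argmax(M))
        e_plus = M[j_plus] - dp1
        support = u > 1e-12
        M_sup = np.where(support, M, np.inf)
        j_minus = int(np.argmin(M_sup))
        e_minus = dp1 - M_sup[j_minus]
        if max(e_plus, e_minus) <= tolerance * dp1:
            break
        if e_plus >= e_minus:
            step = e_plus / (dp1 * (M[j_plus] - 1.0))
            u *= 1.0 - step
            u[j_plus] += step
        else:
            beta = e_minus / (dp1 * (M[j_minus] - 1.0))
            beta = min(beta, u[j_minus] / (1.0 - u[j_minus]))
            u *= 1.0 + beta
            u[j_minus] -= beta
        u = np.maximum(u, 0.0)
        u /= u.sum()
    else:
        raise GeometryError(
            f"MVEE did not converge within {max_iter} iterations "
            f"(gap {max(e_plus, e_minus):.2e})"
        )

    c = P.T @ u
    Sigma = (P * u[:, None]).T @ P - np.outer(c, c)
    A = np.linalg.inv(Sigma) / d
    # inflate minimally so containment is exact, not just within tolerance
    # (the extra 1e-12 absorbs round-off in the eigendecomposition below)
    diff = P - c
    m = float(np.max(np.einsum("ij,jk,ik->i", diff, A, diff)))
    A /= max(m, 1.0) * (1.0 + 1e-12)
    evals, evecs = np.linalg.eigh(A)
    semi_axes = 1.0 / np.sqrt(evals)
    if np.linalg.det(evecs) < 0:
        evecs = evecs.copy()
        evecs[:, 0] = -evecs[:, 0]
    return Ellipsoid(center=c, semi_axes=semi_axes, orientation=evecs)


def extend_ellipsoid(e: Ellipsoid, factor: float = 1.2) -> Ellipsoid:
    """Scale every semi-axis by *factor* (>= 1) about the same centre.

    The default 1.2 defines the peri-tumoral extension ellipsoid; the
    enclosed volume grows by factor^3.
    """
    if factor < 1.0:
        raise ConfigurationError(f"extension factor must be >= 1, got {factor}")
    return e.scaled(factor)


def ellipsoid_mask(e: Ellipsoid, grid_shape: tuple, voxel_size: tuple) -> VoxelMask:
    """Voxels whose centres fall inside the ellipsoid."""
    S, R, C = grid_shape
    dz, dy, dx = voxel_size
    z = _voxel_centers_1d(S, dz)[:, None, None]
    y = _voxel_centers_1d(R, dy)[None, :, None]
    x = _voxel_centers_1d(C, dx)[None, None, :]
    A = e.quadratic_form
    u = z - e.center[0]
    v = y - e.center[1]
    w = x - e.center[2]
    q = (
        A[0, 0] * u * u + A[1, 1] * v * v + A[2, 2] * w * w
        + 2 * A[0, 1] * u * v + 2 * A[0, 2] * u * w + 2 * A[1, 2] * v * w
    )
    return VoxelMask(q <= 1.0, tuple(voxel_size))


def surrounding_mask(extended: Ellipsoid, tumour: VoxelMask) -> VoxelMask:
    """Peri-tumoral region: inside the extension ellipsoid, outside the tumour.

    If the extension ellipsoid spills past the volume bounds it is clipped;
    a warning reports the clipped volume fraction.
    """
    grid_shape = tumour.data.shape
    dz, dy, dx = tumour.voxel_size
    inside = ellipsoid_mask(extended, grid_shape, tumour.voxel_size)
    # bounding-box check for clipping against the voxel-centre lattice
    extents = (np.array(grid_shape) - 1) * np.array(tumour.voxel_size)
    half_widths = np.sqrt(((extended.orientation * extended.semi_axes) ** 2).sum(axis=1))
    lo = extended.center - half_widths
    hi = extended.center + half_widths
    if np.any(lo < -1e-9) or np.any(hi > extents + 1e-9):
        covered = inside.count * float(np.prod(tumour.voxel_size))
        clipped_fraction = max(0.0, 1.0 - covered / extended.volume)
        logger.warning(
            "extension ellipsoid exceeds the volume bounds; ~%.1f%% of its "
            "volume clipped",
            100 * clipped_fraction,
        )
    out = inside.data & ~tumour.data
    return VoxelMask(out, tuple(tumour.voxel_size))


def mirror_roi(
    e: Ellipsoid,
    tumour: VoxelMask,
    target_grid_shape: tuple,
    *,
    axis: int = 2,
    plane: float | None = None,
) -> tuple:
    """Reflect an ROI across a sagittal plane into the contralateral frame.

    Parameters
    ----------
    e, tumour : the ROI to mirror (same geometry).
    target_grid_shape : shape of the contralateral volume (must match the
        source shape so the voxel mask can be flipped index-wise).
    axis : world axis of the mirror normal; default 2, the lateral (column)
        axis.
    plane : mirror plane coordinate in mm; default the volume midline.

    Returns
    -------
    (Ellipsoid, VoxelMask)
    """
    if tuple(target_grid_shape) != tumour.data.shape:
        raise GeometryError(
            "mirroring requires matching source/target grids "
            f"({tumour.data.shape} vs {tuple(target_grid_shape)})"
        )
    step = tumour.voxel_size[axis]
    n = tumour.data.shape[axis]
    if plane is None:
        plane = (n - 1) * step / 2.0
    center = e.center.copy()
    center[axis] = 2.0 * plane - center[axis]
    S = np.eye(3)
    S[axis, axis] = -1.0
    R = S @ e.orientation @ S  # conjugation keeps det = +1
    mirrored_e = Ellipsoid(center, e.semi_axes.copy(), R)

    extents = (np.array(tumour.data.shape) - 1) * np.array(tumour.voxel_size)
    half_widths = np.sqrt(((mirrored_e.orientation * mirrored_e.semi_axes) ** 2).sum(axis=1))
    if np.any(mirrored_e.center - half_widths < -1e-9) or np.any(
        mirrored_e.center + half_widths > extents + 1e-9
    ):
        raise GeometryError("mirrored ROI falls outside the target volume")

    # index-wise flip mirrors about the midline; shift if the plane is offset
    flipped = np.flip(tumour.data, axis=axis)
    offset = 2.0 * plane - (n - 1) * step  # mm shift of the flipped lattice
    shift_vox = offset / step
    if abs(shift_vox - round(shift_vox)) > 1e-6:
        raise GeometryError(
            "mirror plane must sit on a half-voxel boundary of the lattice "
            f"(offset {offset} mm, step {step} mm)"
        )
    shift = int(round(shift_vox))
    if shift:
        rolled = np.zeros_like(flipped)
        src = [slice(None)] * flipped.ndim
        dst = [slice(None)] * flipped.ndim
        if shift > 0:
            src[axis], dst[axis] = slice(0, n - shift), slice(shift, n)
        else:
            src[axis], dst[axis] = slice(-shift, n), slice(0, n + shift)
        rolled[tuple(dst)] = flipped[tuple(src)]
        flipped = rolled
    return mirrored_e, VoxelMask(flipped, tuple(tumour.voxel_size))
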