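"""Coordinate frames, affine transforms, label sampling, oblique reslicing.

World coordinates are RAS millimetres throughout; voxel indices are 0-based
and affines map voxel centers to world mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .core import RigidTransform, VolumeImage


def apply_transform(points, transform: RigidTransform) -> np.ndarray:
    """Apply a homogeneous world-to-world transform to points (mm).

    Accepts a single 3-vector or an (N, 3) array; returns the same shape.
    Used to map post-implant contact picks into the pre-operative frame.
    """
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    if not np.isfinite(pts).all():
        raise ValueError("points contain non-finite coordinates")
    out = pts @ transform.matrix[:3, :3].T + transform.matrix[:3, 3]
    return out[0] if single else out


def voxel_to_world(indices, vol: VolumeImage) -> np.ndarray:
    """Continuous voxel index -> world mm (voxel centers)."""
    idx = np.asarray(indices, dtype=float)
    single = idx.ndim == 1
    idx = idx.reshape(-1, 3)
    out = idx @ vol.affine[:3, :3].T + vol.affine[:3, 3]
    return out[0] if single else out


def world_to_voxel(points, vol: VolumeImage) -> np.ndarray:
    """World mm -> continuous voxel index; out-of-grid values are legal."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3)
    inv = vol.inverse_affine
    out = pts @ inv[:3, :3].T + inv[:3, 3]
    return out[0] if single else out


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # nearest voxel center, half-away-from-zero on each axis
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def sample_label(vol: VolumeImage, points):
    """Label of the nearest voxel center; 0 (background) outside the grid.

    Accepts a single point or an (N, 3) array of world-mm points.
    """
    if not vol.is_label_volume():
        raise ValueError("sample_label requires an integer label volume")
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    idx = _round_half_away(world_to_voxel(pts, vol).reshape(-1, 3)).astype(np.int64)
    shape = np.array(vol.shape)
    inside = ((idx >= 0) & (idx < shape)).all(axis=1)
    out = np.zeros(len(idx), dtype=vol.grid.dtype)
    if inside.any():
        ii = idx[inside]
        out[inside] = vol.grid[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out[0] if single else out


def sample_intensity(vol: VolumeImage, points) -> np.ndarray:
    """Trilinear interpolation of an intensity volume at world-mm points."""
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    idx = world_to_voxel(pts, vol).reshape(-1, 3)
    vals = map_coordinates(vol.grid.astype(float), idx.T, order=1, mode="constant", cval=0.0)
    return vals[0] if single else vals


@dataclass
class ObliqueSlice:
    """A 2-D reslice with its pixel-to-world mapping.

    ``image[row, col]`` samples world point ``origin + col*spacing*u_axis +
    row*spacing*v_axis``; ``u_axis`` runs along the trajectory and ``v_axis``
    is the in-plane direction closest to world inferior-superior, giving the
    coronal-like view along a depth-electrode shaft.
    """

    image: np.ndarray
    origin: np.ndarray
    u_axis: np.ndarray
    v_axis: np.ndarray
    spacing: float

    def pixel_to_world(self, row, col) -> np.ndarray:
        return (
            self.origin
            + np.multiply.outer(np.asarray(col, dtype=float) * self.spacing, self.u_axis)
            + np.multiply.outer(np.asarray(row, dtype=float) * self.spacing, self.v_axis)
        )

    def world_to_pixel(self, point) -> tuple:
        d = np.asarray(point, dtype=float) - self.origin
        return float(d @ self.v_axis) / self.spacing, float(d @ self.u_axis) / self.spacing


def trajectory_plane_axes(p0, p1) -> tuple:
    """In-plane axes for a reslice: u along the trajectory, v the in-plane
    direction closest to world superior (+z); falls back to anterior (+y)
    for superior-inferior trajectories."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    d = p1 - p0
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("trajectory endpoints coincide")
    u = d / norm
    for ref in (np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 0.0])):
        v = ref - (ref @ u) * u
        vn = np.linalg.norm(v)
        if vn > 1e-8:
            return u, v / vn
    raise AssertionError("unreachable: no in-plane axis found")


def reslice_along_trajectory(
    vol: VolumeImage,
    p0,
    p1,
    width_mm: float = 40.0,
    spacing_mm: float = 1.0,
    pad_mm: float = 0.0,
) -> ObliqueSlice:
    """Re-slice the volume along the p0 -> p1 trajectory.

    The plane contains the segment; columns run along the trajectory
    (optionally extended by ``pad_mm`` on each end), rows span ``width_mm``
    perpendicular to it.  Label volumes are sampled nearest-neighbour,
    intensity volumes trilinearly.  ``p0`` maps to pixel
    (row=(n_rows-1)/2, col=pad_mm/spacing_mm) exactly.
    """
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    u, v = trajectory_plane_axes(p0, p1)
    length = float(np.linalg.norm(p1 - p0))
    n_u = int(np.floor((length + 2 * pad_mm) / spacing_mm + 1e-9)) + 1
    n_half = int(np.floor(width_mm / 2.0 / spacing_mm + 1e-9))
    us = -pad_mm + np.arange(n_u) * spacing_mm
    vs = (np.arange(-n_half, n_half + 1)) * spacing_mm
    world = (
        p0[None, None, :]
        + us[None, :, None] * u[None, None, :]
        + vs[:, None, None] * v[None, None, :]
    ).reshape(-1, 3)
    if vol.is_label_volume():
        img = sample_label(vol, world)
    else:
        img = sample_intensity(vol, world)
    img = img.reshape(len(vs), len(us))
    origin = p0 - pad_mm * u + vs[0] * v
    return ObliqueSlice(image=img, origin=origin, u_axis=u, v_axis=v, spacing=spacing_mm)
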