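"""Electrode Volume Labelling (EVL).

Builds a watertight enclosing surface for every brain-region label of the
parcellation, tests contact membership against those surfaces by ray
parity, and classifies each contact as cortical grey, subcortical, white,
on the pial surface, or outside the brain.

The default ``voxelized`` construction extracts the exact boundary of the
union of label-voxel cubes (faces between a labelled voxel and anything
else), so membership agrees with a direct voxel-mask lookup everywhere away
from the boundary.  The ``alpha_complex`` construction instead keeps the
Delaunay tetrahedra of the voxel centers with circumradius below alpha and
uses their once-counted boundary faces; it is smoother but only guaranteed
to enclose ~all voxel centers, and is practical for small structures only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .core import (
    CORTICAL_GREY,
    SUBCORTICAL_GREY,
    WHITE,
    Electrode,
    LabelTable,
    SurfaceMesh,
    VolumeImage,
)

TISSUE_CLASSES = ("cortical_grey", "subcortical", "white", "pial_surface", "outside")

# perturbation applied to the ray origin so axis-aligned query points never
# thread triangle edges exactly (irrational offsets; << any voxel size)
_RAY_EPS = np.array([0.0, 1.6180339887e-7, 2.7182818284e-7])


# ---------------------------------------------------------------------------
# voxel-cube boundary extraction


def _voxel_boundary_quads(mask: np.ndarray):
    """Boundary quads of the voxel-cube union, as integer corner coordinates
    scaled by 2 (corner (i-1/2, j, k) -> (2i-1, 2j, 2k))."""
    quads = []
    # corner offsets (x2) of a cube face, per axis, for the -side and +side
    face_corners = {
        0: [(-1, -1, -1), (-1, 1, -1), (-1, 1, 1), (-1, -1, 1)],
        1: [(-1, -1, -1), (-1, -1, 1), (1, -1, 1), (1, -1, -1)],
        2: [(-1, -1, -1), (1, -1, -1), (1, 1, -1), (-1, 1, -1)],
    }
    padded = np.pad(mask, 1)
    for axis in range(3):
        for sign in (-1, 1):
            # np.roll(padded, s, axis)[i] == padded[i - s]: with s=+1 the
            # comparison exposes voxels whose neighbour at index-1 is empty
            # (face on the -axis side); s=-1 exposes the +axis side.
            neighbor = np.roll(padded, sign, axis=axis)
            exposed = padded & ~neighbor
            ii = np.argwhere(exposed) - 1  # unpad
            if not len(ii):
                continue
            base = 2 * ii  # voxel center x2
            corners = np.array(face_corners[axis])
            if sign == -1:
                # face on the +axis side: mirror the -side template and flip
                # the winding so the normal stays outward
                corners = corners.copy()
                corners[:, axis] = 1
                corners = corners[::-1]
            quad = base[:, None, :] + corners[None, :, :]
            quads.append(quad)
    if not quads:
        raise ValueError("mask has no voxels")
    return np.concatenate(quads, axis=0)


def voxel_boundary_mesh(mask: np.ndarray, affine: np.ndarray) -> SurfaceMesh:
    """Exact closed boundary surface of a voxel mask, in world mm.

    Every voxel center with ``mask`` True is strictly inside the surface and
    the enclosed volume equals (voxel count) x (voxel volume).
    """
    quads = _voxel_boundary_quads(mask)  # (Q, 4, 3) int, x2 scale
    flat = quads.reshape(-1, 3)
    verts_i, inverse = np.unique(flat, axis=0, return_inverse=True)
    qidx = inverse.reshape(-1, 4)
    # two triangles per quad; order chosen so normals point outward
    faces = np.concatenate([qidx[:, [2, 1, 0]], qidx[:, [3, 2, 0]]], axis=0)
    verts_vox = verts_i.astype(float) / 2.0
    verts_world = verts_vox @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return SurfaceMesh(vertices=verts_world, faces=faces)


def is_closed_surface(mesh: SurfaceMesh) -> bool:
    """Every edge shared by an even number (>=2) of faces: the surface
    bounds a volume (voxel unions touching along an edge give 4-fold
    edges while still enclosing their voxels)."""
    if not mesh.n_faces:
        return False
    f = mesh.faces
    e = np.vstack([f[:, [0, 1]], f[:, [1, 2]], f[:, [2, 0]]])
    e.sort(axis=1)
    _, counts = np.unique(e, axis=0, return_counts=True)
    return bool(((counts % 2 == 0) & (counts >= 2)).all())


# ---------------------------------------------------------------------------
# ray-parity membership


class MeshMembership:
    """Point-in-closed-mesh tests by +x ray parity with a (y,z) spatial bin.

    Boundary points (within ``surface_tol``) count as inside.
    """

    def __init__(self, mesh: SurfaceMesh, bin_mm: float = 4.0):
        if not is_closed_surface(mesh):
            raise ValueError("membership tests require a closed (watertight) surface")
        self.tri = mesh.vertices[mesh.faces]  # (M, 3, 3)
        self.bbox_min = mesh.vertices.min(axis=0)
        self.bbox_max = mesh.vertices.max(axis=0)
        self.bin_mm = float(bin_mm)
        yz = self.tri[:, :, 1:]  # (M, 3, 2)
        self._lo = np.floor((yz.min(axis=1) - self.bbox_min[1:]) / bin_mm).astype(int)
        self._hi = np.floor((yz.max(axis=1) - self.bbox_min[1:]) / bin_mm).astype(int)
        self._cells: dict = {}
        for t in range(len(self.tri)):
            for cy in range(self._lo[t, 0], self._hi[t, 0] + 1):
                for cz in range(self._lo[t, 1], self._hi[t, 1] + 1):
                    self._cells.setdefault((cy, cz), []).append(t)
        self._cells = {k: np.array(v) for k, v in self._cells.items()}

    def _candidates(self, y: float, z: float) -> np.ndarray:
        cy = int(np.floor((y - self.bbox_min[1]) / self.bin_mm))
        cz = int(np.floor((z - self.bbox_min[2]) / self.bin_mm))
        return self._cells.get((cy, cz), np.empty(0, dtype=int))

    def contains(self, points, surface_tol: float = 1e-9) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = pts.reshape(-1, 3)
        out = np.zeros(len(pts), dtype=bool)
        inside_box = ((pts >= self.bbox_min - surface_tol) & (pts <= self.bbox_max + surface_tol)).all(axis=1)
        for i in np.flatnonzero(inside_box):
            out[i] = self._contains_one(pts[i], surface_tol)
        return out[0] if single else out

    def _contains_one(self, p: np.ndarray, surface_tol: float) -> bool:
        cand = self._candidates(p[1], p[2])
        if surface_tol > 0 and len(cand) and self._on_surface(p, cand, surface_tol):
            return True
        q = p + _RAY_EPS
        cand = self._candidates(q[1], q[2])
        if not len(cand):
            return False
        tri = self.tri[cand]
        a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
        e1 = (b - a)[:, 1:]
        e2 = (c - a)[:, 1:]
        rhs = q[1:] - a[:, 1:]
        det = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
        ok = np.abs(det) > 1e-14
        s = np.where(ok, (rhs[:, 0] * e2[:, 1] - rhs[:, 1] * e2[:, 0]) / np.where(ok, det, 1.0), -1)
        t = np.where(ok, (e1[:, 0] * rhs[:, 1] - e1[:, 1] * rhs[:, 0]) / np.where(ok, det, 1.0), -1)
        hit = ok & (s >= 0) & (t >= 0) & (s + t <= 1)
        if not hit.any():
            return False
        x_hit = a[hit, 0] + s[hit] * (b[hit, 0] - a[hit, 0]) + t[hit] * (c[hit, 0] - a[hit, 0])
        return bool(np.count_nonzero(x_hit > q[0]) % 2)

    def _on_surface(self, p: np.ndarray, cand: np.ndarray, tol: float) -> bool:
        import trimesh.triangles

        tri = self.tri[cand]
        closest = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
        d2 = ((closest - p) ** 2).sum(axis=1)
        return bool((d2 <= tol * tol).any())


# ---------------------------------------------------------------------------
# enclosing volumes


@dataclass
class EnclosingVolume:
    label: int
    boundary: SurfaceMesh
    method: str
    _membership: Optional[MeshMembership] = field(default=None, repr=False, compare=False)

    @property
    def membership(self) -> MeshMembership:
        if self._membership is None:
            self._membership = MeshMembership(self.boundary)
        return self._membership

    def volume_mm3(self) -> float:
        tri = self.boundary.vertices[self.boundary.faces]
        return float(abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)


def _alpha_complex_mesh(points: np.ndarray, alpha: float) -> SurfaceMesh:
    from scipy.spatial import Delaunay

    dela = Delaunay(points)
    tets = dela.simplices
    # circumradius of each tetrahedron
    a, b, c, d = (points[tets[:, i]] for i in range(4))
    ba, ca, da = b - a, c - a, d - a
    det = np.einsum("ij,ij->i", ba, np.cross(ca, da))
    keepable = np.abs(det) > 1e-12
    num = (
        np.einsum("ij,ij->i", da, da)[:, None] * np.cross(ba, ca)
        + np.einsum("ij,ij->i", ca, ca)[:, None] * np.cross(da, ba)
        + np.einsum("ij,ij->i", ba, ba)[:, None] * np.cross(ca, da)
    )
    circ = np.full(len(tets), np.inf)
    circ[keepable] = np.linalg.norm(num[keepable], axis=1) / (2 * np.abs(det[keepable]))
    keep = tets[circ <= alpha]
    if not len(keep):
        raise ValueError("alpha too small: no tetrahedra retained")
    faces = np.concatenate(
        [keep[:, [0, 1, 2]], keep[:, [0, 1, 3]], keep[:, [0, 2, 3]], keep[:, [1, 2, 3]]]
    )
    faces_sorted = np.sort(faces, axis=1)
    uniq, idx, counts = np.unique(faces_sorted, axis=0, return_index=True, return_counts=True)
    boundary = faces[idx[counts == 1]]
    used = np.unique(boundary)
    remap = np.zeros(len(points), dtype=np.int64)
    remap[used] = np.arange(len(used))
    return SurfaceMesh(vertices=points[used], faces=remap[boundary])


def build_enclosing_volume(
    parcellation: VolumeImage,
    label: int,
    method: str = "voxelized",
    alpha: Optional[float] = None,
) -> EnclosingVolume:
    """Watertight enclosing surface for one parcellation label."""
    mask = parcellation.grid == label
    if not mask.any():
        raise ValueError(f"label {label} not present in the parcellation")
    if method == "voxelized":
        mesh = voxel_boundary_mesh(mask, parcellation.affine)
    elif method == "alpha_complex":
        idx = np.argwhere(mask).astype(float)
        pts = idx @ parcellation.affine[:3, :3].T + parcellation.affine[:3, 3]
        voxel = float(np.cbrt(abs(np.linalg.det(parcellation.affine[:3, :3]))))
        mesh = _alpha_complex_mesh(pts, alpha if alpha is not None else 2.0 * voxel)
    else:
        raise ValueError(f"unknown construction method {method!r}")
    if not is_closed_surface(mesh):
        raise ValueError(f"enclosing surface for label {label} is not closed")
    return EnclosingVolume(label=int(label), boundary=mesh, method=method)


def point_in_volume(points, ev: EnclosingVolume):
    """Membership of world point(s) in an enclosing volume (boundary counts
    as inside)."""
    return ev.membership.contains(points)


def build_enclosing_volumes(
    parcellation: VolumeImage,
    labels: LabelTable,
    categories=(SUBCORTICAL_GREY, CORTICAL_GREY, WHITE),
    method: str = "voxelized",
) -> dict:
    """Enclosing volumes for every present label in the given categories."""
    present = set(np.unique(parcellation.grid).tolist())
    out = {}
    for lid in labels.ids_in_category(*categories):
        if lid in present:
            out[lid] = build_enclosing_volume(parcellation, lid, method=method)
    return out


@dataclass
class TissueClassification:
    electrode: str
    contact: str
    tissue_class: str
    label: int
    label_name: str


def classify_points(
    points,
    parcellation: VolumeImage,
    labels: LabelTable,
    pial: SurfaceMesh,
    volumes: Optional[dict] = None,
    method: str = "voxelized",
):
    """Five-way tissue class for world points, first match wins:
    subcortical volume > cortical volume > white volume > inside the pial
    hull (surface contact) > outside the brain.

    Returns (classes, label ids) as arrays.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    if volumes is None:
        volumes = build_enclosing_volumes(parcellation, labels, method=method)
    pial_member = MeshMembership(pial)

    classes = np.array(["outside"] * len(pts), dtype=object)
    label_out = np.zeros(len(pts), dtype=np.int64)
    unresolved = np.ones(len(pts), dtype=bool)
    tiers = (
        (SUBCORTICAL_GREY, "subcortical"),
        (CORTICAL_GREY, "cortical_grey"),
        (WHITE, "white"),
    )
    for category, class_name in tiers:
        for lid in labels.ids_in_category(category):
            ev = volumes.get(lid)
            if ev is None or not unresolved.any():
                continue
            sel = np.flatnonzero(unresolved)
            hit = ev.membership.contains(pts[sel])
            got = sel[hit]
            classes[got] = class_name
            label_out[got] = lid if class_name != "white" else lid
            unresolved[got] = False
    if unresolved.any():
        sel = np.flatnonzero(unresolved)
        hit = pial_member.contains(pts[sel])
        classes[sel[hit]] = "pial_surface"
    # white has a label id but pial_surface/outside report 0
    for i in range(len(pts)):
        if classes[i] in ("pial_surface", "outside"):
            label_out[i] = 0
    return classes, label_out


def classify_contacts(
    electrode: Electrode,
    parcellation: VolumeImage,
    labels: LabelTable,
    pial: SurfaceMesh,
    volumes: Optional[dict] = None,
    method: str = "voxelized",
) -> list:
    """Per-contact tissue classification for one electrode."""
    classes, lids = classify_points(
        electrode.positions, parcellation, labels, pial, volumes=volumes, method=method
    )
    out = []
    for contact, cls, lid in zip(electrode.contacts, classes, lids):
        name = labels.name(lid) if lid in labels else "n/a"
        if cls in ("pial_surface", "outside"):
            name = "n/a"
        out.append(
            TissueClassification(
                electrode=electrode.name,
                contact=contact.label,
                tissue_class=str(cls),
                label=int(lid),
                label_name=name,
            )
        )
    return out


def export_label_meshes(
    parcellation: VolumeImage,
    labels: LabelTable,
    out_dir,
    method: str = "voxelized",
) -> list:
    """One STL per non-background label present in the parcellation,
    named ``<id>_<name>.stl``."""
    from .formats_io import write_stl

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    present = [int(v) for v in np.unique(parcellation.grid) if v != 0]
    if not present:
        raise ValueError("parcellation contains no non-background labels")
    paths = []
    for lid in present:
        ev = build_enclosing_volume(parcellation, lid, method=method)
        name = labels.name(lid) if lid in labels else str(lid)
        path = out_dir / f"{lid}_{name}.stl"
        write_stl(ev.boundary, path)
        paths.append(path)
    return paths
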