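"""Anatomical measurements around localized contacts.

Distances are Euclidean to the nearest reconstructed *vertex* of the pial
and white surfaces (the field's operational definition of the orthogonal
grey/white distance); the local cortical-column direction is approximated
by the area-weighted vertex normal at that nearest vertex.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import Electrode, SurfaceMesh


@dataclass
class ContactMeasurements:
    electrode: str
    contact: str
    midpoint: Optional[np.ndarray]  # midpoint of the pair starting here
    dist_pial: float
    dist_white: float
    intercontact: Optional[float]  # to the next contact; None for the last
    angle_deg: Optional[float]


def bipolar_midpoints(electrode: Electrode) -> np.ndarray:
    """Midpoints of adjacent contact pairs, in order; empty for <2 contacts."""
    pos = electrode.positions
    if len(pos) < 2:
        return np.empty((0, 3))
    return (pos[:-1] + pos[1:]) / 2.0


def nearest_vertex(point, mesh: SurfaceMesh) -> tuple:
    """(vertex index, distance mm) of the mesh vertex nearest the point.

    Exhaustive minimum over all vertices; ties resolve to the lowest index.
    """
    if mesh.n_vertices == 0:
        raise ValueError("mesh has no vertices")
    d2 = ((mesh.vertices - np.asarray(point, dtype=float)) ** 2).sum(axis=1)
    idx = int(np.argmin(d2))
    return idx, float(np.sqrt(d2[idx]))


def nearest_surface_point_distance(point, mesh: SurfaceMesh) -> float:
    """Distance from a point to the closest point on any triangle of the mesh
    (continuous surface, not just vertices)."""
    import trimesh.triangles

    if mesh.n_faces == 0:
        raise ValueError("mesh has no faces")
    point = np.asarray(point, dtype=float)
    tri = mesh.vertices[mesh.faces]
    closest = trimesh.triangles.closest_point(tri, np.repeat(point[None, :], len(tri), axis=0))
    return float(np.linalg.norm(closest - point, axis=1).min())


def grey_white_distances(
    midpoint, pial: SurfaceMesh, white: SurfaceMesh, method: str = "vertex"
) -> tuple:
    """Distance from a (bipolar-pair) midpoint to the pial and white surfaces.

    ``method="vertex"`` (default) measures to the nearest mesh vertex — the
    field's operational definition; it overestimates by up to roughly half an
    edge length.  ``method="surface"`` measures to the closest point on the
    continuous triangulated surface.
    """
    if method == "vertex":
        return nearest_vertex(midpoint, pial)[1], nearest_vertex(midpoint, white)[1]
    if method == "surface":
        return (
            nearest_surface_point_distance(midpoint, pial),
            nearest_surface_point_distance(midpoint, white),
        )
    raise ValueError(f"unknown distance method: {method!r}")


def intercontact_distances(electrode: Electrode) -> np.ndarray:
    """Euclidean distances between consecutive contacts (length n-1)."""
    pos = electrode.positions
    if len(pos) < 2:
        return np.empty(0)
    return np.linalg.norm(np.diff(pos, axis=0), axis=1)


def vertex_normals(mesh: SurfaceMesh) -> np.ndarray:
    """Area-weighted vertex normals (unit vectors)."""
    tri = mesh.vertices[mesh.faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # |fn| = 2*area
    vn = np.zeros_like(mesh.vertices)
    for c in range(3):
        np.add.at(vn, mesh.faces[:, c], fn)
    norms = np.linalg.norm(vn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return vn / norms


def angle_to_cortical_axis(axis, point, mesh: SurfaceMesh, normals=None) -> float:
    """Angle (degrees, in [0, 90]) between the local shaft direction and the
    cortical-column direction, taken as the surface normal at the nearest
    vertex.  0 means the shaft runs along the cortical column."""
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("zero-length contact axis")
    axis = axis / norm
    if normals is None:
        normals = vertex_normals(mesh)
    idx, _ = nearest_vertex(point, mesh)
    cosang = abs(float(axis @ normals[idx]))
    return float(np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0))))


def measure_electrode(
    electrode: Electrode, pial: SurfaceMesh, white: SurfaceMesh
) -> list:
    """Per-contact measurement records: bipolar midpoint (pair starting at
    the contact), grey/white distances of the contact itself, inter-contact
    distance to the next contact, and the shaft angle to the local cortical
    axis."""
    from .ela import contact_axis

    mids = bipolar_midpoints(electrode)
    gaps = intercontact_distances(electrode)
    normals = vertex_normals(pial)
    records = []
    for i, contact in enumerate(electrode.contacts):
        dp, dw = grey_white_distances(contact.position, pial, white)
        axis = contact_axis(electrode, i)
        angle = (
            None
            if axis is None
            else angle_to_cortical_axis(axis, contact.position, pial, normals=normals)
        )
        records.append(
            ContactMeasurements(
                electrode=electrode.name,
                contact=contact.label,
                midpoint=mids[i] if i < len(mids) else None,
                dist_pial=dp,
                dist_white=dw,
                intercontact=float(gaps[i]) if i < len(gaps) else None,
                angle_deg=angle,
            )
        )
    return records


def trajectory_summary(classifications) -> pd.DataFrame:
    """Contact counts per tissue class per electrode, plus a pooled row.

    ``classifications`` is an iterable of TissueClassification records.
    """
    from .evl import TISSUE_CLASSES

    rows = [
        {"electrode": c.electrode, "tissue": c.tissue_class} for c in classifications
    ]
    if not rows:
        return pd.DataFrame(columns=["electrode", *TISSUE_CLASSES, "total"])
    df = pd.DataFrame(rows)
    table = (
        df.groupby(["electrode", "tissue"]).size().unstack(fill_value=0)
    )
    for cls in TISSUE_CLASSES:
        if cls not in table.columns:
            table[cls] = 0
    table = table[list(TISSUE_CLASSES)]
    table["total"] = table.sum(axis=1)
    pooled = table.sum(axis=0).to_frame().T
    pooled.index = ["(all)"]
    out = pd.concat([table, pooled])
    out.index.name = "electrode"
    return out.reset_index()
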