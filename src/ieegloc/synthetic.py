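"""Synthetic labelled head phantom with analytic ground truth.

A spherical "head" stands in for a FreeSurfer reconstruction: a white-matter
ball of radius ``R_white`` containing a few subcortical blobs, surrounded by
a cortical shell up to ``R_pial`` divided into azimuthal wedge labels, and
background outside.  Because every label boundary is analytic, the truth
label of any world point is known exactly, which makes the probabilistic and
volumetric labelling methods quantitatively testable without clinical data.

Label-id scheme: 0 background, 1..K cortical wedges, 100 white matter,
200, 201, ... subcortical blobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    BACKGROUND,
    CORTICAL_GREY,
    SUBCORTICAL_GREY,
    WHITE,
    Contact,
    Electrode,
    LabelEntry,
    LabelTable,
    SurfaceMesh,
    VolumeImage,
)

WHITE_LABEL = 100
SUBCORTICAL_BASE = 200

#: canonical structure names assigned to the synthetic subcortical blobs so
#: the label table parses with the standard name->category rules
_SUBCORTICAL_NAME_POOL = (
    "Left-Hippocampus",
    "Right-Hippocampus",
    "Left-Thalamus",
    "Right-Thalamus",
    "Left-Amygdala",
    "Right-Amygdala",
)

DEFAULT_SUBCORTICAL = (((-20.0, 0.0, 0.0), 8.0), ((20.0, 0.0, 0.0), 8.0))


@dataclass
class SyntheticHead:
    parcellation: VolumeImage
    pial: SurfaceMesh
    white: SurfaceMesh
    labels: LabelTable
    R_pial: float
    R_white: float
    n_wedges: int
    subcortical: tuple

    def truth(self, points) -> np.ndarray:
        """Analytic ground-truth label for world points (vectorized)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = pts.reshape(-1, 3)
        r = np.linalg.norm(pts, axis=1)
        out = np.zeros(len(pts), dtype=np.int32)

        # cortical shell: wedge by azimuth
        az = np.mod(np.arctan2(pts[:, 1], pts[:, 0]), 2 * np.pi)
        wedge = np.minimum(
            np.floor(az / (2 * np.pi / self.n_wedges)).astype(np.int32), self.n_wedges - 1
        ) + 1
        shell = (r >= self.R_white) & (r < self.R_pial)
        out[shell] = wedge[shell]

        # interior: white unless inside a subcortical blob
        interior = r < self.R_white
        out[interior] = WHITE_LABEL
        for i, (center, radius) in enumerate(self.subcortical):
            blob = np.linalg.norm(pts - np.asarray(center), axis=1) < radius
            out[interior & blob] = SUBCORTICAL_BASE + i
        return out[0] if single else out


def _icosphere_mesh(radius: float, subdivisions: int) -> SurfaceMesh:
    import trimesh

    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(vertices=np.asarray(ico.vertices), faces=np.asarray(ico.faces))


def make_head(
    R_pial: float = 60.0,
    R_white: float = 50.0,
    n_wedges: int = 8,
    subcortical=DEFAULT_SUBCORTICAL,
    voxel_mm: float = 1.0,
    mesh_subdivisions: int = 4,
    margin_mm: float = 4.0,
) -> SyntheticHead:
    """Build the labelled spherical head phantom (deterministic).

    The parcellation grid is centered on the world origin with isotropic
    ``voxel_mm`` spacing; pial and white surfaces are icospheres in the same
    frame.  Subcortical blobs must lie strictly inside the white ball so the
    analytic truth stays unambiguous.
    """
    if not 0 < R_white < R_pial:
        raise ValueError("need 0 < R_white < R_pial")
    if n_wedges < 1:
        raise ValueError("n_wedges must be >= 1")
    subcortical = tuple((tuple(map(float, c)), float(rad)) for c, rad in subcortical)
    if len(subcortical) > len(_SUBCORTICAL_NAME_POOL):
        raise ValueError("too many subcortical blobs for the name pool")
    for center, radius in subcortical:
        if np.linalg.norm(center) + radius > R_white:
            raise ValueError(
                f"subcortical blob at {center} r={radius} crosses the white boundary"
            )

    half = int(np.ceil((R_pial + margin_mm) / voxel_mm))
    n = 2 * half + 1
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -half * voxel_mm  # voxel (half,half,half) sits at the world origin

    entries = [LabelEntry(0, "Unknown", BACKGROUND, (0, 0, 0))]
    palette = np.random.default_rng(0)  # colors only; labelling is deterministic
    for k in range(1, n_wedges + 1):
        color = tuple(int(v) for v in palette.integers(40, 255, 3))
        entries.append(LabelEntry(k, f"ctx-wedge-{k:02d}", CORTICAL_GREY, color))
    entries.append(LabelEntry(WHITE_LABEL, "Cerebral-White-Matter", WHITE, (245, 245, 245)))
    for i in range(len(subcortical)):
        entries.append(
            LabelEntry(
                SUBCORTICAL_BASE + i,
                _SUBCORTICAL_NAME_POOL[i],
                SUBCORTICAL_GREY,
                (220, 216, 20),
            )
        )
    labels = LabelTable(entries)

    head = SyntheticHead(
        parcellation=None,  # filled below; truth() needs only the analytic geometry
        pial=_icosphere_mesh(R_pial, mesh_subdivisions),
        white=_icosphere_mesh(R_white, mesh_subdivisions),
        labels=labels,
        R_pial=R_pial,
        R_white=R_white,
        n_wedges=n_wedges,
        subcortical=subcortical,
    )

    xs = np.arange(n, dtype=float) * voxel_mm - half * voxel_mm
    gx, gy, gz = np.meshgrid(xs, xs, xs, indexing="ij")
    centers = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    grid = head.truth(centers).reshape(n, n, n)
    head.parcellation = VolumeImage(grid=grid, affine=affine, frame="scanner_ras")
    return head


def make_depth_electrode(
    head: SyntheticHead,
    entry,
    target,
    n_contacts: int,
    spacing_mm: float = 5.0,
    name: str = "DEPTH",
):
    """Colinear contacts from target toward entry at exact spacing.

    Emulates a clinical sEEG shaft (4-16 contacts, median 5 mm spacing).
    Returns (Electrode, analytic truth label per contact).
    """
    entry = np.asarray(entry, dtype=float)
    target = np.asarray(target, dtype=float)
    if n_contacts < 1:
        raise ValueError("n_contacts must be >= 1")
    d = entry - target
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError("entry and target coincide")
    u = d / norm
    positions = target[None, :] + np.arange(n_contacts)[:, None] * spacing_mm * u
    contacts = [Contact(str(i + 1), p) for i, p in enumerate(positions)]
    electrode = Electrode(name=name, contacts=contacts, kind="depth")
    return electrode, head.truth(positions)


def _tangent_basis(direction: np.ndarray) -> tuple:
    d = direction / np.linalg.norm(direction)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(d @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = np.cross(d, ref)
    t1 /= np.linalg.norm(t1)
    t2 = np.cross(d, t1)
    return d, t1, t2


def make_grid(
    head: SyntheticHead,
    center_direction,
    rows: int,
    cols: int,
    pitch_mm: float = 10.0,
    lift_mm: float = 0.0,
    jitter_sd_mm: float = 0.0,
    seed: int | None = None,
    name: str = "GRID",
) -> Electrode:
    """Planar ECoG grid tangent to the pial sphere, optionally lifted
    outward and jittered to emulate post-surgical brain shift."""
    if rows < 1 or cols < 1:
        raise ValueError("rows and cols must be >= 1")
    if jitter_sd_mm > 0 and seed is None:
        raise ValueError("seed required when jitter_sd_mm > 0")
    d, t1, t2 = _tangent_basis(np.asarray(center_direction, dtype=float))
    center = d * (head.R_pial + lift_mm)
    offsets_r = (np.arange(rows) - (rows - 1) / 2.0) * pitch_mm
    offsets_c = (np.arange(cols) - (cols - 1) / 2.0) * pitch_mm
    positions = (
        center[None, None, :]
        + offsets_r[:, None, None] * t1[None, None, :]
        + offsets_c[None, :, None] * t2[None, None, :]
    ).reshape(-1, 3)
    if jitter_sd_mm > 0:
        rng = np.random.default_rng(seed)
        positions = positions + rng.normal(0.0, jitter_sd_mm, positions.shape)
    contacts = [Contact(str(i + 1), p) for i, p in enumerate(positions)]
    kind = "grid" if rows > 1 and cols > 1 else "strip"
    shape = (rows, cols) if kind == "grid" else None
    return Electrode(name=name, contacts=contacts, kind=kind, grid_shape=shape)


def sample_cortical_points(
    head: SyntheticHead, n: int, margin_mm: float = 2.0, seed: int = 0
) -> tuple:
    """Uniform random points at least ``margin_mm`` inside a cortical wedge.

    The margin is enforced against the pial and white spheres and against
    the azimuthal wedge-boundary half-planes, so the analytic truth label is
    stable within a ball of radius ``margin_mm`` around each point.
    Returns (points (n,3), truth labels (n,)).
    """
    rng = np.random.default_rng(seed)
    wedge_angle = 2 * np.pi / head.n_wedges
    points: list = []
    while len(points) < n:
        p = rng.uniform(-head.R_pial, head.R_pial, size=(4 * n, 3))
        r = np.linalg.norm(p, axis=1)
        ok = (r >= head.R_white + margin_mm) & (r <= head.R_pial - margin_mm)
        az = np.mod(np.arctan2(p[:, 1], p[:, 0]), 2 * np.pi)
        frac = np.mod(az, wedge_angle)
        rho = np.hypot(p[:, 0], p[:, 1])
        # distance to the nearer wedge-boundary half-plane
        d_boundary = rho * np.sin(np.minimum(frac, wedge_angle - frac))
        ok &= d_boundary >= margin_mm
        points.extend(p[ok])
    pts = np.asarray(points[:n])
    return pts, head.truth(pts)


def sample_phantom_points(
    head: SyntheticHead, n: int, margin_mm: float = 1.0, seed: int = 0, extent: float = 1.1
) -> tuple:
    """Uniform random points in the phantom bounding box, all at least
    ``margin_mm`` from every analytic label boundary.  Returns
    (points, truth labels)."""
    rng = np.random.default_rng(seed)
    lim = head.R_pial * extent
    wedge_angle = 2 * np.pi / head.n_wedges
    points: list = []
    while len(points) < n:
        p = rng.uniform(-lim, lim, size=(4 * n, 3))
        r = np.linalg.norm(p, axis=1)
        ok = np.abs(r - head.R_pial) >= margin_mm
        ok &= np.abs(r - head.R_white) >= margin_mm
        for center, radius in head.subcortical:
            ok &= np.abs(np.linalg.norm(p - np.asarray(center), axis=1) - radius) >= margin_mm
        in_shell = (r > head.R_white) & (r < head.R_pial)
        az = np.mod(np.arctan2(p[:, 1], p[:, 0]), 2 * np.pi)
        frac = np.mod(az, wedge_angle)
        rho = np.hypot(p[:, 0], p[:, 1])
        d_boundary = rho * np.sin(np.minimum(frac, wedge_angle - frac))
        ok &= ~in_shell | (d_boundary >= margin_mm)
        points.extend(p[ok])
    pts = np.asarray(points[:n])
    return pts, head.truth(pts)
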