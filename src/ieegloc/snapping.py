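"""Brain-shift correction for grids and strips.

Surface arrays imaged post-operatively are displaced relative to the
pre-operative MRI by intraoperative brain shift.  Snapping restores them to
a smoothed pial surface while constraining the relationships between
contacts: it minimizes

    E(x) = sum_i ||x_i - x_i0||^2
         + lambda * sum_{(i,j) in edges} (||x_i - x_j|| - d_ij0)^2

subject to every contact lying on the target surface, by alternating one
damped Gauss-Seidel sweep of the unconstrained energy with projection of
each contact to its nearest point on the surface.  A backtracking step-size
guard makes the energy trace non-increasing and the whole procedure
deterministic (fixed sweep order = contact order).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Electrode, SurfaceMesh


@dataclass
class SnapParams:
    lambda_deform: float = 1.0   # weight of the neighbour-distance term
    max_iter: int = 200
    tol: float = 1e-6            # stop when the energy improves by less
    smoothing_iters: int = 20    # Taubin iterations for the target surface

    def __post_init__(self) -> None:
        if self.lambda_deform < 0:
            raise ValueError("lambda_deform must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass
class SnapResult:
    positions: np.ndarray            # snapped coordinates (n, 3)
    displacement_mm: np.ndarray      # per contact, from the original picks
    edge_distortion: np.ndarray      # per edge, relative length change
    energy_trace: list               # energy after projection, per iteration
    edges: list
    converged: bool


def smooth_target_surface(pial: SurfaceMesh, iters: int = 20) -> SurfaceMesh:
    """Taubin (shrink-compensated) smoothing of the pial surface; vertex and
    face counts are unchanged and a watertight input stays watertight."""
    if not pial.is_watertight():
        raise ValueError("target surface must be watertight")
    if iters == 0:
        return SurfaceMesh(vertices=pial.vertices.copy(), faces=pial.faces.copy())
    import trimesh.smoothing

    tm = pial.to_trimesh()
    trimesh.smoothing.filter_taubin(tm, lamb=0.5, nu=0.53, iterations=iters)
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


def grid_edges(electrode: Electrode) -> list:
    """Neighbour topology for the deformation term: 4-neighbourhood for
    grids (rows x cols, row-major contact order), consecutive pairs for
    strips and depth shafts."""
    n = len(electrode)
    if electrode.kind == "grid":
        if electrode.grid_shape is None:
            raise ValueError(f"electrode {electrode.name}: grid without grid_shape")
        rows, cols = electrode.grid_shape
        if rows * cols != n:
            raise ValueError(
                f"electrode {electrode.name}: grid_shape {electrode.grid_shape} "
                f"inconsistent with {n} contacts"
            )
        edges = []
        for r in range(rows):
            for c in range(cols):
                i = r * cols + c
                if c + 1 < cols:
                    edges.append((i, i + 1))
                if r + 1 < rows:
                    edges.append((i, i + cols))
        return edges
    return [(i, i + 1) for i in range(n - 1)]


def _closest_on_mesh(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Nearest point on the (continuous) triangulated surface, per query."""
    import trimesh.triangles

    out = np.empty_like(points)
    for i, p in enumerate(points):
        cand = trimesh.triangles.closest_point(tri, np.tile(p, (len(tri), 1)))
        d2 = ((cand - p) ** 2).sum(axis=1)
        out[i] = cand[np.argmin(d2)]
    return out


def _energy(x, x0, edges, d0, lam) -> float:
    e = float(((x - x0) ** 2).sum())
    if edges:
        i, j = zip(*edges)
        lens = np.linalg.norm(x[list(i)] - x[list(j)], axis=1)
        e += lam * float(((lens - d0) ** 2).sum())
    return e


def snap_to_surface(
    electrode: Electrode, surface: SurfaceMesh, params: SnapParams = None
) -> SnapResult:
    """Snap a grid/strip onto the target surface.

    Depth electrodes are rejected: their contacts belong inside the brain,
    not on it.  The returned energy trace is non-increasing and the final
    energy never exceeds that of naive independent per-contact projection
    (the starting point of the iteration).
    """
    params = params or SnapParams()
    if electrode.kind not in ("grid", "strip"):
        raise ValueError(
            f"electrode {electrode.name} is kind {electrode.kind!r}; "
            "snapping applies to surface grids and strips only"
        )
    if not surface.is_watertight():
        raise ValueError("snapping target surface must be watertight")

    x0 = electrode.positions.copy()
    edges = grid_edges(electrode)
    d0 = np.array(
        [np.linalg.norm(x0[i] - x0[j]) for i, j in edges]
    ) if edges else np.empty(0)
    lam = params.lambda_deform
    tri = surface.vertices[surface.faces]

    neighbours: list = [[] for _ in range(len(x0))]
    rest: list = [[] for _ in range(len(x0))]
    for (i, j), d in zip(edges, d0):
        neighbours[i].append(j)
        rest[i].append(d)
        neighbours[j].append(i)
        rest[j].append(d)

    x = _closest_on_mesh(x0, tri)
    energy = _energy(x, x0, edges, d0, lam)
    trace = [energy]
    converged = False

    for _ in range(params.max_iter):
        accepted = False
        for step in (1.0, 0.5, 0.25, 0.125, 0.0625):
            cand = x.copy()
            for i in range(len(cand)):  # Gauss-Seidel: in-place, contact order
                target = x0[i].copy()
                denom = 1.0
                for j, d in zip(neighbours[i], rest[i]):
                    diff = cand[i] - cand[j]
                    nrm = np.linalg.norm(diff)
                    u = diff / nrm if nrm > 1e-12 else np.zeros(3)
                    target += lam * (cand[j] + d * u)
                    denom += lam
                cand[i] = cand[i] + step * (target / denom - cand[i])
            cand = _closest_on_mesh(cand, tri)
            e_new = _energy(cand, x0, edges, d0, lam)
            if e_new <= energy + 1e-12:
                improvement = energy - e_new
                x, energy = cand, e_new
                trace.append(energy)
                accepted = True
                if improvement < params.tol:
                    converged = True
                break
        if not accepted:
            converged = True  # no descent direction left at minimal step
        if converged:
            break

    if edges:
        i, j = zip(*edges)
        lens = np.linalg.norm(x[list(i)] - x[list(j)], axis=1)
        distortion = (lens - d0) / d0
    else:
        distortion = np.empty(0)
    return SnapResult(
        positions=x,
        displacement_mm=np.linalg.norm(x - x0, axis=1),
        edge_distortion=distortion,
        energy_trace=trace,
        edges=edges,
        converged=converged,
    )


def max_surface_distance(points: np.ndarray, surface: SurfaceMesh) -> float:
    """Largest distance from any point to the surface (diagnostic)."""
    tri = surface.vertices[surface.faces]
    proj = _closest_on_mesh(np.asarray(points, dtype=float), tri)
    return float(np.linalg.norm(proj - points, axis=1).max())
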