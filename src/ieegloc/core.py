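"""Shared domain types for the electrode-localization pipeline.

All coordinates in this package are world RAS millimetres.  The single
working frame is the pre-operative volume's scanner RAS; meshes read from
FreeSurfer-style files (which live in "surface RAS", offset by the volume
center) are shifted into scanner RAS at read time.  The ``frame`` tag on
:class:`VolumeImage` makes accidental frame mixing detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

# Tissue categories used by the label table and the tissue classifier.
CORTICAL_GREY = "cortical_grey"
SUBCORTICAL_GREY = "subcortical_grey"
WHITE = "white"
CSF = "csf"
BACKGROUND = "background"

CATEGORIES = (CORTICAL_GREY, SUBCORTICAL_GREY, WHITE, CSF, BACKGROUND)

GREY_CATEGORIES = (CORTICAL_GREY, SUBCORTICAL_GREY)


@dataclass
class VolumeImage:
    """A 3-D scalar or integer-label grid with a voxel-to-world affine.

    Voxel indices are 0-based and the affine maps voxel *centers* to world
    RAS mm.  ``frame`` tags the world frame ('scanner_ras' or 'surface_ras').
    """

    grid: np.ndarray
    affine: np.ndarray
    frame: str = "scanner_ras"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.grid.ndim != 3:
            raise ValueError(f"volume grid must be 3-D, got shape {self.grid.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("volume affine is not invertible")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    @property
    def inverse_affine(self) -> np.ndarray:
        return np.linalg.inv(self.affine)

    def is_label_volume(self) -> bool:
        return np.issubdtype(self.grid.dtype, np.integer)


@dataclass
class SurfaceMesh:
    """Triangle mesh in world RAS mm (pial/white surface, enclosing volume)."""

    vertices: np.ndarray
    faces: np.ndarray
    frame: str = "scanner_ras"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise ValueError("face indices out of vertex range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_watertight(self) -> bool:
        """True when every edge is shared by exactly two faces."""
        if not len(self.faces):
            return False
        e = np.vstack([self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]])
        e.sort(axis=1)
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool((counts == 2).all())

    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)


@dataclass
class RigidTransform:
    """4x4 homogeneous world-to-world transform (post-op to pre-op space)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError(f"transform matrix is not invertible:\n{self.matrix}")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        m = np.eye(4)
        m[:3, 3] = t
        return cls(m)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix)

    def is_rigid(self, tol: float = 1e-6) -> bool:
        r = self.matrix[:3, :3]
        return np.allclose(r @ r.T, np.eye(3), atol=tol)


@dataclass
class LabelEntry:
    id: int
    name: str
    category: str
    color: tuple = (128, 128, 128)

    def __post_init__(self) -> None:
        if self.id < 0:
            raise ValueError(f"label id must be non-negative, got {self.id}")
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for label {self.id}")


class LabelTable:
    """Lookup table id -> name / tissue category (FreeSurfer color-LUT style)."""

    def __init__(self, entries):
        self._by_id = {}
        for e in entries:
            if e.id in self._by_id:
                raise ValueError(f"duplicate label id {e.id}")
            self._by_id[e.id] = e
        if 0 not in self._by_id:
            self._by_id[0] = LabelEntry(0, "Unknown", BACKGROUND, (0, 0, 0))
        elif self._by_id[0].category != BACKGROUND:
            raise ValueError("label id 0 must have category background")

    def __contains__(self, label_id: int) -> bool:
        return int(label_id) in self._by_id

    def __iter__(self):
        return iter(sorted(self._by_id.values(), key=lambda e: e.id))

    def __len__(self) -> int:
        return len(self._by_id)

    def entry(self, label_id: int) -> LabelEntry:
        return self._by_id[int(label_id)]

    def name(self, label_id: int) -> str:
        return self._by_id[int(label_id)].name

    def category(self, label_id: int) -> str:
        e = self._by_id.get(int(label_id))
        return e.category if e is not None else BACKGROUND

    def ids_in_category(self, *categories: str) -> list:
        return sorted(e.id for e in self._by_id.values() if e.category in categories)

    def is_grey(self, label_id: int) -> bool:
        return self.category(label_id) in GREY_CATEGORIES


@dataclass
class Contact:
    """A single recording contact with its world-RAS position."""

    label: str
    position: np.ndarray
    size_mm: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if not np.isfinite(self.position).all():
            raise ValueError(f"contact {self.label}: non-finite coordinates")


@dataclass
class Electrode:
    """Named ordered contacts; kind is depth (sEEG shaft), grid or strip."""

    name: str
    contacts: list
    kind: str = "depth"
    grid_shape: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.kind not in ("depth", "grid", "strip"):
            raise ValueError(f"unknown electrode kind {self.kind!r}")
        if self.kind == "grid" and self.grid_shape is not None:
            r, c = self.grid_shape
            if r * c != len(self.contacts):
                raise ValueError(
                    f"electrode {self.name}: grid_shape {self.grid_shape} "
                    f"inconsistent with {len(self.contacts)} contacts"
                )

    @property
    def positions(self) -> np.ndarray:
        return np.array([c.position for c in self.contacts], dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.contacts)
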