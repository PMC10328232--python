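"""Electrode Labelling Algorithm (ELA).

Each contact (or bipolar pair) is assigned per-region probabilities from the
overlap of an expanding cylinder around the contact with the parcellation:
a fixed cubic lattice of sample points covers the largest cylinder, and for
each radius r_k in the expansion schedule the fraction of lattice points
inside radius r_k carrying each label is computed; the probability of a
label is the average of these fractions over the schedule.  Background
(outside-brain) mass is retained so probabilities always sum to one and are
comparable across contacts.  The final region assignment is the argmax over
grey-matter (cortical or subcortical) labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import Electrode, LabelTable, VolumeImage
from .geometry import sample_label


@dataclass
class ElaParams:
    """Tunable parameters of the expanding-cylinder sampling.

    r_max is the largest cylinder radius (mm); the schedule is
    r_k = k * r_max / n_radii for k = 1..n_radii.  half_length is half the
    cylinder length along the shaft; when None it defaults to half the local
    inter-contact spacing (1.0 mm for isolated contacts).  sample_spacing is
    the lattice pitch.
    """

    r_max: float = 3.0
    n_radii: int = 6
    half_length: Optional[float] = None
    sample_spacing: float = 0.5
    mode: str = "monopolar"

    def __post_init__(self) -> None:
        if self.r_max <= 0:
            raise ValueError("r_max must be positive")
        if self.n_radii < 1:
            raise ValueError("n_radii must be >= 1")
        if self.sample_spacing > self.r_max:
            raise ValueError("sample_spacing must not exceed r_max")
        if self.mode not in ("monopolar", "bipolar"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def radii(self) -> np.ndarray:
        return np.arange(1, self.n_radii + 1) * self.r_max / self.n_radii


@dataclass
class RegionAssignment:
    label: int
    probability: float
    fallback: bool = False
    tie: bool = False


@dataclass
class ContactProbabilities:
    """Per-contact (or bipolar-pair) ELA output: one spreadsheet row."""

    electrode: str
    contact: str
    probabilities: dict
    assigned_label: int
    assigned_probability: float
    fallback: bool = False
    tie: bool = False
    multi_region: bool = False


def contact_axis(electrode: Electrode, index: int) -> Optional[np.ndarray]:
    """Local shaft direction at a contact (unit vector), or None when the
    electrode has a single contact (caller switches to spherical sampling).

    Interior contacts use the central difference of their neighbours; end
    contacts a one-sided difference.
    """
    pos = electrode.positions
    n = len(pos)
    if n == 0:
        raise ValueError("electrode has no contacts")
    if not 0 <= index < n:
        raise IndexError(f"contact index {index} out of range for {n} contacts")
    if n == 1:
        return None
    lo = max(index - 1, 0)
    hi = min(index + 1, n - 1)
    d = pos[hi] - pos[lo]
    norm = np.linalg.norm(d)
    if norm < 1e-12:
        raise ValueError(
            f"electrode {electrode.name}: contacts {lo} and {hi} coincide; no axis"
        )
    return d / norm


def _cylinder_lattice(params: ElaParams, half_length: float, axis: Optional[np.ndarray]):
    """Cubic lattice (centered on the contact) covering the largest cylinder,
    expressed in the cylinder frame.  Returns (offsets (n,3) in the world
    frame once rotated, radial distance, axial distance)."""
    s = params.sample_spacing
    n_rad = int(np.floor(params.r_max / s + 1e-9))
    if axis is None:
        half_length = params.r_max  # sphere
    n_ax = int(np.floor(half_length / s + 1e-9))
    ax = np.arange(-n_ax, n_ax + 1) * s
    rad = np.arange(-n_rad, n_rad + 1) * s
    U, V, W = np.meshgrid(ax, rad, rad, indexing="ij")
    pts = np.stack([U.ravel(), V.ravel(), W.ravel()], axis=1)
    radial = np.hypot(pts[:, 1], pts[:, 2])
    if axis is None:
        radial = np.linalg.norm(pts, axis=1)
        keep = radial <= params.r_max + 1e-12
    else:
        keep = (radial <= params.r_max + 1e-12) & (np.abs(pts[:, 0]) <= half_length + 1e-12)
    return pts[keep], radial[keep]


def _frame_from_axis(axis: np.ndarray) -> np.ndarray:
    u = axis / np.linalg.norm(axis)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return np.stack([u, v, w], axis=1)  # columns: axial, radial1, radial2


def ela_fractions(
    position,
    axis: Optional[np.ndarray],
    parcellation: VolumeImage,
    params: ElaParams = None,
    half_length: Optional[float] = None,
) -> tuple:
    """Per-radius label fractions f_L(r_k) of the expanding cylinder.

    Returns (label ids (L,), fractions (n_radii, L)); each row sums to 1.
    With ``axis`` None a sphere of radius r_max is sampled instead.
    """
    params = params or ElaParams()
    if not parcellation.is_label_volume():
        raise ValueError("ELA requires an integer label volume")
    if half_length is None:
        half_length = params.half_length if params.half_length is not None else 1.0
    position = np.asarray(position, dtype=float).reshape(3)

    offsets, radial = _cylinder_lattice(params, half_length, axis)
    if axis is None:
        world = position[None, :] + offsets
    else:
        R = _frame_from_axis(np.asarray(axis, dtype=float))
        world = position[None, :] + offsets @ R.T
    sampled = np.asarray(sample_label(parcellation, world))

    radii = params.radii
    if not (radial <= radii[0] + 1e-12).any():
        raise ValueError(
            f"no lattice point inside the smallest radius {radii[0]:.3g} mm; "
            "decrease sample_spacing"
        )
    uniq, inv = np.unique(sampled, return_inverse=True)
    frac = np.empty((len(radii), len(uniq)))
    for k, r_k in enumerate(radii):
        mask = radial <= r_k + 1e-12
        counts = np.bincount(inv[mask], minlength=len(uniq)).astype(float)
        frac[k] = counts / counts.sum()
    return uniq.astype(int), frac


def ela_probabilities(
    position,
    axis: Optional[np.ndarray],
    parcellation: VolumeImage,
    labels: LabelTable,
    params: ElaParams = None,
    half_length: Optional[float] = None,
) -> dict:
    """Probability per label from the expanding cylinder around a contact:
    the average over the radius schedule of the per-radius label fractions.

    Deterministic: the lattice is fixed by the contact position, the axis and
    the parameters.  With ``axis`` None a sphere of radius r_max is sampled.
    """
    uniq, frac = ela_fractions(position, axis, parcellation, params, half_length)
    acc = frac.mean(axis=0)
    return {int(label): float(p) for label, p in zip(uniq, acc) if p > 0}


def bipolar_probabilities(
    electrode: Electrode,
    pair_index: int,
    parcellation: VolumeImage,
    labels: LabelTable,
    params: ElaParams = None,
) -> dict:
    """ELA probabilities for the bipolar pair (pair_index, pair_index+1):
    cylinder centered on the pair midpoint, oriented along the pair, with
    half-length equal to half the pair separation."""
    n = len(electrode)
    if not 0 <= pair_index < n - 1:
        raise IndexError(
            f"bipolar pair ({pair_index},{pair_index + 1}) does not exist on "
            f"electrode {electrode.name} with {n} contacts"
        )
    a = electrode.contacts[pair_index].position
    b = electrode.contacts[pair_index + 1].position
    sep = np.linalg.norm(b - a)
    if sep < 1e-12:
        raise ValueError("bipolar pair contacts coincide")
    return ela_probabilities(
        (a + b) / 2.0, (b - a) / sep, parcellation, labels, params, half_length=sep / 2.0
    )


def assign_region(probs: dict, labels: LabelTable) -> RegionAssignment:
    """Argmax over grey-matter labels; ties broken toward the lower label id
    (flagged).  When no grey label has mass, the overall argmax is returned
    with the fallback flag set so white/outside contacts are reported as
    such rather than silently forced grey."""
    if not probs:
        raise ValueError("empty probability map")
    grey = {lid: p for lid, p in probs.items() if labels.is_grey(lid) and p > 0}
    pool = grey if grey else probs
    best_p = max(pool.values())
    winners = sorted(lid for lid, p in pool.items() if p == best_p)
    return RegionAssignment(
        label=winners[0],
        probability=best_p,
        fallback=not grey,
        tie=len(winners) > 1,
    )


def _local_half_length(electrode: Electrode, index: int) -> float:
    pos = electrode.positions
    n = len(pos)
    if n == 1:
        return 1.0
    gaps = []
    if index > 0:
        gaps.append(np.linalg.norm(pos[index] - pos[index - 1]))
    if index < n - 1:
        gaps.append(np.linalg.norm(pos[index + 1] - pos[index]))
    return float(np.mean(gaps)) / 2.0


def label_electrode(
    electrode: Electrode,
    parcellation: VolumeImage,
    labels: LabelTable,
    params: ElaParams = None,
) -> list:
    """Run ELA over a whole electrode -> list of ContactProbabilities.

    In monopolar mode one record per contact; in bipolar mode one record per
    adjacent pair (named "c1-c2").
    """
    params = params or ElaParams()
    records = []
    if params.mode == "bipolar":
        for i in range(len(electrode) - 1):
            probs = bipolar_probabilities(electrode, i, parcellation, labels, params)
            a = assign_region(probs, labels)
            records.append(
                ContactProbabilities(
                    electrode=electrode.name,
                    contact=f"{electrode.contacts[i].label}-{electrode.contacts[i + 1].label}",
                    probabilities=probs,
                    assigned_label=a.label,
                    assigned_probability=a.probability,
                    fallback=a.fallback,
                    tie=a.tie,
                    multi_region=sum(1 for p in probs.values() if p > 0) >= 2,
                )
            )
        return records
    for i, contact in enumerate(electrode.contacts):
        axis = contact_axis(electrode, i)
        hl = params.half_length if params.half_length is not None else _local_half_length(electrode, i)
        probs = ela_probabilities(
            contact.position, axis, parcellation, labels, params, half_length=hl
        )
        a = assign_region(probs, labels)
        records.append(
            ContactProbabilities(
                electrode=electrode.name,
                contact=contact.label,
                probabilities=probs,
                assigned_label=a.label,
                assigned_probability=a.probability,
                fallback=a.fallback,
                tie=a.tie,
                multi_region=sum(1 for p in probs.values() if p > 0) >= 2,
            )
        )
    return records
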