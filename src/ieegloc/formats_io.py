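"""Readers and writers for the standard formats the pipeline touches.

Volumes are NIfTI-1 (MGZ also accepted via nibabel), surfaces are
FreeSurfer binary triangle files, label tables use the FreeSurfer color-LUT
text dialect, contact picks are delimited text, meshes export to binary
STL, and electrode tables export to iEEG-BIDS ``electrodes.tsv`` +
``coordsystem.json``.

FreeSurfer surfaces are stored in "surface RAS" (tkrRAS), which is offset
from scanner RAS by the volume-center world position.  When a companion
volume is supplied to :func:`read_surface`/:func:`write_surface` the offset
is applied so meshes and contact picks coexist in one scanner-RAS frame;
otherwise the mesh is tagged ``surface_ras``.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import (
    BACKGROUND,
    CATEGORIES,
    CORTICAL_GREY,
    CSF,
    SUBCORTICAL_GREY,
    WHITE,
    Contact,
    Electrode,
    LabelEntry,
    LabelTable,
    SurfaceMesh,
    VolumeImage,
)


class FormatError(ValueError):
    """A file could not be parsed in its declared format."""


# ---------------------------------------------------------------------------
# volumes


def read_volume(path) -> VolumeImage:
    path = Path(path)
    try:
        img = nib.load(str(path))
        grid = np.asanyarray(img.dataobj)
        affine = np.asarray(img.affine, dtype=float)
    except Exception as exc:  # nibabel raises a zoo of error types
        raise FormatError(f"cannot read volume {path}: {exc}") from exc
    return VolumeImage(grid=grid, affine=affine, frame="scanner_ras")


def write_volume(vol: VolumeImage, path) -> None:
    path = Path(path)
    grid = vol.grid
    if vol.is_label_volume():
        grid = grid.astype(np.int32, copy=False)
    img = nib.Nifti1Image(grid, vol.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# surfaces

def surface_ras_offset(vol: VolumeImage) -> np.ndarray:
    """World position of the volume center: the tkrRAS -> scanner-RAS shift."""
    center_index = np.asarray(vol.shape, dtype=float) / 2.0
    return vol.affine[:3, :3] @ center_index + vol.affine[:3, 3]


def read_surface(path, companion_volume: VolumeImage | None = None) -> SurfaceMesh:
    """Read a FreeSurfer binary triangle surface.

    With a companion volume the vertices are shifted from surface RAS into
    the volume's scanner-RAS frame.
    """
    path = Path(path)
    try:
        vertices, faces = nib.freesurfer.read_geometry(str(path))
    except Exception as exc:
        raise FormatError(f"cannot read surface {path}: {exc}") from exc
    vertices = np.asarray(vertices, dtype=float)
    frame = "surface_ras"
    if companion_volume is not None:
        vertices = vertices + surface_ras_offset(companion_volume)
        frame = "scanner_ras"
    return SurfaceMesh(vertices=vertices, faces=np.asarray(faces, dtype=np.int64), frame=frame)


def write_surface(mesh: SurfaceMesh, path, companion_volume: VolumeImage | None = None) -> None:
    vertices = mesh.vertices
    if companion_volume is not None:
        vertices = vertices - surface_ras_offset(companion_volume)
    nib.freesurfer.write_geometry(str(path), vertices, mesh.faces)


# ---------------------------------------------------------------------------
# label tables

_SUBCORTICAL_NAMES = (
    "hippocampus", "amygdala", "thalamus", "caudate", "putamen", "pallidum",
    "accumbens", "ventraldc", "brain-stem", "brainstem", "substancia-nigra",
)
_CSF_NAMES = ("ventricle", "csf", "choroid")


def default_name_category(name: str) -> str | None:
    """Tissue category from a FreeSurfer-style structure name, or None."""
    low = name.lower()
    if low in ("unknown", "background") or low.endswith("-unknown"):
        return BACKGROUND
    if "white-matter" in low or low.startswith("wm-") or low == "white":
        return WHITE
    if any(k in low for k in _CSF_NAMES):
        return CSF
    if low.startswith("ctx-") or low.startswith("ctx_") or low.startswith("ctx."):
        return CORTICAL_GREY
    if any(k in low for k in _SUBCORTICAL_NAMES):
        return SUBCORTICAL_GREY
    return None


#: FreeSurfer id-range conventions used when a name is not recognized.
DEFAULT_ID_RANGE_RULES = (
    ((1000, 2999), CORTICAL_GREY),   # aparc/DKT cortical labels
    ((3000, 5999), WHITE),           # wm-parc labels
)


def read_label_table(path, id_range_rules=DEFAULT_ID_RANGE_RULES) -> LabelTable:
    """Parse a FreeSurfer color-LUT text file: ``id name R G B A``.

    Categories come from canonical structure names; unknown names fall back
    to the configured id-range rules.  Duplicate ids are an error.
    """
    path = Path(path)
    entries = []
    seen = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: expected 'id name R G B A', got {raw!r}")
        try:
            label_id = int(parts[0])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer label id {parts[0]!r}") from exc
        name = parts[1]
        color = (128, 128, 128)
        if len(parts) >= 5:
            try:
                color = tuple(int(c) for c in parts[2:5])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer color") from exc
        if label_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate label id {label_id}")
        seen.add(label_id)
        if label_id == 0:
            category = BACKGROUND
        else:
            category = default_name_category(name)
            if category is None:
                for (lo, hi), cat in id_range_rules:
                    if lo <= label_id <= hi:
                        category = cat
                        break
            if category is None:
                raise FormatError(
                    f"{path}:{lineno}: cannot infer tissue category for label "
                    f"{label_id} {name!r}; extend id_range_rules"
                )
        entries.append(LabelEntry(label_id, name, category, color))
    return LabelTable(entries)


def write_label_table(labels: LabelTable, path) -> None:
    lines = ["# id name R G B A"]
    for e in labels:
        r, g, b = e.color
        lines.append(f"{e.id:<6d} {e.name:<40s} {r:3d} {g:3d} {b:3d} 0")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# contact picks

_ELECTRODE_KEYS = ("electrode", "group", "shaft")
_CONTACT_KEYS = ("contact", "name", "label", "number")


def _find_column(header, keys, path):
    low = [h.strip().lower() for h in header]
    for key in keys:
        if key in low:
            return low.index(key)
    raise FormatError(f"{path}: header must name one of {keys}, got {header}")


def read_contacts(path, kinds: dict | None = None, grid_shapes: dict | None = None) -> list:
    """Read a delimited (comma or tab) contact-pick table into Electrodes.

    The header must name electrode, contact, x, y, z (size optional).
    Contacts are grouped by electrode preserving file order; electrode kind
    comes from ``kinds`` (name -> depth/grid/strip), defaulting to depth.
    """
    path = Path(path)
    text = path.read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    if not rows:
        raise FormatError(f"{path}: empty file")
    header = rows[0]
    ie = _find_column(header, _ELECTRODE_KEYS, path)
    ic = _find_column(header, _CONTACT_KEYS, path)
    ix = _find_column(header, ("x",), path)
    iy = _find_column(header, ("y",), path)
    iz = _find_column(header, ("z",), path)
    low = [h.strip().lower() for h in header]
    isz = low.index("size") if "size" in low else None

    groups: dict = {}
    seen_pairs = set()
    for lineno, row in enumerate(rows[1:], start=2):
        if not any(cell.strip() for cell in row):
            continue
        name = row[ie].strip()
        contact = row[ic].strip()
        if (name, contact) in seen_pairs:
            raise FormatError(f"{path}:{lineno}: duplicate contact {name}/{contact}")
        seen_pairs.add((name, contact))
        try:
            xyz = [float(row[i]) for i in (ix, iy, iz)]
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric coordinate in {row!r}") from exc
        size = None
        if isz is not None and row[isz].strip() not in ("", "n/a"):
            try:
                size = float(row[isz])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric size") from exc
        groups.setdefault(name, []).append(Contact(contact, xyz, size))

    kinds = kinds or {}
    grid_shapes = grid_shapes or {}
    return [
        Electrode(
            name=name,
            contacts=contacts,
            kind=kinds.get(name, "depth"),
            grid_shape=grid_shapes.get(name),
        )
        for name, contacts in groups.items()
    ]


def write_contacts(electrodes, path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["electrode", "contact", "x", "y", "z", "size"])
        for e in electrodes:
            for c in e.contacts:
                size = "" if c.size_mm is None else f"{c.size_mm:.6g}"
                w.writerow(
                    [e.name, c.label] + [f"{v:.9g}" for v in c.position] + [size]
                )


# ---------------------------------------------------------------------------
# STL


def write_stl(mesh: SurfaceMesh, path) -> None:
    """Export a mesh as binary STL (one triangle per face)."""
    if mesh.n_faces == 0:
        raise ValueError("cannot export an empty mesh to STL")
    mesh.to_trimesh().export(str(path), file_type="stl")


def read_stl(path) -> SurfaceMesh:
    import trimesh

    path = Path(path)
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:
        raise FormatError(f"cannot read STL {path}: {exc}") from exc
    return SurfaceMesh(vertices=np.asarray(tm.vertices), faces=np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# probability spreadsheet (ELA output)


def write_probability_table(records, labels: LabelTable, path) -> None:
    """Write the per-contact region-probability spreadsheet as CSV.

    One row per contact (or bipolar pair), one column per label seen
    anywhere, plus the assigned region and the maximum grey-matter
    probability.  Values carry 8 significant digits so row sums re-read
    within 1e-6 of 1.
    """
    records = list(records)
    if not records:
        raise ValueError("no probability records to write")
    label_ids = sorted({lid for r in records for lid in r.probabilities})
    rows = []
    for r in records:
        row = {
            "electrode": r.electrode,
            "contact": r.contact,
            "assigned_region": labels.name(r.assigned_label),
            "assigned_label_id": r.assigned_label,
            "max_grey_probability": float(f"{r.assigned_probability:.8g}")
            if not r.fallback
            else 0.0,
            "assigned_probability": float(f"{r.assigned_probability:.8g}"),
            "multi_region": int(r.multi_region),
        }
        for lid in label_ids:
            row[labels.name(lid)] = float(f"{r.probabilities.get(lid, 0.0):.8g}")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# iEEG-BIDS electrodes


def write_bids_electrodes(
    electrodes,
    classifications=None,
    measurements=None,
    out_dir=".",
    coordinate_frame_name: str = "Other",
    basename: str = "sub-01_ses-01_space-Other",
) -> tuple:
    """Write iEEG-BIDS ``*_electrodes.tsv`` and ``*_coordsystem.json``.

    ``classifications`` maps (electrode name, contact label) to an object
    with ``tissue_class`` and ``label_name`` attributes (or a (class, name)
    tuple); ``measurements`` maps the same key to a dict of extra numeric
    columns.  Unknown values are written as "n/a" per BIDS convention.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    classifications = classifications or {}
    measurements = measurements or {}

    extra_cols: list = []
    for m in measurements.values():
        for k in m:
            if k not in extra_cols:
                extra_cols.append(k)

    header = ["name", "x", "y", "z", "size", "group", "tissue", "region"] + extra_cols
    lines = ["\t".join(header)]
    for e in electrodes:
        for c in e.contacts:
            key = (e.name, c.label)
            cls = classifications.get(key)
            if cls is None:
                tissue, region = "n/a", "n/a"
            elif isinstance(cls, tuple):
                tissue, region = cls
            else:
                tissue, region = cls.tissue_class, cls.label_name
            cells = [
                f"{e.name}{c.label}",
                f"{c.position[0]:.6f}",
                f"{c.position[1]:.6f}",
                f"{c.position[2]:.6f}",
                "n/a" if c.size_mm is None else f"{c.size_mm:.6g}",
                e.name,
                tissue,
                region,
            ]
            meas = measurements.get(key, {})
            for col in extra_cols:
                v = meas.get(col)
                cells.append("n/a" if v is None else f"{float(v):.6f}")
            lines.append("\t".join(cells))

    tsv_path = out_dir / f"{basename}_electrodes.tsv"
    tsv_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    coordsystem = {
        "iEEGCoordinateSystem": coordinate_frame_name,
        "iEEGCoordinateUnits": "mm",
        "iEEGCoordinateSystemDescription": (
            "Scanner RAS of the pre-operative T1-weighted MRI (native space)."
        ),
        "iEEGCoordinateProcessingDescription": (
            "Post-implant picks rigidly co-registered to the pre-operative MRI; "
            "labels assigned by probabilistic (ELA) and volumetric (EVL) methods."
        ),
    }
    json_path = out_dir / f"{basename}_coordsystem.json"
    json_path.write_text(json.dumps(coordsystem, indent=2) + "\n", encoding="utf-8")
    return tsv_path, json_path
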