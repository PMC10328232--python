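"""Shareable per-contact visual report.

For every contact: the three orthogonal MRI/parcellation slices through the
contact's voxel with a marker at the projected pixel, plus an oblique
reslice along the long axis of the electrode shaft (the "length-wise"
coronal-like view), and the pages collected into one multi-page PDF ordered
by electrode then contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.backends.backend_pdf import PdfPages

from .core import Electrode, VolumeImage
from .geometry import reslice_along_trajectory, world_to_voxel

_PLANE_NAMES = ("sagittal", "coronal", "axial")  # slices at fixed x / y / z index


@dataclass
class PageDescriptor:
    """What was drawn where: used to verify marker placement and ordering."""

    electrode: str
    contact: str
    voxel: tuple                  # continuous voxel index of the contact
    markers: dict                 # panel name -> (row, col) marker pixel
    panel_shapes: dict            # panel name -> 2-D image shape


def _shaft_endpoints(electrode: Electrode, index: int):
    pos = electrode.positions
    if len(pos) >= 2:
        return pos[0], pos[-1]
    # isolated contact: a short sagittal-axis segment gives a valid plane
    p = pos[index]
    return p - np.array([5.0, 0, 0]), p + np.array([5.0, 0, 0])


def contact_page(
    volume: VolumeImage,
    electrode: Electrode,
    index: int,
    out_png=None,
    reslice_width_mm: float = 40.0,
    fig=None,
) -> PageDescriptor:
    """Render one contact page; returns the descriptor of what was drawn.

    The orthogonal panels slice the volume at the contact's (rounded) voxel
    index; the fourth panel re-slices along the whole shaft.  The marker
    pixel in each panel is the exact world-to-voxel projection of the
    contact.
    """
    contact = electrode.contacts[index]
    vox = world_to_voxel(contact.position, volume)
    shape = np.array(volume.shape)
    if ((vox < -0.5) | (vox > shape - 0.5)).any():
        raise ValueError(
            f"contact {electrode.name}{contact.label} at voxel {vox} is outside "
            f"the volume grid {tuple(shape)}"
        )
    i, j, k = [int(round(v)) for v in vox]

    p0, p1 = _shaft_endpoints(electrode, index)
    oblique = reslice_along_trajectory(
        volume, p0, p1, width_mm=reslice_width_mm, spacing_mm=1.0, pad_mm=5.0
    )
    ob_marker = oblique.world_to_pixel(contact.position)

    owns_fig = fig is None
    if owns_fig:
        fig = plt.figure(figsize=(8, 8))
    axes = fig.subplots(2, 2)
    panels = {
        "sagittal": (volume.grid[i, :, :], (vox[1], vox[2])),
        "coronal": (volume.grid[:, j, :], (vox[0], vox[2])),
        "axial": (volume.grid[:, :, k], (vox[0], vox[1])),
    }
    markers = {}
    panel_shapes = {}
    for ax, (name, (img, (mr, mc))) in zip(axes.ravel()[:3], panels.items()):
        ax.imshow(np.asarray(img, dtype=float).T, origin="lower", cmap="gray")
        ax.plot([mr], [mc], "r+", markersize=12)
        ax.set_title(f"{name} ({electrode.name}{contact.label})", fontsize=9)
        ax.set_xticks([])
        ax.set_yticks([])
        markers[name] = (float(mr), float(mc))
        panel_shapes[name] = img.shape
    ax = axes.ravel()[3]
    ax.imshow(np.asarray(oblique.image, dtype=float), origin="lower", cmap="gray")
    ax.plot([ob_marker[1]], [ob_marker[0]], "r+", markersize=12)
    ax.set_title("along shaft", fontsize=9)
    ax.set_xticks([])
    ax.set_yticks([])
    markers["along_shaft"] = (float(ob_marker[0]), float(ob_marker[1]))
    panel_shapes["along_shaft"] = oblique.image.shape

    if out_png is not None:
        fig.savefig(out_png, dpi=100)
    if owns_fig and out_png is not None:
        plt.close(fig)
    return PageDescriptor(
        electrode=electrode.name,
        contact=contact.label,
        voxel=tuple(float(v) for v in vox),
        markers=markers,
        panel_shapes=panel_shapes,
    )


def report_document(volume: VolumeImage, electrodes, out_path) -> list:
    """Multi-page PDF, one page per contact, ordered by electrode then
    contact.  Returns the page descriptors in page order."""
    electrodes = list(electrodes)
    total = sum(len(e) for e in electrodes)
    if total == 0:
        raise ValueError("no contacts to report")
    descriptors = []
    with PdfPages(out_path) as pdf:
        for e in electrodes:
            for idx in range(len(e)):
                fig = plt.figure(figsize=(8, 8))
                descriptors.append(contact_page(volume, e, idx, fig=fig))
                pdf.savefig(fig)
                plt.close(fig)
    return descriptors
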