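"""NIfTI / JSON / CSV input-output for volumes, labels and reports."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .segmentation import Compartment, CompartmentLabels, SpectVolume

__all__ = [
    "read_spect_volume",
    "write_spect_volume",
    "read_labels",
    "write_labels",
    "write_json_report",
    "LABEL_CODES",
]

#: On-disk integer code per compartment (stored in NIfTI label volumes).
LABEL_CODES = {c.name: int(c) for c in Compartment}


def _affine(voxel_spacing) -> np.ndarray:
    aff = np.diag(list(voxel_spacing) + [1.0])
    return aff


def write_spect_volume(volume: SpectVolume, path) -> None:
    img = nib.Nifti1Image(volume.counts.astype(np.float32), _affine(volume.voxel_spacing))
    img.header.set_zooms(volume.voxel_spacing)
    img.header["descrip"] = volume.tracer.encode()[:79]
    nib.save(img, str(path))


def read_spect_volume(path, tracer: str | None = None) -> SpectVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if tracer is None:
        tracer = img.header["descrip"].tobytes().split(b"\x00")[0].decode() or "TcMAA"
    return SpectVolume(np.asarray(img.dataobj, dtype=float), spacing, tracer)


def write_labels(labels: CompartmentLabels, path) -> None:
    img = nib.Nifti1Image(labels.labels.astype(np.uint8), _affine(labels.voxel_spacing))
    img.header.set_zooms(labels.voxel_spacing)
    nib.save(img, str(path))


def read_labels(path) -> CompartmentLabels:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CompartmentLabels(np.asarray(img.dataobj, dtype=np.uint8), spacing)


def write_json_report(payload: dict, path) -> None:
    """Serialise a report with pinned key order and float formatting so a
    fixed input always produces byte-identical output."""
    text = json.dumps(payload, indent=2, sort_keys=True, allow_nan=False)
    Path(path).write_text(text + "\n")
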