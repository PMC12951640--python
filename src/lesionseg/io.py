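"""NIfTI input/output and run manifests.

Volumes and masks are read with nibabel and reoriented to the closest
canonical (RAS) orientation on load, so array axes follow the package
convention (X = sagittal normal, Y = coronal normal, Z = axial normal).
Missing contrasts are specified by omission and loaded as zero-filled
channels with cleared presence flags.  Confidence maps are written as
integer-typed NIfTI so their integrality survives serialization.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Optional

import nibabel as nib
import numpy as np

from .geometry import CONTRASTS, MulticontrastVolume

__all__ = [
    "read_image",
    "read_mask",
    "load_multicontrast",
    "write_image",
    "write_mask",
    "write_confidence",
    "write_manifest",
]


class GridError(ValueError):
    """Contrasts or masks do not share a voxel grid."""


class MaskValueError(ValueError):
    """A mask file contains values other than 0 and 1."""


def read_image(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a 3D NIfTI image; returns (data, affine) in canonical orientation."""
    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asarray(img.get_fdata(), dtype=np.float64)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    return data, np.asarray(img.affine)


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Load a binary 3D mask; non-binary values raise MaskValueError."""
    data, affine = read_image(path)
    vals = np.unique(data)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise MaskValueError(f"{path}: mask must be binary, found values {vals[:5]}")
    return data.astype(np.uint8), affine


def load_multicontrast(paths: Mapping[str, object]) -> MulticontrastVolume:
    """Build a MulticontrastVolume from per-contrast NIfTI paths.

    ``paths`` maps contrast names ('t1w', 't2w', 'pdw', 'flair') to file
    paths; omitted or None entries become absent (all-zero) contrasts.
    All given contrasts must share a grid.
    """
    unknown = set(paths) - set(CONTRASTS)
    if unknown:
        raise ValueError(f"unknown contrast names {sorted(unknown)}; expected {CONTRASTS}")
    loaded = {}
    for name in CONTRASTS:
        p = paths.get(name)
        if p is not None:
            loaded[name] = read_image(p)
    if not loaded:
        raise ValueError("at least one contrast path is required")
    shapes = {name: d.shape for name, (d, _) in loaded.items()}
    if len(set(shapes.values())) != 1:
        raise GridError(f"contrasts have inconsistent shapes: {shapes}")
    first = next(iter(loaded.values()))
    shape, affine = first[0].shape, first[1]
    spacing = tuple(float(s) for s in nib.affines.voxel_sizes(affine))
    channels = np.zeros((len(CONTRASTS),) + shape)
    present = np.zeros(len(CONTRASTS), dtype=bool)
    for i, name in enumerate(CONTRASTS):
        if name in loaded:
            channels[i] = loaded[name][0]
            present[i] = True
    return MulticontrastVolume(channels, present, spacing, affine)


def write_image(path, data: np.ndarray, affine: Optional[np.ndarray] = None, dtype=np.float32) -> None:
    affine = np.eye(4) if affine is None else np.asarray(affine)
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))


def write_mask(path, mask: np.ndarray, affine: Optional[np.ndarray] = None) -> None:
    write_image(path, np.asarray(mask, dtype=np.uint8), affine, dtype=np.uint8)


def write_confidence(path, cmap, affine: Optional[np.ndarray] = None) -> None:
    """Integer-typed NIfTI of a confidence map (array or ConfidenceMap)."""
    C = getattr(cmap, "C", cmap)
    write_image(path, np.asarray(C, dtype=np.int16), affine, dtype=np.int16)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for block in iter(lambda: f.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def write_manifest(path, config: dict, seed: Optional[int], inputs: list) -> None:
    """Record config, seed and input hashes sufficient to reproduce a run."""
    manifest = {
        "config": config,
        "seed": seed,
        "inputs": {str(p): _sha256(p) for p in inputs if Path(p).is_file()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
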