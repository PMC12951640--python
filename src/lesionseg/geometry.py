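"""Multi-orientation transforms and 2.5D slab extraction.

Test-time augmentation uses the 8 in-plane dihedral operations (rotations by
0/90/180/270 degrees, each optionally followed by a flip) applied within each
of the three cardinal planes of a 3D volume, giving 24 distinct transforms.
All transforms permute voxels exactly — no interpolation — so the per-channel
multiset of intensities is conserved and every transform has an exact inverse.

Axis convention: arrays are indexed (X, Y, Z) with X = sagittal normal,
Y = coronal normal, Z = axial normal.  "Axial" slices are orthogonal to Z,
i.e. the in-plane axes of the axial plane are (0, 1).  Rotations are
counter-clockwise in array index space; the optional flip reverses the second
in-plane axis (a horizontal flip of the 2D slice as indexed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PLANES",
    "PLANE_INPLANE_AXES",
    "PLANE_NORMAL_AXIS",
    "CONTRASTS",
    "TransformDescriptor",
    "MulticontrastVolume",
    "Slab25D",
    "list_augmentations",
    "apply_transform",
    "apply_to_array",
    "invert_transform",
    "invert_to_array",
    "extract_25d",
    "num_slices",
]

PLANES = ("axial", "sagittal", "coronal")

#: in-plane (row, col) axes of each plane in the (X, Y, Z) array convention
PLANE_INPLANE_AXES = {"axial": (0, 1), "sagittal": (1, 2), "coronal": (0, 2)}

#: array axis orthogonal to each plane
PLANE_NORMAL_AXIS = {"axial": 2, "sagittal": 0, "coronal": 1}

#: fixed contrast channel order used throughout the package
CONTRASTS = ("t1w", "t2w", "pdw", "flair")


@dataclass(frozen=True)
class TransformDescriptor:
    """One of the 24 (plane x dihedral) test-time transforms.

    ``rotation`` counts 90-degree counter-clockwise in-plane rotations
    (0..3); ``flip`` reverses the second in-plane axis *after* rotating.
    """

    plane: str
    rotation: int
    flip: bool

    def __post_init__(self) -> None:
        if self.plane not in PLANES:
            raise ValueError(f"unknown plane {self.plane!r}")
        if self.rotation not in (0, 1, 2, 3):
            raise ValueError(f"rotation must be 0..3, got {self.rotation}")

    @property
    def dihedral_name(self) -> str:
        base = f"rot{self.rotation * 90}"
        return f"flipH*{base}" if self.flip else base

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.plane}, {self.dihedral_name})"


def list_augmentations() -> tuple[TransformDescriptor, ...]:
    """Return the 24 transforms in a fixed, documented order.

    Order: planes in (axial, sagittal, coronal); within a plane the four
    pure rotations rot0..rot270, then the four flipped ops flipH*rot0..
    flipH*rot270.  The first element, (axial, rot0), is the identity on
    axial slices.
    """
    out = []
    for plane in PLANES:
        for flip in (False, True):
            for rot in range(4):
                out.append(TransformDescriptor(plane, rot, flip))
    return tuple(out)


def _inplane_axes(d: TransformDescriptor, offset: int) -> tuple[int, int]:
    a, b = PLANE_INPLANE_AXES[d.plane]
    return a + offset, b + offset


def apply_to_array(arr: np.ndarray, d: TransformDescriptor, *, channel_axis: bool = False) -> np.ndarray:
    """Apply a dihedral transform to a 3D array (or 4D with leading channels).

    Pure index permutation: rotate ``rotation`` times CCW in the plane's
    in-plane axes, then optionally flip the second in-plane axis.
    """
    if not isinstance(d, TransformDescriptor):
        raise TypeError(f"expected TransformDescriptor, got {type(d).__name__}")
    offset = 1 if channel_axis else 0
    if arr.ndim != 3 + offset:
        raise ValueError(f"expected {3 + offset}D array, got {arr.ndim}D")
    axes = _inplane_axes(d, offset)
    out = np.rot90(arr, k=d.rotation, axes=axes)
    if d.flip:
        out = np.flip(out, axis=axes[1])
    return np.ascontiguousarray(out)


def invert_to_array(arr: np.ndarray, d: TransformDescriptor, *, channel_axis: bool = False) -> np.ndarray:
    """Undo :func:`apply_to_array`: unflip, then rotate back."""
    offset = 1 if channel_axis else 0
    if arr.ndim != 3 + offset:
        raise ValueError(f"expected {3 + offset}D array, got {arr.ndim}D")
    axes = _inplane_axes(d, offset)
    out = np.flip(arr, axis=axes[1]) if d.flip else arr
    out = np.rot90(out, k=-d.rotation, axes=axes)
    return np.ascontiguousarray(out)


@dataclass
class MulticontrastVolume:
    """A co-registered 4-channel (T1w, T2w, PDw, FLAIR) 3D intensity stack.

    Absent contrasts are stored as all-zero channels with ``present`` False.
    """

    intensities: np.ndarray  # (4, X, Y, Z)
    present: np.ndarray  # (4,) bool
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 4 or self.intensities.shape[0] != len(CONTRASTS):
            raise ValueError(
                f"intensities must be ({len(CONTRASTS)}, X, Y, Z), got {self.intensities.shape}"
            )
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(CONTRASTS),):
            raise ValueError("present must have one flag per contrast")
        if not self.present.any():
            raise ValueError("at least one contrast must be present")
        for i, p in enumerate(self.present):
            if not p:
                self.intensities[i] = 0.0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape[1:]

    def copy(self) -> "MulticontrastVolume":
        return MulticontrastVolume(
            self.intensities.copy(),
            self.present.copy(),
            tuple(self.voxel_spacing),
            self.affine.copy(),
        )


def apply_transform(vol: MulticontrastVolume, d: TransformDescriptor) -> MulticontrastVolume:
    """Transform all contrast channels; presence flags are unchanged."""
    out = apply_to_array(vol.intensities, d, channel_axis=True)
    return MulticontrastVolume(out, vol.present.copy(), tuple(vol.voxel_spacing), vol.affine.copy())


def invert_transform(mask: np.ndarray, d: TransformDescriptor) -> np.ndarray:
    """Map a (binary) 3D mask from transformed space back to the original grid."""
    return invert_to_array(np.asarray(mask), d)


@dataclass
class Slab25D:
    """Three adjacent slices of every contrast, stacked channel-wise.

    Channel order is slice-major, contrast-minor:
    (k-1,T1w) (k-1,T2w) (k-1,PDw) (k-1,FLAIR) (k,T1w) ... (k+1,FLAIR).
    Out-of-volume neighbour slices are zero-filled.
    """

    channels: np.ndarray  # (3*4, H, W)
    plane: str
    central_index: int


def num_slices(vol_or_arr, plane: str) -> int:
    """Extent of a volume along the given plane's normal axis."""
    arr = vol_or_arr.intensities if isinstance(vol_or_arr, MulticontrastVolume) else np.asarray(vol_or_arr)
    off = 1 if arr.ndim == 4 else 0
    return arr.shape[PLANE_NORMAL_AXIS[plane] + off]


def _take_slice(stack: np.ndarray, plane: str, k: int) -> np.ndarray:
    """(C, X, Y, Z) -> (C, H, W) slice k orthogonal to the plane normal."""
    axis = PLANE_NORMAL_AXIS[plane] + 1
    return np.take(stack, k, axis=axis)


def extract_25d(vol: MulticontrastVolume, plane: str, k: int) -> Slab25D:
    """Extract the 2.5D slab (slices k-1, k, k+1 of every contrast) at k."""
    if plane not in PLANES:
        raise ValueError(f"unknown plane {plane!r}")
    n = num_slices(vol, plane)
    if not 0 <= k < n:
        raise IndexError(f"slice index {k} out of range [0, {n})")
    parts = []
    for kk in (k - 1, k, k + 1):
        if 0 <= kk < n:
            parts.append(_take_slice(vol.intensities, plane, kk))
        else:
            shape = _take_slice(vol.intensities, plane, k).shape
            parts.append(np.zeros(shape, dtype=vol.intensities.dtype))
    return Slab25D(np.concatenate(parts, axis=0), plane, k)
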