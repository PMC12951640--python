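"""Training loop and full test-time prediction pipeline.

Training samples lesion-containing 2.5D slabs: each batch draws one imaging
plane and one in-plane dihedral augmentation shared by all items; items draw
a random subject, a random rater label, and a random slice whose central
label slice contains at least one lesion voxel.  Volumes are optionally
warped in 3D (affine or elastic, probability 0.75 each) before slicing, with
nearest-neighbour resampling for labels.  Contrast dropout zeroes a random
subset of each item's contrasts, and the per-item combination conditions
CondIN.  The loss is the L2 distance between the predicted central-slice
probability map and the (augmented) label, optimized with Adam; the
last-iteration model is the final model.

Inference runs the full self-ensemble: the 24 multi-orientation transforms
each produce a binary 3D mask, the masks are summed into a confidence map,
and two-threshold connected growth yields the final segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from . import _nn
from .fusion import ConfidenceMap, FusionParams, confidence_map, connected_growth, threshold_mask
from .geometry import (
    CONTRASTS,
    PLANE_NORMAL_AXIS,
    PLANES,
    MulticontrastVolume,
    extract_25d,
    list_augmentations,
)
from .model import SegmentationModel, contrast_dropout, segment_volume, standardize_volume
from .normalization import combo_from_present
from .phantom import PhantomSubject

__all__ = [
    "TrainConfig",
    "TrainSubject",
    "sample_batch",
    "augment_3d",
    "train",
    "predict_subject",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization schedule; defaults are the full-scale settings.

    ``desk_scale`` returns the reduced schedule used for phantom-scale
    training in tests and examples.
    """

    lr: float = 1e-4
    batch_size: int = 12
    epochs: int = 150
    iters_per_epoch: int = 300
    elastic_affine_prob: float = 0.75
    contrast_dropout: bool = True
    loss: str = "l2"
    seed: int = 0
    optimizer: str = "adam"
    model_selection: str = "last"

    def __post_init__(self) -> None:
        if min(self.lr, self.batch_size, self.epochs, self.iters_per_epoch) <= 0:
            raise ValueError("lr, batch_size, epochs and iters_per_epoch must be positive")
        if not 0.0 <= self.elastic_affine_prob <= 1.0:
            raise ValueError("elastic_affine_prob must be in [0, 1]")
        if self.loss != "l2" or self.optimizer != "adam" or self.model_selection != "last":
            raise ValueError("supported: loss='l2', optimizer='adam', model_selection='last'")

    @classmethod
    def desk_scale(cls, seed: int = 0) -> "TrainConfig":
        """Phantom-scale schedule: 600 iterations at a learning rate scaled
        up to 1e-3 to compensate for the much shorter run."""
        return cls(lr=1e-3, epochs=2, iters_per_epoch=300, seed=seed)

    def to_dict(self) -> dict:
        return {
            "lr": self.lr,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "iters_per_epoch": self.iters_per_epoch,
            "elastic_affine_prob": self.elastic_affine_prob,
            "contrast_dropout": self.contrast_dropout,
            "loss": self.loss,
            "seed": self.seed,
            "optimizer": self.optimizer,
            "model_selection": self.model_selection,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        return cls(**d)


@dataclass
class TrainSubject:
    """A training unit: a volume plus one or more reference lesion masks."""

    vol: MulticontrastVolume
    labels: list[np.ndarray]

    @classmethod
    def from_phantom(cls, subj: PhantomSubject, use_raters: bool = True) -> "TrainSubject":
        labels = list(subj.raters) if use_raters else [subj.truth]
        return cls(subj.vol, [np.asarray(l, dtype=np.uint8) for l in labels])


def _elastic_warp_coords(shape, rng, disp_sd: float, grid: int = 4):
    """Dense coordinates for a smooth random displacement field."""
    coords = list(np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij"))
    for axis in range(3):
        coarse = rng.normal(0.0, disp_sd, size=(grid,) * 3)
        zoom = [s / grid for s in shape]
        dense = ndimage.zoom(coarse, zoom, order=1, mode="nearest")
        coords[axis] = coords[axis] + dense
    return coords


def _random_affine_matrix(rng, max_rot_deg=10.0, scale_range=(0.95, 1.05), max_shift=2.0):
    angles = np.deg2rad(rng.uniform(-max_rot_deg, max_rot_deg, size=3))
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(rng.uniform(*scale_range, size=3))
    A = Rx @ Ry @ Rz @ S
    shift = rng.uniform(-max_shift, max_shift, size=3)
    return A, shift


def augment_3d(
    vol: MulticontrastVolume,
    labels: Sequence[np.ndarray],
    rng: np.random.Generator,
    prob: float = 0.75,
    elastic_disp_sd: float = 0.6,
) -> tuple[MulticontrastVolume, list[np.ndarray]]:
    """Random 3D affine or elastic warp of a volume and its labels.

    With probability ``prob`` one warp (affine or elastic, equal odds) is
    applied identically to every contrast channel (linear interpolation) and
    every label (nearest neighbour, so labels stay binary).  Otherwise the
    inputs are returned unchanged.
    """
    labels = [np.asarray(l) for l in labels]
    if rng.random() >= prob:
        return vol, list(labels)
    shape = vol.shape
    if rng.random() < 0.5:
        A, shift = _random_affine_matrix(rng)
        center = (np.asarray(shape) - 1) / 2.0
        offset = center - A @ center + shift
        warp_img = lambda c: ndimage.affine_transform(c, A, offset=offset, order=1, mode="constant")
        warp_lab = lambda l: ndimage.affine_transform(
            l.astype(np.uint8), A, offset=offset, order=0, mode="constant"
        )
    else:
        coords = _elastic_warp_coords(shape, rng, elastic_disp_sd)
        warp_img = lambda c: ndimage.map_coordinates(c, coords, order=1, mode="constant")
        warp_lab = lambda l: ndimage.map_coordinates(l.astype(np.uint8), coords, order=0, mode="constant")

    channels = np.stack([
        warp_img(vol.intensities[i]) if vol.present[i] else vol.intensities[i]
        for i in range(len(CONTRASTS))
    ])
    out_vol = MulticontrastVolume(channels, vol.present.copy(), tuple(vol.voxel_spacing), vol.affine.copy())
    return out_vol, [warp_lab(l) for l in labels]


def _dihedral_2d(arr: np.ndarray, rotation: int, flip: bool) -> np.ndarray:
    """In-plane dihedral op on (..., H, W)."""
    axes = (arr.ndim - 2, arr.ndim - 1)
    out = np.rot90(arr, k=rotation, axes=axes)
    if flip:
        out = np.flip(out, axis=axes[1])
    return np.ascontiguousarray(out)


def _take_slice_3d(arr: np.ndarray, plane: str, k: int) -> np.ndarray:
    return np.take(arr, k, axis=PLANE_NORMAL_AXIS[plane])


def _dropout_slab(channels: np.ndarray, present: np.ndarray, rng) -> tuple[np.ndarray, int]:
    """Contrast dropout on a stacked slab; returns the surviving combo."""
    present_idx = np.flatnonzero(present)
    if len(present_idx) > 1:
        pick = 1 + int(rng.integers((1 << len(present_idx)) - 1))
        keep = {int(present_idx[i]) for i in range(len(present_idx)) if pick >> i & 1}
    else:
        keep = {int(present_idx[0])}
    nc = len(CONTRASTS)
    out = channels.copy()
    flags = np.zeros(nc, dtype=bool)
    for i in range(nc):
        if i in keep:
            flags[i] = True
        else:
            out[i::nc] = 0.0  # contrast i occupies channels i, i+4, i+8
    return out, combo_from_present(flags)


def sample_batch(
    dataset: Sequence[TrainSubject],
    rng: np.random.Generator,
    config: TrainConfig,
    _std_cache: Optional[dict] = None,
    return_info: bool = False,
):
    """One training batch: (slabs (n,12,H,W), labels (n,H,W), combos (n,)).

    All items share one plane and one dihedral op; every central label slice
    contains at least one lesion voxel.  With ``return_info`` a fourth
    element describes the shared plane/op and the per-item slice indices.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    plane = PLANES[rng.integers(len(PLANES))]
    rotation = int(rng.integers(4))
    flip = bool(rng.integers(2))

    xs, ys, combos = [], [], []
    slice_indices = []
    for _ in range(config.batch_size):
        si = int(rng.integers(len(dataset)))
        subj = dataset[si]
        if _std_cache is not None:
            if si not in _std_cache:
                _std_cache[si] = standardize_volume(subj.vol)
            svol = _std_cache[si]
        else:
            svol = standardize_volume(subj.vol)
        labels = subj.labels
        if config.elastic_affine_prob > 0:
            wvol, wlabels = augment_3d(svol, labels, rng, prob=config.elastic_affine_prob)
        else:
            wvol, wlabels = svol, list(labels)
        label = wlabels[int(rng.integers(len(wlabels)))]
        axis = PLANE_NORMAL_AXIS[plane]
        sums = label.sum(axis=tuple(a for a in range(3) if a != axis))
        ks = np.flatnonzero(sums)
        if len(ks) == 0:
            # a warp occasionally pushes all lesions out; fall back unwarped
            wvol, label = svol, labels[int(rng.integers(len(labels)))]
            sums = label.sum(axis=tuple(a for a in range(3) if a != axis))
            ks = np.flatnonzero(sums)
        if len(ks) == 0:
            raise ValueError("dataset has no lesion-containing slices")
        k = int(ks[rng.integers(len(ks))])
        slab = extract_25d(wvol, plane, k).channels
        y = _take_slice_3d(label, plane, k).astype(np.float64)
        slab = _dihedral_2d(slab, rotation, flip)
        y = _dihedral_2d(y, rotation, flip)
        if config.contrast_dropout:
            slab, combo = _dropout_slab(slab, wvol.present, rng)
        else:
            combo = combo_from_present(wvol.present)
        xs.append(slab)
        ys.append(y)
        combos.append(combo)
        slice_indices.append(k)
    out = (np.stack(xs), np.stack(ys), np.asarray(combos))
    if return_info:
        info = {"plane": plane, "rotation": rotation, "flip": flip, "slice_indices": slice_indices}
        return out + (info,)
    return out


def train(
    model: SegmentationModel,
    dataset: Sequence[TrainSubject],
    config: TrainConfig,
    n_iterations: Optional[int] = None,
) -> tuple[SegmentationModel, list[float]]:
    """Run the schedule and return (last-iteration model, loss history).

    ``n_iterations`` overrides epochs x iters_per_epoch when given (handy
    for smoke tests).  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng(config.seed)
    total = n_iterations if n_iterations is not None else config.epochs * config.iters_per_epoch
    opt = _nn.Adam(model.parameters(), lr=config.lr)
    cache: dict = {}
    history: list[float] = []
    for it in range(total):
        x, y, combos = sample_batch(dataset, rng, config, _std_cache=cache)
        p = model.forward(x, combos, train=True, use_ttin=False)
        loss = float(((p - y) ** 2).mean())
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: non-finite loss at iteration {it}")
        history.append(loss)
        model.backward(2.0 * (p - y) / y.size)
        opt.step()
        opt.zero_grad()
    return model, history


def predict_subject(
    model: SegmentationModel,
    vol: MulticontrastVolume,
    params: FusionParams = FusionParams(),
    use_ttin: bool = True,
    return_masks: bool = False,
):
    """Full self-ensembled inference on one subject.

    Standardizes the volume, runs all 24 multi-orientation passes, builds
    the confidence map, and fuses with the two-threshold connected growth.
    The contrast combination is inferred from the volume's presence flags.
    Returns (final mask, ConfidenceMap) — plus the per-transform masks in
    listing order when ``return_masks`` is set.
    """
    svol = standardize_volume(vol)
    combo = combo_from_present(vol.present)
    masks = [segment_volume(model, svol, d, combo, use_ttin=use_ttin) for d in list_augmentations()]
    cmap = confidence_map(masks)
    m1 = threshold_mask(cmap, params.tau1)
    m2 = threshold_mask(cmap, params.tau2)
    final = connected_growth(m1, m2)
    if return_masks:
        return final, cmap, masks
    return final, cmap
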