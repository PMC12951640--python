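"""2.5D encoder-decoder segmentation backbone with pluggable normalization.

The network is a U-Net operating on 2.5D slabs (three adjacent slices of
four contrasts, 12 input channels) and predicting a probability map for the
central slice.  Each level applies two blocks of (3x3 convolution, ReLU,
feature normalization); downsampling is 2x2 max pooling and upsampling is
nearest-neighbour interpolation followed by a convolution.  The output is
squashed to [0, 1] with a logistic sigmoid and thresholded at 0.5 to yield
binary masks.

The full-size configuration is 5 levels with 64/128/256/512/1024 channels;
a ``tiny`` preset (2 levels, 8/16 channels) ships for desk-scale training
and tests.  Normalization mode (BN, IN or CondIN) is pluggable, and
inference can switch to test-time instance statistics (TTIN) regardless of
the training mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _nn
from .geometry import (
    CONTRASTS,
    MulticontrastVolume,
    Slab25D,
    TransformDescriptor,
    apply_transform,
    extract_25d,
    invert_transform,
    num_slices,
)

__all__ = [
    "BackboneConfig",
    "TINY_CONFIG",
    "SegmentationModel",
    "build_backbone",
    "predict_slice",
    "segment_volume",
    "contrast_dropout",
    "standardize_volume",
]


@dataclass(frozen=True)
class BackboneConfig:
    levels: int = 5
    channels: tuple[int, ...] = (64, 128, 256, 512, 1024)
    norm_mode: str = "CondIN"
    in_channels: int = 3 * len(CONTRASTS)
    out_channels: int = 1

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 levels")
        if len(self.channels) != self.levels:
            raise ValueError("one channel width per level")
        if any(b <= a for a, b in zip(self.channels, self.channels[1:])):
            raise ValueError("channel widths must be strictly increasing")
        if self.in_channels % 3 != 0:
            raise ValueError("in_channels must be 3 x n_contrasts")

    @property
    def divisor(self) -> int:
        """Spatial extents must be divisible by this (2^(levels-1))."""
        return 1 << (self.levels - 1)

    def to_dict(self) -> dict:
        return {
            "levels": self.levels,
            "channels": list(self.channels),
            "norm_mode": self.norm_mode,
            "in_channels": self.in_channels,
            "out_channels": self.out_channels,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackboneConfig":
        return cls(
            levels=int(d["levels"]),
            channels=tuple(int(c) for c in d["channels"]),
            norm_mode=str(d["norm_mode"]),
            in_channels=int(d["in_channels"]),
            out_channels=int(d["out_channels"]),
        )


TINY_CONFIG = BackboneConfig(levels=2, channels=(8, 16), norm_mode="CondIN")


def _conv_block(cin: int, cout: int, mode: str, rng) -> list:
    """Two (conv 3x3, ReLU, norm) units."""
    layers = []
    for c_in in (cin, cout):
        layers += [_nn.Conv2d(c_in, cout, 3, rng), _nn.ReLU(), _nn.NormLayer(mode, cout)]
    return layers


class SegmentationModel:
    """U-Net over 2.5D slabs; see module docstring for the architecture."""

    def __init__(self, config: BackboneConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        ch = config.channels
        mode = config.norm_mode
        self.enc_blocks = []
        cin = config.in_channels
        for lvl in range(config.levels - 1):
            self.enc_blocks.append(_conv_block(cin, ch[lvl], mode, rng))
            cin = ch[lvl]
        self.pools = [_nn.MaxPool2() for _ in range(config.levels - 1)]
        self.bottleneck = _conv_block(cin, ch[-1], mode, rng)
        self.ups = []
        self.up_convs = []
        self.dec_blocks = []
        for lvl in range(config.levels - 2, -1, -1):
            self.ups.append(_nn.UpsampleNearest2())
            self.up_convs.append(_nn.Conv2d(ch[lvl + 1], ch[lvl], 3, rng))
            self.dec_blocks.append(_conv_block(2 * ch[lvl], ch[lvl], mode, rng))
        self.head = _nn.Conv2d(ch[0], config.out_channels, 1, rng)
        self.sigmoid = _nn.Sigmoid()

    # -- parameter plumbing ------------------------------------------------
    def _all_layers(self):
        for blk in self.enc_blocks:
            yield from blk
        yield from self.pools
        yield from self.bottleneck
        for up, uc, blk in zip(self.ups, self.up_convs, self.dec_blocks):
            yield up
            yield uc
            yield from blk
        yield self.head
        yield self.sigmoid

    def parameters(self):
        for layer in self._all_layers():
            yield from layer.parameters()

    def norm_states(self):
        for layer in self._all_layers():
            if isinstance(layer, _nn.NormLayer):
                yield layer.state

    # -- forward / backward ------------------------------------------------
    @staticmethod
    def _run(layers, x, train, combos, use_ttin):
        for layer in layers:
            if isinstance(layer, _nn.NormLayer):
                x = layer.forward(x, train, combos=combos, use_ttin=use_ttin)
            else:
                x = layer.forward(x, train)
        return x

    def forward(self, x: np.ndarray, combos, *, train: bool = False, use_ttin: bool = False) -> np.ndarray:
        """Map (n, in_channels, H, W) slabs to (n, H, W) probabilities."""
        x = np.asarray(x, dtype=np.float64)
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (n, {self.config.in_channels}, H, W) input, got {x.shape}"
            )
        d = self.config.divisor
        H, W = x.shape[2:]
        pad_h, pad_w = (-H) % d, (-W) % d
        if pad_h or pad_w:
            if train:
                raise ValueError(f"training inputs must have extents divisible by {d}")
            x = np.pad(x, ((0, 0), (0, 0), (0, pad_h), (0, pad_w)))
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            x = self._run(blk, x, train, combos, use_ttin)
            skips.append(x)
            x = pool.forward(x, train)
        x = self._run(self.bottleneck, x, train, combos, use_ttin)
        for up, uc, blk, skip in zip(self.ups, self.up_convs, self.dec_blocks, reversed(skips)):
            x = up.forward(x, train)
            x = uc.forward(x, train)
            x = np.concatenate([skip, x], axis=1)
            x = self._run(blk, x, train, combos, use_ttin)
        x = self.head.forward(x, train)
        x = self.sigmoid.forward(x, train)
        if pad_h or pad_w:
            x = x[:, :, :H, :W]
        if train:
            self._skip_channels = [s.shape[1] for s in skips]
        return x[:, 0]

    def backward(self, gout: np.ndarray) -> None:
        """Backprop a gradient w.r.t. the (n, H, W) probability output."""
        g = np.asarray(gout)[:, None]
        g = self.sigmoid.backward(g)
        g = self.head.backward(g)
        # decoder ran in order ups[0]..ups[-1] with skips reversed; undo in reverse
        skip_gs = [None] * len(self.dec_blocks)
        for idx in range(len(self.dec_blocks) - 1, -1, -1):
            blk = self.dec_blocks[idx]
            for layer in reversed(blk):
                g = layer.backward(g)
            c_skip = self._skip_channels[len(self.dec_blocks) - 1 - idx]
            skip_gs[idx] = g[:, :c_skip]
            g = g[:, c_skip:]
            g = self.up_convs[idx].backward(g)
            g = self.ups[idx].backward(g)
        for layer in reversed(self.bottleneck):
            g = layer.backward(g)
        for lvl in range(len(self.enc_blocks) - 1, -1, -1):
            g = self.pools[lvl].backward(g)
            # dec_blocks are built for levels L-2..0, so the skip from
            # encoder level lvl was consumed at decoder index (L-2 - lvl)
            g = g + skip_gs[len(self.enc_blocks) - 1 - lvl]
            for layer in reversed(self.enc_blocks[lvl]):
                g = layer.backward(g)

    # -- checkpointing -----------------------------------------------------
    def save(self, path) -> None:
        """Write weights (.npz) plus a JSON sidecar describing the config."""
        path = Path(path)
        arrays = {}
        for i, (p, _) in enumerate(self.parameters()):
            arrays[f"p{i}"] = p
        for i, st in enumerate(self.norm_states()):
            if st.mode == "BN":
                arrays[f"mm{i}"] = st.moving_mean
                arrays[f"mv{i}"] = st.moving_var
        np.savez(path, **arrays)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({"backbone": self.config.to_dict()}, indent=2))

    @classmethod
    def load(cls, path) -> "SegmentationModel":
        path = Path(path)
        sidecar = path.with_suffix(".json")
        config = BackboneConfig.from_dict(json.loads(sidecar.read_text())["backbone"])
        model = cls(config)
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            for i, (p, _) in enumerate(model.parameters()):
                p[...] = data[f"p{i}"]
            for i, st in enumerate(model.norm_states()):
                if st.mode == "BN":
                    st.moving_mean = data[f"mm{i}"].copy()
                    st.moving_var = data[f"mv{i}"].copy()
        return model


def build_backbone(config: BackboneConfig, seed: int = 0) -> SegmentationModel:
    """Construct a randomly initialized backbone from a configuration."""
    return SegmentationModel(config, seed=seed)


def predict_slice(model, slab: Slab25D, combo: int, use_ttin: bool = True) -> np.ndarray:
    """Probability map of the slab's central slice, shape (H, W) in [0, 1]."""
    if combo is None:
        raise ValueError("contrast combination required")
    x = slab.channels[None]
    return model.forward(x, np.array([combo]), train=False, use_ttin=use_ttin)[0]


def segment_volume(
    model,
    vol: MulticontrastVolume,
    d: TransformDescriptor,
    combo: int,
    use_ttin: bool = True,
    threshold: float = 0.5,
) -> np.ndarray:
    """Binary 3D mask in the *original* grid from one augmented pass.

    Applies ``d``, predicts slice-by-slice along ``d``'s plane (2.5D),
    thresholds at 0.5, stacks, and maps the stacked mask back through the
    inverse transform.  Slices are batched for speed; per-slice semantics
    are preserved because every inference statistics source is per-instance
    or input-independent.
    """
    tvol = apply_transform(vol, d)
    n = num_slices(tvol, d.plane)
    slabs = np.stack([extract_25d(tvol, d.plane, k).channels for k in range(n)])
    combos = np.full(n, combo)
    probs = model.forward(slabs, combos, train=False, use_ttin=use_ttin)
    from .geometry import PLANE_NORMAL_AXIS  # local import to avoid cycle noise

    # probs[k] is the in-plane slice k; stack back along the plane normal
    mask_t = np.moveaxis(probs > threshold, 0, PLANE_NORMAL_AXIS[d.plane])
    return invert_transform(mask_t.astype(np.uint8), d)


def contrast_dropout(vols: Sequence[MulticontrastVolume], rng: np.random.Generator) -> list[MulticontrastVolume]:
    """Zero a random subset of each volume's present contrasts.

    The surviving combination is drawn uniformly from the non-empty subsets
    of the present contrasts, so at least one contrast always survives and
    (for four-contrast inputs) all 15 combinations occur in training.
    Volumes with a single present contrast are returned unchanged.
    """
    out = []
    for vol in vols:
        present_idx = np.flatnonzero(vol.present)
        if len(present_idx) == 1:
            out.append(vol.copy())
            continue
        subsets = [s for s in range(1, 1 << len(present_idx)) ]
        pick = int(rng.integers(len(subsets)))
        keep = {int(present_idx[i]) for i in range(len(present_idx)) if subsets[pick] >> i & 1}
        v = vol.copy()
        for i in range(len(CONTRASTS)):
            if v.present[i] and i not in keep:
                v.intensities[i] = 0.0
                v.present[i] = False
        out.append(MulticontrastVolume(v.intensities, v.present, tuple(v.voxel_spacing), v.affine))
    return out


def standardize_volume(vol: MulticontrastVolume) -> MulticontrastVolume:
    """Per-contrast z-scoring over nonzero voxels; zeros (air, absent) stay zero.

    Applied before the network so absent contrasts remain exactly-zero
    channels, matching what contrast dropout produces in training.
    """
    v = vol.copy()
    for i in range(len(CONTRASTS)):
        if not v.present[i]:
            continue
        chan = v.intensities[i]
        nz = chan != 0
        if nz.sum() < 2:
            continue
        mu = chan[nz].mean()
        sd = chan[nz].std()
        if sd == 0:
            sd = 1.0
        chan[nz] = (chan[nz] - mu) / sd
    return v
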