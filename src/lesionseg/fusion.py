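"""Self-ensembled lesion fusion of multi-orientation TTA predictions.

Given N binary masks of the same volume (one per test-time transform), the
voxel-wise integer sum forms a *confidence map* C(r) in [0, N].  Two
thresholds tau1 >= tau2 then yield a high-confidence *detection* mask
M1 = [C > tau1] and a permissive *candidate* mask M2 = [C > tau2], and the
final segmentation is obtained by growing each detected lesion into the
26-connected component of M2 that contains it — a 3D analogue of the
hysteresis thresholding used in Canny edge detection.  Candidate components
with no detected voxel never appear in the output.

Defaults tau1 = 16, tau2 = 7 (for N = 24) follow cross-validated settings;
majority voting is the degenerate case tau1 = tau2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ConfidenceMap",
    "FusionParams",
    "confidence_map",
    "threshold_mask",
    "connected_growth",
    "fuse",
    "majority_vote",
    "CONNECTIVITY_26",
]

#: full 3x3x3 neighbourhood: voxels sharing a face, edge or corner connect
CONNECTIVITY_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class ConfidenceMap:
    """Voxel-wise count of positive predictions; integers in [0, n_models]."""

    C: np.ndarray
    n_models: int

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C)
        if not np.issubdtype(self.C.dtype, np.integer):
            raise ValueError("confidence map must be integer-valued")
        if self.C.min(initial=0) < 0 or self.C.max(initial=0) > self.n_models:
            raise ValueError(f"confidence values must lie in [0, {self.n_models}]")


@dataclass(frozen=True)
class FusionParams:
    """Detection threshold tau1 and growth threshold tau2 (tau1 >= tau2 >= 0)."""

    tau1: int = 16
    tau2: int = 7

    def __post_init__(self) -> None:
        if not (self.tau1 >= self.tau2 >= 0):
            raise ValueError(f"need tau1 >= tau2 >= 0, got ({self.tau1}, {self.tau2})")


def _as_binary_stack(masks: Sequence[np.ndarray]) -> np.ndarray:
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    stack = np.stack([np.asarray(m) for m in masks])
    if stack.ndim != 4:
        raise ValueError("masks must be 3D arrays of identical shape")
    vals = np.unique(stack)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"masks must be binary, found values {vals[:5]}")
    return stack.astype(np.uint8)


def confidence_map(masks: Sequence[np.ndarray]) -> ConfidenceMap:
    """Voxel-wise sum of N binary masks on a common grid."""
    stack = _as_binary_stack(masks)
    return ConfidenceMap(stack.sum(axis=0, dtype=np.int32), n_models=stack.shape[0])


def threshold_mask(cmap: ConfidenceMap, tau: int) -> np.ndarray:
    """Strict threshold: voxels with C(r) > tau."""
    if not 0 <= tau <= cmap.n_models:
        raise ValueError(f"tau must be in [0, {cmap.n_models}], got {tau}")
    return (cmap.C > tau).astype(np.uint8)


def connected_growth(m1: np.ndarray, m2: np.ndarray) -> np.ndarray:
    """Grow detected lesions (m1) into their 26-connected m2 components.

    Implemented as component labelling of m2 followed by selection of the
    labels that contain at least one m1 voxel — the fixed point of
    iteratively dilating m1 within m2 under 26-connectivity.
    """
    m1 = np.asarray(m1).astype(bool)
    m2 = np.asarray(m2).astype(bool)
    if m1.shape != m2.shape:
        raise ValueError("m1 and m2 must share a grid")
    if (m1 & ~m2).any():
        raise ValueError("contract violation: m1 must be a subset of m2")
    labels, n = ndimage.label(m2, structure=CONNECTIVITY_26)
    if n == 0 or not m1.any():
        return np.zeros_like(m2, dtype=np.uint8)
    seeded = np.unique(labels[m1])
    seeded = seeded[seeded > 0]
    return np.isin(labels, seeded).astype(np.uint8)


def fuse(masks: Sequence[np.ndarray], params: FusionParams = FusionParams()) -> np.ndarray:
    """Full two-threshold fusion of N binary masks; M1 ⊆ result ⊆ M2."""
    cmap = confidence_map(masks)
    if params.tau1 > cmap.n_models:
        raise ValueError(f"tau1={params.tau1} exceeds the number of masks {cmap.n_models}")
    m1 = threshold_mask(cmap, params.tau1)
    m2 = threshold_mask(cmap, params.tau2)
    return connected_growth(m1, m2)


def majority_vote(masks: Sequence[np.ndarray], threshold: int | None = None) -> np.ndarray:
    """Voxel-wise majority voting: fuse with tau1 = tau2 = threshold.

    The default is the strict majority of N masks, C(r) > floor(N/2)
    (for N = 24, voxels with 13 or more positive votes).  Pass an explicit
    ``threshold`` to reproduce other voting conventions.
    """
    cmap = confidence_map(masks)
    t = cmap.n_models // 2 if threshold is None else int(threshold)
    return fuse(masks, FusionParams(tau1=t, tau2=t))
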