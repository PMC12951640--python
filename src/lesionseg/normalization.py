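"""Feature normalization: BN / IN / conditional IN, and the test-time switch.

A normalization layer standardizes each feature channel x_j,

    x_hat_j = (x_j - E[x_j]) / sqrt(Var[x_j] + eps),        y_j = gamma_j * x_hat_j + beta_j,

and differs only in *where* the statistics E and Var come from:

* **BN** (batch norm): statistics over the whole mini-batch and spatial
  dims; exponential moving averages are stored during training and replace
  the batch statistics at test time.
* **IN** (instance norm): statistics over the spatial dims of each instance
  separately; no moving averages.
* **CondIN** (conditional IN): instance statistics, but a separate learned
  (gamma, beta) pair per input contrast combination — 15 sets for the four
  MR contrasts (every non-empty subset of {T1w, T2w, PDw, FLAIR}).

**TTIN** (test-time instance normalization) recomputes E and Var from the
single test input (batch size one) regardless of training mode, while gamma
and beta are retained from training.  This makes the normalized features
invariant to per-channel affine intensity perturbations of the input, which
is what confers robustness to domain shift and missing contrasts.

Contrast combinations are encoded as a bitmask with bit 0 = T1w, bit 1 =
T2w, bit 2 = PDw, bit 3 = FLAIR; valid masks are 1..15 and CondIN stores
its parameter sets at index ``bitmask - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import CONTRASTS

__all__ = [
    "N_COMBINATIONS",
    "NormalizationState",
    "combo_from_present",
    "combo_contrasts",
    "all_combinations",
    "normalize_train",
    "normalize_ttin",
    "select_affine",
]

N_COMBINATIONS = (1 << len(CONTRASTS)) - 1  # 15 non-empty subsets


def combo_from_present(present) -> int:
    """Bitmask of a presence-flag vector (bit i = CONTRASTS[i])."""
    present = np.asarray(present, dtype=bool)
    if present.shape != (len(CONTRASTS),):
        raise ValueError("present must have one flag per contrast")
    mask = int(sum(1 << i for i, p in enumerate(present) if p))
    _check_combo(mask)
    return mask


def combo_contrasts(combo: int) -> tuple[str, ...]:
    """Names of the contrasts present in a combination bitmask."""
    _check_combo(combo)
    return tuple(c for i, c in enumerate(CONTRASTS) if combo >> i & 1)


def all_combinations() -> tuple[int, ...]:
    """The 15 valid combination bitmasks, ascending."""
    return tuple(range(1, N_COMBINATIONS + 1))


def _check_combo(combo: int) -> None:
    if not 1 <= int(combo) <= N_COMBINATIONS:
        raise ValueError(f"contrast combination must be in 1..{N_COMBINATIONS}, got {combo}")


@dataclass
class NormalizationState:
    """Learnable affine parameters plus (for BN) running statistics.

    ``gamma``/``beta`` have shape (c,) for BN and IN, (15, c) for CondIN.
    """

    mode: str  # "BN" | "IN" | "CondIN"
    gamma: np.ndarray
    beta: np.ndarray
    moving_mean: Optional[np.ndarray] = None
    moving_var: Optional[np.ndarray] = None
    eps: float = 1e-5
    momentum: float = 0.1

    def __post_init__(self) -> None:
        if self.mode not in ("BN", "IN", "CondIN"):
            raise ValueError(f"unknown normalization mode {self.mode!r}")
        self.gamma = np.asarray(self.gamma, dtype=np.float64)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        expected_ndim = 2 if self.mode == "CondIN" else 1
        if self.gamma.ndim != expected_ndim or self.gamma.shape != self.beta.shape:
            raise ValueError(f"{self.mode} expects gamma/beta of ndim {expected_ndim}")
        if self.mode == "CondIN" and self.gamma.shape[0] != N_COMBINATIONS:
            raise ValueError(f"CondIN needs {N_COMBINATIONS} parameter sets, got {self.gamma.shape[0]}")
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.mode == "BN":
            c = self.gamma.shape[0]
            if self.moving_mean is None:
                self.moving_mean = np.zeros(c)
            if self.moving_var is None:
                self.moving_var = np.ones(c)

    @property
    def n_channels(self) -> int:
        return self.gamma.shape[-1]

    @classmethod
    def create(cls, mode: str, n_channels: int, eps: float = 1e-5, momentum: float = 0.1) -> "NormalizationState":
        shape = (N_COMBINATIONS, n_channels) if mode == "CondIN" else (n_channels,)
        return cls(mode, np.ones(shape), np.zeros(shape), eps=eps, momentum=momentum)


def select_affine(state: NormalizationState, combo: int) -> tuple[np.ndarray, np.ndarray]:
    """(gamma, beta) for a combination: combo-indexed for CondIN, shared otherwise."""
    _check_combo(combo)
    if state.mode == "CondIN":
        return state.gamma[combo - 1], state.beta[combo - 1]
    return state.gamma, state.beta


def _combo_per_item(combo, n: int) -> np.ndarray:
    combos = np.broadcast_to(np.asarray(combo, dtype=int), (n,)).copy()
    for c in combos:
        _check_combo(int(c))
    return combos


def _affine_per_item(state: NormalizationState, combos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Stack per-item (gamma, beta) as (n, c) arrays."""
    g = np.stack([select_affine(state, int(c))[0] for c in combos])
    b = np.stack([select_affine(state, int(c))[1] for c in combos])
    return g, b


def normalize_train(
    x: np.ndarray,
    state: NormalizationState,
    combo=None,
    *,
    update_stats: bool = True,
    return_cache: bool = False,
):
    """Training-mode normalization of an (n, c, H, W) feature map.

    BN normalizes over (batch, spatial) and, if ``update_stats``, updates the
    moving averages with momentum ``state.momentum``.  IN/CondIN normalize
    each instance over its spatial dims only.  ``combo`` may be a scalar or a
    per-item array; it is required for CondIN and ignored otherwise (pass it
    anyway for uniform call sites).
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"expected (n, c, H, W) feature map, got shape {x.shape}")
    n, c = x.shape[:2]
    if n < 1:
        raise ValueError("batch must be non-empty")
    if c != state.n_channels:
        raise ValueError(f"channel mismatch: x has {c}, state has {state.n_channels}")

    if state.mode == "BN":
        mean = x.mean(axis=(0, 2, 3))
        var = x.var(axis=(0, 2, 3))
        if update_stats:
            m = state.momentum
            state.moving_mean = (1 - m) * state.moving_mean + m * mean
            state.moving_var = (1 - m) * state.moving_var + m * var
        xhat = (x - mean[None, :, None, None]) / np.sqrt(var[None, :, None, None] + state.eps)
        g, b = state.gamma, state.beta
        y = g[None, :, None, None] * xhat + b[None, :, None, None]
        cache = (xhat, var, g, None)
    else:
        if state.mode == "CondIN" and combo is None:
            raise ValueError("CondIN requires a contrast combination")
        combos = _combo_per_item(combo if combo is not None else N_COMBINATIONS, n)
        mean = x.mean(axis=(2, 3), keepdims=True)
        var = x.var(axis=(2, 3), keepdims=True)
        xhat = (x - mean) / np.sqrt(var + state.eps)
        g, b = _affine_per_item(state, combos)
        y = g[:, :, None, None] * xhat + b[:, :, None, None]
        cache = (xhat, var, g, combos)
    if return_cache:
        return y, cache
    return y


def normalize_ttin(x: np.ndarray, state: NormalizationState, combo=None) -> np.ndarray:
    """Test-time instance normalization of a single (1, c, H, W) input.

    Statistics come from this input's spatial dims alone; gamma/beta are the
    trained parameters (combo-indexed under CondIN).  Moving averages are
    never consulted or modified.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 4:
        raise ValueError(f"expected (1, c, H, W) feature map, got shape {x.shape}")
    if x.shape[0] != 1:
        raise ValueError(f"TTIN requires batch size one, got {x.shape[0]}")
    if x.shape[1] != state.n_channels:
        raise ValueError("channel mismatch")
    if state.mode == "CondIN" and combo is None:
        raise ValueError("CondIN requires a contrast combination")
    mean = x.mean(axis=(2, 3), keepdims=True)
    var = x.var(axis=(2, 3), keepdims=True)
    xhat = (x - mean) / np.sqrt(var + state.eps)
    g, b = select_affine(state, int(np.asarray(combo).flat[0])) if combo is not None else (state.gamma, state.beta)
    return g[None, :, None, None] * xhat + b[None, :, None, None]


def normalize_eval_bn(x: np.ndarray, state: NormalizationState) -> np.ndarray:
    """Classic BN inference: normalize with the stored moving averages.

    A pure per-channel affine map of the input — no dependence on the test
    instance — which is exactly why it is brittle under domain shift.
    """
    if state.mode != "BN":
        raise ValueError("moving-statistics inference is only defined for BN")
    x = np.asarray(x, dtype=np.float64)
    mean = state.moving_mean[None, :, None, None]
    var = state.moving_var[None, :, None, None]
    xhat = (x - mean) / np.sqrt(var + state.eps)
    return state.gamma[None, :, None, None] * xhat + state.beta[None, :, None, None]
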