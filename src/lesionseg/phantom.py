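"""Synthetic multicontrast MS phantoms with ground truth and simulated raters.

A phantom is a skull-stripped-looking ellipsoidal "brain" on a dark
background, carrying a configurable number of lesions built as unions of
random ellipsoids (so confluent lesions occur and exercise the connected
component code).  Per-contrast rendering follows MS lesion appearance:
lesions are hyperintense on T2w/PDw/FLAIR and hypointense on T1w.  A
central CSF-like region reproduces the informativeness asymmetry of real
multicontrast MRI: it is bright on T2w/PDw (so lesions are confusable with
fluid there) and suppressed on FLAIR (fluid-attenuated), and the default
lesion offsets are strongest on FLAIR and weakest on T1w.  Dropping FLAIR
therefore genuinely removes the dominant lesion evidence, as it does in
clinical data.  On top of the piecewise-constant tissue model the generator
adds a smooth multiplicative bias field and white Gaussian noise, and can
zero out contrasts to emulate missing acquisitions.

Two simulated raters are derived from the true mask by randomly perturbing
each lesion's boundary (partial one-voxel dilation or erosion), emulating
inter-rater variability at a realistic agreement level (Dice with truth
around 0.8-0.9 at default settings).

Everything is reproducible from a single seed.  The phantoms emulate the
statistical structure the segmentation pipeline cares about — contrast
polarity, lesion multiplicity and confluence, rater disagreement, noise,
bias, missing contrasts — not brain anatomy.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .geometry import CONTRASTS, MulticontrastVolume

__all__ = [
    "PhantomConfig",
    "PhantomSubject",
    "generate_phantom",
    "corrupt",
    "make_dataset",
    "CORRUPTION_KINDS",
]

CORRUPTION_KINDS = ("gaussian_noise", "bias_field", "blur", "gamma", "drop_contrast")


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters; intensities are in arbitrary units.

    ``lesion_contrast`` holds the signed lesion-minus-tissue offset per
    contrast in channel order (T1w, T2w, PDw, FLAIR): negative for T1w
    (hypointense lesions), positive elsewhere (hyperintense), largest on
    FLAIR.  ``csf_offset`` is the CSF-minus-tissue offset of the central
    fluid region (bright on T2w/PDw, dark on T1w and FLAIR).
    ``rater_jitter`` is the probability that each boundary-shell voxel of a
    lesion is toggled when simulating a rater.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    n_lesions: int = 4
    lesion_radius_range: tuple[float, float] = (2.2, 4.2)
    tissue_means: tuple[float, ...] = (120.0, 100.0, 110.0, 90.0)
    lesion_contrast: tuple[float, ...] = (-15.0, 25.0, 20.0, 45.0)
    csf_offset: tuple[float, ...] = (-40.0, 50.0, 25.0, -30.0)
    noise_sd: float = 5.0
    bias_field_amplitude: float = 0.15
    rater_jitter: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be non-negative")
        lo, hi = self.lesion_radius_range
        if lo < 1 or hi < lo:
            raise ValueError("lesion radii must satisfy 1 <= lo <= hi")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for tup in (self.tissue_means, self.lesion_contrast, self.csf_offset):
            if len(tup) != len(CONTRASTS):
                raise ValueError("one tissue mean, lesion offset and CSF offset per contrast")


@dataclass
class PhantomSubject:
    vol: MulticontrastVolume
    truth: np.ndarray
    rater1: np.ndarray
    rater2: np.ndarray
    config: PhantomConfig

    @property
    def raters(self) -> tuple[np.ndarray, np.ndarray]:
        return (self.rater1, self.rater2)


def _ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semiaxes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _brain_mask(shape) -> np.ndarray:
    center = [(s - 1) / 2 for s in shape]
    semiaxes = [0.44 * s for s in shape]
    return _ellipsoid_mask(shape, center, semiaxes)


def _csf_mask(shape, rng) -> np.ndarray:
    """Ventricle-like central fluid region with a jittered pose."""
    center = [(s - 1) / 2 + rng.uniform(-1.5, 1.5) for s in shape]
    semiaxes = [rng.uniform(0.10, 0.16) * s for s in shape]
    return _ellipsoid_mask(shape, center, semiaxes)


def _smooth_bias(shape, amplitude, rng) -> np.ndarray:
    """Low-order multiplicative field 1 + amplitude * p(x), |p| <= 1."""
    if amplitude == 0:
        return np.ones(shape)
    coords = [np.linspace(-1, 1, s) for s in shape]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    basis = [X, Y, Z, X * Y, X * Z, Y * Z, X**2, Y**2, Z**2]
    coeff = rng.normal(size=len(basis))
    p = sum(c * b for c, b in zip(coeff, basis))
    p = p / max(1e-12, np.abs(p).max())
    return 1.0 + amplitude * p


def _place_lesions(config: PhantomConfig, brain: np.ndarray, csf: np.ndarray, rng) -> np.ndarray:
    shape = config.shape
    lo, hi = config.lesion_radius_range
    margin = int(np.ceil(hi)) + 1
    interior = ndimage.binary_erosion(brain, iterations=margin) & ~csf
    centers = np.argwhere(interior)
    if config.n_lesions > 0 and len(centers) == 0:
        raise ValueError("lesions cannot fit in the given shape")
    truth = np.zeros(shape, dtype=bool)
    for _ in range(config.n_lesions):
        c = centers[rng.integers(len(centers))] + rng.uniform(-0.5, 0.5, size=3)
        semi = rng.uniform(lo, hi, size=3)
        truth |= _ellipsoid_mask(shape, c, semi)
    # lesions may abut the fluid region (periventricular) but not enter it
    return truth & brain & ~csf


def _jitter_rater(truth: np.ndarray, jitter: float, rng) -> np.ndarray:
    """Perturb each lesion's boundary shell: partial dilation or erosion."""
    labels, n = ndimage.label(truth, structure=np.ones((3, 3, 3)))
    rater = truth.copy()
    struct = ndimage.generate_binary_structure(3, 1)
    for lab in range(1, n + 1):
        lesion = labels == lab
        if rng.random() < 0.5:  # partial dilation
            shell = ndimage.binary_dilation(lesion, structure=struct) & ~truth
            add = shell & (rng.random(truth.shape) < jitter)
            rater |= add
        else:  # partial erosion
            shell = lesion & ~ndimage.binary_erosion(lesion, structure=struct)
            drop = shell & (rng.random(truth.shape) < jitter)
            candidate = rater & ~drop
            if (candidate & lesion).any():  # never erase a lesion entirely
                rater = candidate
    return rater


def generate_phantom(config: PhantomConfig) -> PhantomSubject:
    """Render one phantom: volume, true mask and two simulated rater masks."""
    rng = np.random.default_rng(config.seed)
    brain = _brain_mask(config.shape)
    csf = _csf_mask(config.shape, rng) & brain
    truth = _place_lesions(config, brain, csf, rng)

    channels = np.zeros((len(CONTRASTS),) + tuple(config.shape))
    for i in range(len(CONTRASTS)):
        img = np.where(brain, config.tissue_means[i], 0.0)
        img = img + np.where(csf, config.csf_offset[i], 0.0)
        img = img + np.where(truth, config.lesion_contrast[i], 0.0)
        img = img * _smooth_bias(config.shape, config.bias_field_amplitude, rng)
        noise = rng.normal(0.0, config.noise_sd, size=config.shape) if config.noise_sd else 0.0
        img = np.where(brain, img + noise, 0.0)
        channels[i] = img
    vol = MulticontrastVolume(channels, np.ones(len(CONTRASTS), dtype=bool))

    rater1 = _jitter_rater(truth, config.rater_jitter, rng).astype(np.uint8)
    rater2 = _jitter_rater(truth, config.rater_jitter, rng).astype(np.uint8)
    return PhantomSubject(vol, truth.astype(np.uint8), rater1, rater2, config)


def corrupt(
    vol: MulticontrastVolume,
    kind: str,
    magnitude: float,
    seed: int = 0,
    contrast: str = "flair",
) -> MulticontrastVolume:
    """Apply a domain-shift corruption; ``magnitude`` 0 is the identity
    for the continuous kinds.  ``drop_contrast`` zeroes the named contrast
    and clears its presence flag regardless of magnitude.
    """
    if kind not in CORRUPTION_KINDS:
        raise ValueError(f"unknown corruption kind {kind!r}")
    rng = np.random.default_rng(seed)
    v = vol.copy()
    present = np.flatnonzero(v.present)

    if kind == "drop_contrast":
        idx = CONTRASTS.index(contrast)
        if v.present[idx] and v.present.sum() == 1:
            raise ValueError("cannot drop the last present contrast")
        v.intensities[idx] = 0.0
        v.present[idx] = False
        return MulticontrastVolume(v.intensities, v.present, tuple(v.voxel_spacing), v.affine)
    if magnitude == 0:
        return v
    for i in present:
        chan = v.intensities[i]
        support = chan != 0
        if kind == "gaussian_noise":
            chan[support] += rng.normal(0.0, magnitude, size=int(support.sum()))
        elif kind == "bias_field":
            chan *= _smooth_bias(chan.shape, magnitude, rng)
        elif kind == "blur":
            blurred = ndimage.gaussian_filter(chan, sigma=magnitude)
            chan[...] = np.where(support, blurred, 0.0)
        elif kind == "gamma":
            peak = chan[support].max()
            if peak > 0:
                scaled = np.clip(chan / peak, 0.0, None)
                chan[...] = np.where(support, peak * scaled ** (1.0 + magnitude), 0.0)
    return v


def make_dataset(
    n_subjects: int,
    template: PhantomConfig = PhantomConfig(),
    seed: int = 0,
    val_fraction: float = 0.2,
) -> tuple[list[PhantomSubject], list[PhantomSubject]]:
    """Generate a cohort with varied lesion load and tissue intensities.

    Per-subject configs are drawn reproducibly from ``seed``: lesion count
    varies by +/-2 around the template, tissue means by +/-10%, lesion
    offsets by +/-20%.  Returns a (train, val) split with the last
    ``val_fraction`` of subjects held out.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    rng = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        n_les = max(1, template.n_lesions + int(rng.integers(-2, 3)))
        means = tuple(m * rng.uniform(0.9, 1.1) for m in template.tissue_means)
        offsets = tuple(o * rng.uniform(0.8, 1.2) for o in template.lesion_contrast)
        cfg = replace(
            template,
            n_lesions=n_les,
            tissue_means=means,
            lesion_contrast=offsets,
            seed=int(rng.integers(2**31 - 1)),
        )
        subjects.append(generate_phantom(cfg))
    n_val = int(round(n_subjects * val_fraction))
    if n_val == 0:
        return subjects, []
    return subjects[:-n_val], subjects[-n_val:]
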