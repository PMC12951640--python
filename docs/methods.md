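# Methods

## Problem and approach

Automated segmentation of multiple sclerosis (MS) white-matter lesions from
multicontrast MRI (T1w, T2w, PDw, FLAIR) must cope with small training
sets, domain shift across scanners and protocols, and contrasts that are
simply missing at test time.  This package implements a single ("unified")
2.5D segmentation network wrapped in two test-time mechanisms that address
accuracy and robustness separately:

1. **Self-ensembled lesion fusion.**  At inference the input volume is
   processed 24 times — the 8 in-plane dihedral operations (rotations by
   0°/90°/180°/270°, each optionally composed with a flip) applied within
   each of the 3 cardinal planes.  Each pass produces a binary mask (slice
   probabilities thresholded at 0.5, stacked, mapped back through the exact
   inverse transform).  The voxel-wise sum of the N_M = 24 masks is an
   integer *confidence map* C(r) ∈ [0, 24].  Two thresholds τ1 ≥ τ2 give a
   detection mask M1 = [C > τ1] and a candidate mask M2 = [C > τ2]; the
   final mask is the union of the 26-connected components of M2 that
   contain at least one M1 voxel.  This is hysteresis thresholding in 3D:
   a lesion needs high confidence *somewhere* to exist, but only moderate
   confidence to have extent.  Defaults τ1 = 16, τ2 = 7 follow
   cross-validated values; majority voting is the special case τ1 = τ2.

2. **Test-time instance normalization (TTIN).**  Every normalization layer
   computes `x̂_j = (x_j − E[x_j]) / √(Var[x_j] + ε)`, `y_j = γ_j x̂_j + β_j`.
   Under TTIN the statistics E, Var are computed from the *single test
   input's* spatial dimensions (batch size one per 2.5D slab), while γ, β
   are retained from training.  The normalized features are then invariant
   to per-channel affine perturbations of the layer input, which removes
   much of the latent-feature mismatch caused by scanner shift or by
   zeroed-out (missing) contrasts.  Three training modes provide the
   affine parameters: batch norm (BN, with moving averages for classic
   inference), instance norm (IN), and conditional IN (CondIN) with one
   (γ, β) set per non-empty contrast subset — 15 sets for four contrasts,
   indexed by a bitmask (bit 0 = T1w … bit 3 = FLAIR, slot = bitmask − 1).

Training uses contrast dropout (CD): each sampled slab keeps a surviving
contrast combination drawn uniformly from the non-empty subsets of its
present contrasts (so all 15 combinations occur and at least one contrast
always survives), and CondIN conditions on the combination actually fed.

## Backbone and training procedure

The backbone is a U-Net over 2.5D slabs: three adjacent slices of each
contrast concatenated channel-wise (12 input channels, slice-major /
contrast-minor order, zero-filled at volume boundaries), predicting the
probability map of the central slice.  Each level applies two blocks of
(3×3 convolution → ReLU → feature normalization); downsampling is 2×2 max
pooling, upsampling is nearest-neighbour followed by a convolution, and a
1×1 convolution plus logistic sigmoid produces the output.  The full-size
configuration is 5 levels with 64/128/256/512/1024 channels; a *tiny*
preset (2 levels, 8/16 channels) is used for all desk-scale experiments.

The network, its normalization layers and the optimizer are implemented
from scratch in NumPy (float64, fully deterministic), with analytically
derived backward passes verified against central finite differences in all
three normalization modes (relative error < 1e-7).

Batches sample lesion-containing 2.5D slabs: one plane and one dihedral op
shared per batch, per-item random subject, random rater label, and a
central slice constrained to contain lesion; 3D affine or elastic warps
(probability 0.75, nearest-neighbour for labels) precede slicing.  The loss
is the L2 distance between the predicted central-slice probabilities and
the label, optimized with Adam; the last-iteration model is used.  Only
the central slice carries supervision.  Full-scale defaults: learning rate
1e-4, batch 12, 150 epochs × 300 iterations.  The **desk-scale schedule**
(`TrainConfig.desk_scale`) is 600 iterations at learning rate 1e-3 — the
rate is scaled up because the schedule is ~75× shorter; with the tiny
backbone on 32³ phantoms the loss plateaus within this budget (~3 minutes
on one CPU).

## Synthetic phantoms: what they emulate, and what they do not

The phantom generator provides ground truth for every test.  Each phantom
is an ellipsoidal "brain" (zero outside, emulating skull-stripping) of
32³ voxels with:

* **lesions** — unions of random ellipsoids (radii 2.2–4.2 voxels, default
  4 per subject, varied ±2 across a cohort), so confluent lesions exercise
  the connected-component code; hypointense on T1w, hyperintense on
  T2w/PDw and most strongly on FLAIR (default offsets −15/+25/+20/+45
  against tissue means 120/100/110/90);
* **a CSF-like central region** — bright on T2w (+50) and PDw (+25), dark
  on T1w (−40) and *suppressed on FLAIR* (−30).  This reproduces the
  informativeness asymmetry of clinical MRI: on T2w/PDw lesions are
  confusable with fluid, while FLAIR shows lesions on a clean background.
  Without this asymmetry all four contrasts are redundant and
  missing-contrast robustness cannot be probed at all;
* **two simulated raters** — per-lesion partial dilation or erosion of the
  boundary shell (each shell voxel toggled with probability 0.4), giving
  rater-vs-truth Dice ≈ 0.8–0.9, a realistic inter-rater regime;
* **corruptions** — additive Gaussian noise (default σ = 5), a smooth
  low-order multiplicative bias field (±15%), blur, gamma transformation,
  and contrast drop (zero channel + cleared presence flag).

Not emulated: brain anatomy (no atlas or tissue classes beyond the fluid
region), k-space artifacts (motion, ghosting), anisotropic acquisition.
Consequently, passing desk-scale tests demonstrates that the mechanisms
work as specified (fusion recovers lesions, TTIN confers missing-contrast
robustness) — not that clinical-grade accuracy would be reached on real
MRI, which additionally requires full-scale training on expert-labelled
data.

## Desk-scale study design

The end-to-end study (`lesionseg.experiments.run_recovery_study`) trains
two tiny models on the same 12 phantoms and evaluates on 10 held-out
phantoms: (a) CD + CondIN, run with TTIN; (b) no CD + BN, run with BN
moving statistics.  It measures (i) the fused Dice of (a) against the
per-plane single-orientation Dice, (ii) the challenge-style composite
Score = DSC/8 + PPV/8 + LTPR/4 + (1−LFPR)/4 + VC/4 against the two
simulated raters, and (iii) the median Dice lost when FLAIR is dropped at
test time, for (a) vs (b).  In this regime the BN model without dropout
collapses when FLAIR is missing (an all-zero channel is far outside its
training distribution and its stored statistics cannot adapt), while the
CD + CondIN + TTIN model degrades only mildly — the desk-scale analogue of
the out-of-domain behaviour the method targets.  The cohort sizes
(12 train / 10 eval) and the tiny backbone keep the full study at roughly
ten CPU-minutes.

## Numerical and design choices

* ε = 1e-5 in the normalization denominator; BN moving-average momentum
  0.1 (conventional defaults; neither is stated by the method's source).
* Zero-variance channels (e.g. features driven by a dropped contrast)
  normalize to β through the ε guard; no special-casing.
* Strict inequalities C > τ in both fusion thresholds, implemented
  literally.  Growth is component labelling of M2 plus selection by M1
  overlap — equivalent to iterated 26-neighbour dilation of M1 within M2
  (a tested property against a BFS flood-fill oracle), but cheaper.
* Majority voting defaults to the strict majority C > ⌊N/2⌋ (13+ of 24).
  The convention "τ1 = τ2 = 13" seen elsewhere is available as an explicit
  threshold override; with strict inequality it demands 14+ votes, and the
  ambiguity is deliberately left to the caller.
* Axis convention: arrays are (X, Y, Z) with axial slices orthogonal to Z;
  rotations are counter-clockwise in index space; the flip reverses the
  second in-plane axis after rotation.  On loading NIfTI, volumes are
  reoriented to the closest canonical (RAS) orientation.  Non-cubic
  volumes are supported; 90°/270° rotations swap in-plane extents.
* Input intensities are z-scored per contrast per volume over nonzero
  voxels before the network (zeros — air and absent contrasts — stay
  exactly zero, matching what contrast dropout produces).
* Lesion-wise metrics use 26-connectivity by default (matching the growth
  step), with 18/6 available; one shared voxel counts as detection.
  Empty-mask conventions: empty/empty is perfect (DSC = PPV = TPR = LTPR
  = 1, LFPR = 0); empty prediction vs non-empty reference is all-zero
  except LFPR = 0.  Scores are reported on [0, 1]; multiply by 100 for
  the conventional percentage display.
* Checkpoints are a `.npz` of parameters (plus BN moving statistics) with
  a JSON sidecar describing the architecture; save → load → predict is
  bit-identical.

## Known limitations

* Training the full-size 5-level backbone is out of desk-scale reach; the
  full configuration is constructed and shape-checked but all learning
  experiments use the tiny preset.
* TTIN assumes each test slab has informative spatial statistics; slabs
  that are almost entirely background rely on the ε guard and produce
  near-constant features (handled, but with no useful signal).
* The elastic-warp field is a coarse 4³ control grid linearly upsampled —
  adequate for augmentation diversity, not a diffeomorphism guarantee.
* Fusion accepts any N ≥ 1 masks, but τ defaults (16, 7) presume N = 24;
  callers using partial ensembles must rescale thresholds.
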