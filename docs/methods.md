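# Methods

## The problem

A scanning two-photon fiberscope builds each frame from concentric spirals
traced by a resonant fiber cantilever.  Its frame rate is

    frame_rate = duty_ratio × scanning_speed / scanning_density,

with the scanning speed (spirals/s) fixed by the scanner resonance and the
scanning density (spirals/frame) setting the radial sampling.  Raising the
frame rate therefore costs image quality twice over: a faster scan shortens
the pixel dwell time (more shot noise), and a sparser scan drops radial
rings (less resolution).  This package implements the computational half of
the solution: simulate the degradation, restore it with a two-stage
conditional-GAN protocol, and quantify what survives.

## Scan model

`scanmodel` treats the spiral geometry as concentric rings on the Cartesian
frame.  `build_ring_map` labels every pixel with
`floor(r / Δr)`, `Δr = R_corner / density`, centered at `((H−1)/2, (W−1)/2)`
with the outermost ring at the corner radius.  Uniform ring spacing is a
declared simplification — resonant spiral scanners are radially nonuniform —
and is isolated in `build_ring_map` for later replacement.  Densities finer
than one pixel per ring are rejected; full 512-ring maps therefore need a
frame of ≥ 725 px on a side (tests use 760).

`radial_downsample` keeps rings with index ≡ 0 (mod M) bit-identically and
regrids the rest by one of three policies: `nearest_ring` (default; sample
the input along the pixel's ray at the nearest kept ring, which resembles a
low-density reconstruction), `zero` (ring-striped frames), or
`linear_radial` (blend of the two bracketing kept rings).  A digital
decimation could equally well keep every M-th spiral or block-average
groups of M; keep-every-M-th is the direct model of acquiring fewer
spirals and is what we implement.

Reported operating points are matched with duty_ratio = 0.5 (hardware duty
is typically 50–80%); duty is always a config value.

## Phantom generator

`phantom` stands in for tissue.  Scenes are elliptical somas (radii 4–7 px
at the 64–128 px desk scale) placed by rejection sampling with curvilinear
dendrites — smoothed random-walk polylines with a Gaussian cross-section at
half the soma intensity.  Intensities are 8-bit: somas 120–200, background
2.  The dim background is deliberate: in two-photon imaging the background
is mostly detector/shot noise rather than fluorescence, and it is what
gives a denoiser measurable SNR (in the mean-soma/mean-background sense)
to recover.

Activity is a linear spike-to-fluorescence model: per-neuron Poisson spike
trains (default 0.05 events/frame) with uniform amplitudes (0.5–1.5 ΔF/F
units) convolved with a single exponential decay (τ = 8 frames), modulating
each neuron's contribution multiplicatively.  This is adequate for fidelity
testing, not a biophysical indicator model: no rise time, no saturation, no
neuropil.

Noise is the standard photon-limited model: intensities scale to expected
photons (`photons_per_unit_at_ref_speed × ref_speed / speed` per 8-bit
unit — dwell time inversely proportional to speed), Poisson draw, rescale,
add Gaussian read noise (σ = 3), clip to [0, 255].  Defaults (4 photons per
unit at 1650 spirals/s) put the high-speed regime at roughly 1–2 photons
per background unit, i.e. genuinely shot-noise limited.  Note one subtlety
the tests rely on: the mean-ratio SNR metric only responds to noise through
the positive bias that clipping induces on a dim background, so the
SNR-vs-speed monotonicity test runs in a shot-dominated configuration
(0.5 photons/unit, σ_read = 1, background 6) where that bias is the leading
effect.

## Restoration networks

The restoration engine is a conditional GAN in the pix2pix mold, written
directly on NumPy (a compact layer library with explicit backpropagation —
im2col/GEMM convolutions, nearest-neighbour upsampling, instance norm,
dropout — plus Adam).  The generator is a U-Net with one full-resolution
stem block feeding both the encoder and a direct skip into the output
stage; below it, `gen_depth` stride-2 levels mirror upsampling levels with
concatenated skips, and a final Tanh bounds outputs to the canonical unit
range ([0, 255] ↔ [−1, 1], applied symmetrically at entry and exit).  The
full-resolution stem is a deliberate departure from the textbook U-Net:
with a strided first layer the trivial identity mapping is unlearnable at
small scale, and restoration should never have to squeeze fine detail
through a ×2 bottleneck.

The discriminator is a PatchGAN: stride-2 convolution blocks followed by
two stride-1 blocks and a sigmoid, emitting a probability field whose
per-unit receptive field approximates `patch_scale` (16/34/70 px for 1/2/3
stride-2 layers).

The objective is the standard cGAN value function — the discriminator
maximises E[log D(x,y)] + E[log(1 − D(G(z,y),y))] — plus an L1 term on the
generator weighted by λ = 100.  The generator uses the non-saturating form
(−E[log D(G,y)]) by default; the minimax form is selectable
(`gen_loss_mode`).  Logs are clipped at 1e−7.  Gradients of every layer are
checked against central finite differences in float64 (relative error
≤ 1e−4 asserted; observed ~1e−8).

Hyperparameter defaults and the two places we depart from pix2pix lineage:

- λ = 100, patch_scale = 70, Adam β₁ = 0.5, β₂ = 0.999 — standard.
- learning rate 1e-3 (not 2e-4).  Desk-scale runs here take a few hundred
  optimiser steps, not tens of thousands; at 2e-4 the networks demonstrably
  undertrain (the identity task plateaus at 2–3× its achievable L1).
- dropout (the stochastic z input) is implemented but off by default.  At
  this data scale it slowed training ~3× and made stage-2 outcomes
  seed-dependent; with it off, results are stable across seeds.  Enable
  with `dropout_p` for parity experiments.

Everything — initialisation, shuffling, dropout, validation split — derives
from `GanConfig.seed`, so identical config + data + seed reruns are
bit-identical on a fixed backend.

## Two-stage learning transfer

Ideal ground truth (slow-scan, frame-averaged, full-density) exists only
for motion-free recordings, so the protocol transfers it in two hops:

1. **DNN-1 (denoiser).**  Trained on motion-free, activity-free stacks
   (the analogue of fixed tissue slices).  Per field of view: ground truth
   x = 10-frame average (`averaging_k`, default 10); input y = one randomly
   chosen frame with extra acquisition noise applied at a random speed from
   a declared range (default 1650–3360 spirals/s) to mimic varied imaging
   conditions.  The magnitude/distribution of this augmentation noise is
   not specified by any source; it is the package's own photon-noise model
   and is recorded in each dataset's provenance.  One pair per FOV is the
   default; `pairs_per_stack` enlarges small synthetic datasets.
   Training the stage-1 net on *active* scenes is a known failure mode —
   the frame-averaged ground truth then teaches the network to average
   transients away — which is why the stage-1 phantom stacks are static.

2. **DNN-2 (denoiser + inpainter), one per M.**  The trained DNN-1 is
   applied to a second, activity-bearing dataset to manufacture the
   intermediate ground truth; each raw frame is also radially down-sampled
   by M, and the (down-sampled, DNN-1-output) pairs train DNN-2.  Stage-2
   ground truth is never a raw frame (asserted via provenance).  A given
   DNN-2 is specific to one scanning density.  Initialisation is "Scratch"
   (random) or "Pretrain" (transplant DNN-1's generator and discriminator
   parameters); both converge to comparable validation L1 on the phantom
   task, the pre-trained start mainly buying faster early convergence
   before the two schemes' loss curves merge.

## Metrics

One deliberate idiosyncrasy up front: both NRMSE variants normalise by the
*evaluated* signal's range, not the reference's — swapping arguments
changes the answer, and a regression test pins that asymmetry.  (The more
common convention normalises by the reference; the evaluated-range form is
the one this pipeline's quality claims are stated in, so it is what we
implement.)

- SNR(dB) = 10 log₁₀(mean soma intensity / mean adjacent-background
  intensity).  Background masks for phantoms are a morphological annulus
  (2 px gap, 4 px wide) around each soma, excluding all structure.
- ΔF/F: soma mean minus adjacent-background mean per frame; baseline = 10th
  percentile of the subtracted trace (configurable; no source states the
  baseline rule); normalised to peak 1 over the whole trace (the
  normalisation window is ambiguous in the source; whole-trace is used and
  documented).  All-zero traces return zeros.
- Trace NRMSE: RMSE between the evaluated and reference normalised ΔF/F,
  divided by the evaluated trace's range.
- Image NRMSE: RMSE over all pixels divided by the evaluated image's range.
- MS-SSIM: Gaussian 11×11 window (σ = 1.5), K1 = 0.01, K2 = 0.03,
  contrast-structure at every dyadic scale (2×2 mean pool between scales),
  luminance at the coarsest, canonical five-scale exponent weights
  (0.0448, 0.2856, 0.3001, 0.2363, 0.1333).  Five scales need ≥ 176 px
  images; desk-scale 64 px evaluations use 3 scales with the truncated
  weights renormalised to unit sum.  Negative contrast-structure terms
  clamp to zero (the standard convention under fractional exponents),
  keeping the index in [0, 1].

`evaluate_sweep` aggregates per-frame MS-SSIM/NRMSE into mean ± sd per
down-sampling factor — the density-sweep analysis table.

## Desk-scale study conditions

The validation suite runs the full protocol at deliberately reduced sizes:
64×64 frames, 3 somas/scene, 8 static stacks × 12 frames for stage 1
(k = 10, 3 pairs per FOV), 4 active stacks × 10 frames for stage 2 (M = 8,
ring density 44), networks with base 16 channels and depth 3, 30 epochs —
about a minute of CPU per stage, versus hours of GPU for the full 512×512,
500-frame, 200-epoch configuration the design targets.  Calcium-fidelity
checks use 3 movies × 150 frames at 0.05 events/frame.  At this scale the
restored-over-decimated improvement direction and the ~3% trace NRMSE are
reproduced; the absolute MS-SSIM parity numbers of the full-scale system
(> 0.85 at M = 8) are not expected from networks this small, and the tests
gate on the improvement direction, not the parity values.

## What the phantoms do not capture

No motion (and no motion correction), no vasculature or neuropil
background, no indicator nonlinearity, no scanner-specific radial
nonuniformity, no segmentation step (phantom ROIs are known by
construction).  Passing tests therefore demonstrate the pipeline's internal
correctness and the direction of its quality trade-offs on photon-limited
synthetic scenes — not performance on real in vivo recordings.

## Numerical notes

Float32 training by default (float64 for gradient checks); safeguarded
logs (1e-7); L1 subgradient sign(0) = 0; frame averaging in float64;
8-bit quantisation only at I/O and at `infer`'s uint8 output path;
placement rejection bounded at 2000 attempts per soma with an explicit
density error.  Checkpoints embed config, seed and dataset fingerprint;
histories export to CSV; run manifests record config hash, seeds and file
checksums for bit-identical regeneration.
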