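# Methods

## Problem and model

`facephys` estimates three driver-state quantities from facial video alone:
a binary cognitive-load class, heart rate (HR, beats/min) and respiration
rate (RR, breaths/min).  The premise is that cognitive demand leaves
measurable traces in facial behaviour (blinking, mouth movement, head pose)
and in physiology observable by remote photoplethysmography (rPPG): the
blood-volume pulse modulates skin colour at the HR frequency, with a
respiratory amplitude modulation on top.

The network consumes five temporally aligned streams per fixed-length
window of L frames:

* left-eye, right-eye and mouth crops (25×25 and 15×35 pixels), each
  encoded per frame by a small two-stage convolutional network; a temporal
  shift module (one channel group shifted one frame forward, one backward,
  zero-filled at the ends) mixes neighbouring frames into each frame's
  input beforehand;
* the 106-point facial landmark sequence, normalized by frame size and
  encoded by a 1-D convolution over the point axis with the (x, y)
  coordinates as channels;
* a spatio-temporal map (STMap): the landmark bounding box is divided into
  a 5×5 grid, each cell's mean R, G, B per frame forms a (channel, cell)
  time series, min–max normalized over the window.  A 2-D convolutional
  encoder collapses the cell axis by adaptive average pooling and resamples
  time back to exactly L steps.

Each branch emits an L×d sequence; concatenation gives F ∈ R^{L×D},
D = 5d.  No interpolation is needed — all branches share the window index.

### Bidirectional selective state-space encoder

The temporal encoder is a stack of selective state-space (Mamba-style)
blocks.  The continuous model h′ = A h + B x, y = C h + D x is discretized
per step under a zero-order hold, Ā = exp(AΔ), B̄ = (Ā − 1)/A · B (the
exact integral for diagonal A; an Euler variant Δ·B is available by
config).  A is diagonal with entries −exp(A_log), so every Ā lies in
(0, 1) and the recurrence is unconditionally stable for any learned
parameters.  Δ, B and C are computed from the current input (softplus for
Δ > 0), which makes the system time-varying; the block therefore runs as a
true recurrence.  When the parameters are frozen (LTI mode) the same
operator is exactly a causal convolution with kernel K_t = C Ā^t B̄, and
the test suite verifies scan/convolution agreement to <1e−6 on random
instances — this equivalence is the core correctness oracle for the
encoder.

One block is: RMS pre-norm → input projection to 2E (E = 2D) → depthwise
causal convolution (width 4) → SiLU → selective scan (state size N per
channel) → SiLU gate with the second projection half → output projection →
residual.  Causality of the whole block is tested by perturbing future
inputs.

Two independent stacks of `depth` blocks (default 3 per direction) process
F and its time reversal; the backward stack's output is re-reversed so
both share the forward time axis — the mean pooling that follows assumes a
single consistent axis.  Each is mapped by its own linear layer to d_out
(default D) and the two are concatenated into H_bi ∈ R^{L×2·d_out}.

### Heads and objective

h_fused is the arithmetic mean of H_bi over time.  Three independent
two-layer MLPs (hidden 128, SiLU) map it to the outputs; the cognitive
head ends in a sigmoid.  The heads share no parameters — the network
branches only at the prediction layer.

Losses: truncated cross-entropy −log max(p_y, ε) for the class (ε = 0.01
by default; samples whose true-class probability falls below ε contribute
a constant loss and zero gradient, bounding the influence of mislabeled
windows), smooth-L1 for HR and RR.  The joint objective is
L_total = L_cog + λ(L_hr + L_rr) with λ = 2/(1 + exp(−10t)), t = 2·iter/total.
Note λ(0) = 1: the regression terms are active from the first step and
their weight ramps from 1 toward 2.  We implement this formula as printed;
a `lambda_start_zero` option subtracts 1 for users who want the regression
tasks silent at the start.

An optional `normalize_targets` training flag z-scores the HR/RR labels
(statistics from the training split, stored in the checkpoint); predictions
are mapped back to physical units before any metric is computed.  It is
off by default and in the desk benchmark: balancing the loss scales also
removes the large early regression gradients, and in short runs those
gradients are what drive the shared encoder to learn the pulse-frequency
features at all — with z-scored targets a 400-step run leaves heart-rate
error at the global-mean level.  The flag exists for long training runs
where task balance matters more than warm-up speed.

## Default hyperparameters

| parameter | default | why |
|---|---|---|
| window length L | 300 frames (10 s @ 30 fps) | long enough for ~5–17 pulse cycles and 1–4 breaths |
| stride s | 30 frames | 90% overlap; windows inherit trial labels |
| crop sizes | 25×25 eyes, 15×35 mouth (h×w) | fixed output shapes; mouth wider than tall |
| STMap grid | 5×5 over the landmark bounding box (H = 25) | standard grid-ROI STMap practice |
| per-branch width d | 64 (D = 320) | keeps the full model at ≈4.7 M parameters, inside a 5.95 M budget |
| encoder depth | 3 per direction | full-scale recipe; see the desk-scale caveat below |
| state size N | 16 (full) / 8 (desk) | canonical selective-SSM sizing |
| optimizer | Adam, lr 1e−5, batch 250, 20 000 iters (full scale) | GPU-scale recipe; the desk profile overrides all three |
| ε (CE floor) | 0.01 | caps a single sample's loss at ≈4.6 |
| classification threshold | 0.5 | labels are balanced by construction |

Checkpoint selection uses validation L_total (evaluated every 50 steps at
the current λ).  Subjects are split 6:2:2 (train/val/test) by seeded
shuffle; every window inherits its subject's split, so no subject leaks
across splits.

## Synthetic data: what it emulates, and what it does not

The generator produces subjects with truncated-normal baselines
(HR ~ N(70, 7) on [50, 95] bpm; RR ~ N(15, 2) on [10, 22] rpm) and windows
in which high cognitive load adds +8 bpm and +2 rpm (plus unit-variance
per-window jitter) and doubles the blink rate (12 → 24 blinks/min, Poisson
events, 150 ms closures).  Pixel-level windows render a flat-skin-tone
face ellipse whose green channel pulses at the HR frequency with
respiratory amplitude modulation plus a direct low-frequency respiratory
baseline (two recoverable signatures), eye patches darkened during blinks,
random-walk head motion on the landmarks, slow lighting drift and additive
Gaussian noise.  Tensor-level windows embed the same signals directly into
the five model inputs and are what the training benchmarks consume (no
video-synthesis cost).  Labels equal the generating values exactly, and at
zero noise the STMap FFT oracle recovers HR and RR within one bin — the
generator is self-verifying.

The blink-rate direction (more blinks under load) is a fixture choice to
give the eye branches class-discriminative signal; it is not a claim about
drivers.  The generator does not model facial expression, gaze, realistic
skin texture, motion blur, illumination colour shifts, or label noise, so
passing benchmarks demonstrate that the pipeline can extract the signals
it was built for — not performance on real driving video.

A consequence worth stating plainly: with these defaults the cognitive
classes overlap substantially at the single-window level.  The only class
cues are the blink count (Poisson means differ by a factor of two, heavily
overlapping at 5–10 s windows) and the HR/RR shifts (+8 bpm against a
7 bpm between-subject spread, with the subject unseen at test time).  A
Bayes-optimal classifier combining all three cues tops out around 0.8–0.85
accuracy on held-out subjects; any higher figure on this generator would
indicate leakage, not skill.  The regression tasks have no such ceiling —
the pulse frequency is explicitly present in the STMap.

## Desk benchmark

Training the full configuration needs GPU-scale resources; the *desk
benchmark* (`facephys.benchmarks`) is the package's CPU-scale reference
experiment, chosen once as the standard demonstration: 10 subjects × 20
tensor-level windows (balanced classes), L = 150 at 30 fps, noise σ = 0.5
(high SNR), model d = 16 / depth 3 / N = 8 with halved embedding widths,
Adam lr 2e−3, batch 8, 400 iterations, raw-unit regression targets,
subject-wise 6:2:2 split.  One training run takes a few minutes on a
single core.  The depth sweep reuses the same data, split and seed and
varies only encoder depth, giving a controlled 1- vs 3-layer comparison.

## Numerical choices and edge cases

* Degenerate (constant) STMap rows normalize to 0.5; the FFT oracle
  reports an undefined rate with confidence 0 for flat maps.
* Crop boxes are clamped inside the frame (no padding), so output shapes
  depend only on the region tag; windows shorter than L are dropped, never
  padded.
* Landmark normalization clamps to [0, 1]; denormalization is exact for
  in-bounds points.
* The temporal shift uses fold_div = 3 on RGB clips (one channel each
  way); wider inputs can use larger fold_div, and a group size of zero is
  rejected.
* Δ is floored at 1e−6 after softplus; Ā = exp(AΔ) ∈ (0, 1) guarantees a
  bounded scan for any parameters.
* Ties in the elementwise `maximum` route the gradient to the first
  argument; for the truncated CE this yields a live gradient exactly at
  p_y = ε and zero below.
* All randomness flows from one run-level seed through
  `numpy.random.Generator`; training is bit-reproducible on a fixed
  platform, and checkpoints (parameters + buffers + config JSON in one
  archive) round-trip bit-exactly.
* The whole network runs in float32; the state-space reference operations
  (`facephys.ssm`) run in float64 for oracle-grade comparisons.

A caveat the sweep itself exposes: at desk scale the deeper encoder is not
reliably better.  With ~10^2 training windows and a few hundred optimizer
steps, model capacity is not the binding constraint, and the one-layer
encoder — fewer parameters, faster per-sample convergence — can match or
beat three layers on heart-rate error.  Depth trends measured at this
scale say little about the full-scale configuration, where both the data
and the step budget are two orders of magnitude larger.

## Known limitations

* The scan is a per-step recurrence on CPU; throughput, not fidelity, is
  the cost of the framework-free implementation.
* Mid-band workload scores (30–60 on the raw questionnaire scale) are
  excluded from classification but retained for regression, a documented
  interpretation of the two stated bands.
* Whether "three layers" means per direction or in total is ambiguous in
  the underlying design; we use per-direction and expose `depth`.
* The synthetic effect sizes are not calibrated to any real driving
  corpus; see the class-overlap note above.
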