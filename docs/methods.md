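# Methods

`cnvsnn` reimplements, end to end, a braking-intention decoding analysis:
synthetic countdown-trial EEG carrying a contingent negative variation
(CNV) is preprocessed into labelled segments and classified — intention
vs. no intention — by a convolutional spiking neural network (CSNN)
trained with surrogate gradients, benchmarked against a matched CNN and
three graph neural networks under class-weighted stratified 10-fold
cross-validation. This note records the models, the assumptions behind
the synthetic data, the numerical choices, and what the tests do and do
not establish.

## The synthetic experiment

Each trial emulates a cued-braking protocol: an audible "Start" cue
(written as an explicit marker), countdown markers "5".."1" at jittered
~1 s intervals (uniform ±10% per gap), and a "Stop" command on which the
subject brakes. The stream carries 2 s of plain background before the
cue and after the trial, as a continuous acquisition would — without
this context, zero-phase filtering places its edge transients inside the
first and last analysed windows, and since the intention window is
always the last one, even pure-noise data acquires class-correlated
smoothness (a genuine positional leak, measured and eliminated). The
window between "1" and "Stop" is the intention class (label 1); the five
earlier windows (Start→5, 5→4, …, 2→1) are label 0, giving the 5:1 class
imbalance the analysis assumes (a flag drops the Start window for a 4:1
variant).

The intention window carries the CNV: a piecewise-linear ramp from 0 at
a configurable onset fraction of the window to `cnv_amplitude` (µV, ≤ 0)
exactly at the Stop sample, relaxing linearly back to baseline over a
0.25 s post-stop tail. Slow anticipatory potentials are strongest over
the vertex, so the ramp is scaled per channel by a Gaussian fall-off of
distance from Cz on the shipped 2-D 10-20 layout (σ = 0.45 in unit-disc
coordinates: the Fz/Pz/C3/C4 ring gets ≈ 0.54, the outer ring < 0.1).
The exact waveform is a free modelling choice; a ramp peaking at the
imperative stimulus is the simplest shape consistent with CNV
phenomenology (negativity accelerating after the penultimate count and
extremal just before the stop).

Background noise is zero-mean Gaussian per sample (default SD 5 µV),
optionally 1/f-shaped via spectral reweighting. Blink-like artifacts —
0.2 s Hann bumps, default 150 µV, frontal channels — occur per window
with probability `artifact_rate`. Per-trial generators are seeded as
`SeedSequence(seed, spawn_key=(trial_id,))`, so any subset of trials is
reproducible independently of generation order.

What the generator does **not** emulate: volume conduction (channels
share the CNV topography but their noise is independent, so inter-channel
correlations are far lower than in real EEG), EOG/EMG, mains pickup,
electrode drift and hardware noise. Consequences: the recording-level
neighbour-correlation and line-noise rejection rules — meaningful only
for volume-conducted data — are implemented but opt-in, and passing
end-to-end tests demonstrates that the pipeline recovers the modelled
effect, not that it would reach the same numbers on real recordings.

## Preprocessing

Fixed order: zero-phase FIR band-pass → recording-level cleaning →
segmentation by markers → per-segment baseline correction (mean
subtraction) → per-segment artifact cleaning → zero-padding to a uniform
length → per-channel min–max normalization to [0, 1].

* **Band-pass.** 0.1–1 Hz (the slow-cortical-potential band), Hamming
  firwin, applied forward–backward (`filtfilt`) so markers stay aligned —
  the grand-average analysis assumes zero phase shift of the CNV. The
  tap count is configurable; the default targets a transition width ≈ the
  low cut-off but is capped at a third of the recording so the
  forward–backward padding fits. On short trials the cap dominates and
  the filter is deliberately gentle.
* **Recording-level cleaning.** Flat channels (≥ 5 s) are removed and
  re-interpolated; 0.5 s windows whose SD exceeds 20× the channel SD
  (a simplified burst-rejection rule standing in for subspace-based
  artifact correction, which is an external algorithm) are excised and
  linearly interpolated. Neighbour-correlation (< 0.8) and line-noise
  (> 4 SD) channel rejection exist behind flags, off by default (see
  above).
* **Per-segment cleaning.** A sample is bad if |x| > 100 µV or its
  z-score exceeds 3 against the channel's own distribution (local) or
  all channels pooled (global). Channels bad for ≥ 10% of the segment
  are removed and re-interpolated from the inverse-distance-weighted
  mean of their three nearest surviving neighbours on the 10-20 layout;
  shorter bad stretches are excised and linearly interpolated in time.
  Segments losing more than 10 channels (> 50% of 19) are rejected.
* **Padding and normalization.** Zeros are appended (never truncation)
  to the configured target (1848 samples at the full 500 Hz scale);
  normalization follows padding, so the padded zeros participate in the
  per-channel min/max — kept deliberately, with a flag to normalize on
  the unpadded extent only. Constant channels map to zeros with a
  warning.
* **Quality index.** `QI = tanh(√((ζL/100µV)² + (ζm/250µV)² +
  (O/280mV)²))` with green/orange/red bands at 0.5 and 0.8, provided for
  acquisition-side screening; it plays no role in the synthetic pipeline.
* **Grand average.** Pointwise mean of one channel across segments over
  their unpadded extents. Start-locked by default; `align="end"`
  (response-locked, every segment contributing at every point) is used
  for CNV amplitude checks, since with jittered segment lengths the
  start-locked tail is averaged over arbitrarily few segments and its
  extremum is noise-dominated.

## Spike encoding

Delta modulation: per channel, a spike wherever the successive-sample
change exceeds a threshold; the first sample never spikes, so the binary
array keeps the input shape. The change is absolute by default (the
steep negative CNV ramp and positive deflections register alike); a
`signed` mode (positive-only) exists for sensitivity analysis. The
comparison is to the previous *sample* (first differences), not to the
last spike-emitting sample as in send-on-delta encoders — a deliberate,
documented choice.

## Models

All models run on a small in-repo reverse-mode autodiff engine over
numpy (float64): broadcasting arithmetic, matmul, im2col-based 2-D
convolution, clipped max pooling, reductions, and the spike
nonlinearities with custom backward passes. Adam is implemented on top.

* **LIF neuron.** `U[t] = β·U[t−1] + I[t]`; spike when `U ≥ θ` (firing
  on equality, fixing the Heaviside's open convention at 0); reset by
  subtraction of θ, preserving residual drive (reset-to-zero would
  discard it). Defaults β = 0.5, θ = 0.5.
* **Surrogate gradient.** The backward pass replaces the Heaviside
  derivative with `1/(k·|U−θ|+1)²` (k = 0.25): symmetric about θ,
  exactly 1 at θ, sharpening toward a delta as k → ∞. It is the exact
  derivative of the smoothed spike `(U−θ)/(1+k|U−θ|)`, which the
  gradient tests use as a differentiable stand-in forward pass. In the
  recurrent network the subtractive reset is treated as constant during
  backpropagation (detached), the common stabilizing choice.
* **CSNN.** Two convolutional-spiking layers — conv (5×5, stride 1, no
  padding; 12 then 64 filters) → 2×2/stride-2 max pool → LIF tensor —
  then a linear layer to two output LIF neurons. The static channels ×
  time input is presented identically at each of `n_steps` steps (direct
  encoding; 25 by default); the prediction is the class whose output
  neuron spiked most over the steps, ties to class 0. The loss is
  class-weighted cross entropy on softmaxed, step-normalized spike
  counts (with two classes this collapses to a logit BCE on the count
  difference). Since the input is static, the first convolution is
  hoisted out of the step loop, and the spikes of layer 1 across all
  steps are stacked so the second convolution runs as one batched
  operation — an exact restructuring, verified bit-identical.
* **Kernel/pool clipping.** Kernels and pool regions clip to the
  available extent per dimension (a 5×5 kernel on a height-1 map becomes
  1×5; a 2×2 pool on it pools width only). Without this the printed
  architecture cannot run on five input channels (height 5 → conv → 1 →
  pool would collapse), yet the five-channel ablation is part of the
  design.
* **CNN.** Same conv/pool stack, then a linear layer to a single
  sigmoid unit (decision at 0.5). No additional activations — kept
  exactly as specified so differences against the CSNN are attributable
  to the spiking dynamics.
* **GNNs.** Channels are nodes; node features are the channel's time
  series; one shared adjacency `A = |P| − I` (absolute Pearson
  correlation over the *training* data, zero diagonal). GCN layers use
  self-loop-normalized propagation `D̂^{-1/2}(A+I)D̂^{-1/2}XW + b`; GCS
  adds a trainable skip `D^{-1/2}AD^{-1/2}XW₁ + XW₂ + b` without
  self-loops (as printed — some formulations add them; isolated nodes
  get a zero normalized term); GIN computes `MLP((1+ε)x_i + Σ_{j∈N(i)}
  x_j)` with the unweighted binary neighbourhood `N(i) = {j: A_ij > 0}`
  and ε initialized at 0 (the aggregation sums features, not weighted
  features, so the correlation weights inform GCN/GCS only). Stacks:
  GCN/GCS 115→28→14→3, GIN 924→462→231 with 5×256-hidden MLPs (each
  MLP's output size taken as the layer's output size). ReLU between graph
  layers, then attention-sum pooling `Σ αᵢxᵢ, α = softmax(Xa)` over
  nodes, a ReLU hidden layer (width 32, a free choice), and one sigmoid
  unit.

## Training and evaluation

Adam (lr 5e-4, β₁ 0.9, β₂ 0.999, ε 1e-8), batch size 8, up to 1000
epochs with early termination when the epoch training loss has not been
*strictly* lower than the best so far for 50 consecutive epochs (no
validation split is part of the protocol). Class weights `w_c =
N_D/(2N_c)` are computed on each fold's training partition only, as is
the GNN adjacency — nothing is fitted on test data. Folds are stratified
(class ratio preserved within ±1 sample), shuffled with a fixed seed,
and every architecture is re-initialized per fold from the same
fold-specific seed. Batches are re-shuffled each epoch (standard
practice; the protocol wording fixes only the pre-training shuffle).

Metrics per fold come from confusion counts (Acc, TPR, TNR, F1);
summaries report fold-averaged mean (SD) — fold-averaging, rather than
pooling counts, matches the mean (SD) presentation — and two-sample
t-tests against a reference model (classic equal-variance two-sided,
df = 2k−2; Welch behind a flag). When both samples have zero variance, p
is reported as 1 for equal means and 0 otherwise.

Three drivers: `full19` (all channels, floating-point input, all
models), `ablation5` (Cz, Pz, C3, C4, Fz), and `spike_sweep`
(delta-modulated input to the CSNN over the grid
{0.05, 0.25, 0.375, 0.5, 0.625, 0.75, 1.0}).

## The scaled reference study

The full-scale protocol this package models (a 15-participant cohort,
thousands of trials at 500 Hz, segments padded to 1848 samples, 25
presentation steps, up to 1000 training epochs per fold) is far beyond
desk scale, and no public recordings of such an experiment exist. `cnvsnn.study` pins one scaled study used by the end-to-end
tests and `scripts/acceptance.py`:

* 120 trials → 600 no-intention / 120 intention segments, 19 channels,
  ~1 s jittered windows; CNV −10 µV on 5 µV noise (SNR 2), no artifacts;
* sampling rate 25 Hz (the 0.1–1 Hz band of interest is ~250×
  oversampled at 500 Hz), segments padded to 32 samples; FIR length
  pinned at 51 taps so the zero-phase edge transient fits inside the
  generator's 2 s stream context;
* CSNN with 10 presentation steps; training 8 epochs, patience 3 — the
  scaled task converges within a few epochs; 10-fold CV throughout.

**Threshold-grid scaling.** A signal bandlimited to f_max sampled at fs
changes per sample by at most ≈ 2π·f_max/fs of its range, so the
successive-difference distribution — and with it the spike density at a
given delta-modulation threshold — shifts with the time resolution. The
full-scale grid spans three regimes on 500 Hz recordings:
saturated (tiny threshold), moderate-density (mid thresholds, where
classification peaks), and near-silent (threshold ≈ 1). At 25 Hz those
regimes sit at {0.005, 0.05, 1.0}, which the scaled sweep uses; the
qualitative result — an inverted-U of accuracy over thresholds, with
both the saturated and the silent extremes degraded — is the property
the study design predicts and the tests assert.

**Null-control behaviour.** On the null dataset (CNV amplitude 0) the
pipeline shows no skill: sensitivity tracks the false-positive rate and
balanced accuracy sits at 1/2. Raw accuracy, however, does *not* settle
at the majority-class rate (600/720 ≈ 83.3%) under the class-weighted
protocol, and cannot: the weights `w_c = N_D/(2N_c)` equalize the two
classes' total loss mass (`w₁π₁ = w₀π₀ = 1/2`), so on featureless data
the weighted optimum lies exactly on the decision boundary and the
discrete spike-count readout splits predictions between the classes
(measured: 38–44% class-1 guesses, raw accuracy 0.50–0.68, partial
training-set memorization). Dropping the class weights restores the
majority default exactly (null accuracy 0.833, zero class-1
predictions) — that contrast, asserted in the tests, is the cleanest
evidence that the weighted pipeline's null behaviour is balanced
no-skill rather than leakage.

## Numerical choices and degenerate inputs

* Engine dtype float64; gradient checks use central differences at
  1e-6 and pass at 1e-4 relative error.
* Min–max normalization guards max = min by mapping the channel to
  zeros (warning); Pearson adjacency raises on zero-variance channels,
  naming the channel.
* Marker files must be strictly increasing; unknown marker labels,
  ragged matrix rows and empty marker files are format errors carrying
  the offending row number.
* `pad_segment` never truncates (error if the segment exceeds the
  target); `segment_by_markers` errors on missing markers (naming the
  first absent label) and zero-length windows.
* Divergent (NaN) training loss aborts with the epoch number; NaN
  membrane input raises rather than propagating.

## Known limitations

* No volume conduction or realistic noise spectra in the generator (see
  above); accuracy on synthetic data does not forecast accuracy on real
  EEG.
* The GNNs at their full-scale layer sizes are large; the scaled tests
  exercise them at reduced sizes and verify the layer algebra exactly
  against dense oracles rather than training them to convergence.
* EEGNet, subspace-based artifact correction, topographic rendering and
  hardware deployment are out of scope; the classifier interface is
  pluggable so external models can be slotted in.
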