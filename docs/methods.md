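# Methods

`multistress` models the computational stack of a multimodal wearable
stress-assessment system: five synchronized biosignal modalities (ECG, skin
conductance, radial-artery pulse, skin temperature, sweat cortisol) recorded
under a block-structured stressor protocol, encoded by per-modality 1-D
Inception networks, fused by soft attention, and evaluated subject-
independently. Because no public recordings exist for this class of device,
the package ships a first-class synthetic cohort generator whose defaults
encode the published physiological dynamics, so every stage is testable
without data access.

## Stressor protocol

A session is a pre-stress rest block followed by five stressor blocks, each
with a recovery block (`make_protocol_schedule`). Block and recovery
durations default to 600 s. Six states are labeled: rest plus cognitive
(time-constrained quiz / Stroop), environmental (cold pressor),
emotional (horror film), psychosocial (simulated interview) and physical
(high-intensity exercise) stress. The stressor order
(cognitive, environmental, emotional, psychosocial, physical) is fixed by
convention; recovery blocks are labeled rest.

## Synthetic cohort generator

Per-state targets for heart rate, tonic skin conductance (SCL), SCR event
rate, crest time, and skin temperature are approached with first-order
relaxation (τ_on = 10 s, τ_off = 12 s), reflecting fast autonomic onset and
slightly slower recovery. Defaults encode the printed dynamics:

| state         | ΔHR (bpm) | cortisol (nM)      | ST (°C) | CT (ms) |
|---------------|-----------|--------------------|---------|---------|
| cognitive     | +18 (89→107) | 86 → 113 peak   |  0      | −15     |
| environmental | +5        | 86 → 104 → 97      | −1.5    | +15     |
| emotional     | +8        | 86 → 107 peak      | −0.3    | −10     |
| psychosocial  | +12       | 86 → 100 peak      | −0.2    | −10     |
| physical      | +8 (87→95) | 84 → 94           | +0.8    | −25     |

Psychosocial magnitudes are not printed anywhere; they were chosen once as
moderate values between the quiz and exercise responses.

* **ECG** (mV, 128 Hz default): a sum-of-five-Gaussians PQRST template per
  beat; P/T delays scale with the local RR interval; the R peak sits exactly
  on the beat clock, which is obtained by integrating the instantaneous
  heart rate, so mean RR = 60/HR by construction. The same beat clock drives
  the pulse channel.
* **GSR** (µS, 128 Hz default): tonic level plus phasic skin-conductance
  responses arriving as an inhomogeneous Poisson process (thinning), each a
  biexponential (Bateman) kernel with 0.75 s rise and 3 s decay, peak
  amplitude ≈ 0.3 µS × a per-state scale. The kernel support is 40 s with
  end-value subtraction so truncation introduces no step edge.
* **Pulse / RAP** (relative current, 64 Hz default): each pulse rises
  linearly from its foot to the percussion peak over exactly the crest time
  (a stylized upstroke chosen to be exactly consistent with the
  intersecting-tangent foot definition used by the extractor), then decays
  with superposed tidal and dicrotic Gaussian waves.
* **Skin temperature** (°C, 1 Hz): the relaxed state series plus noise.
* **Sweat cortisol** (nM, sparse at the 60-s minimum incubation cadence):
  a linear circadian baseline between morning and evening anchors (defaults
  95 → 80 nM; the in-vivo demonstration values 105 → 79 nM are used in the
  tests) plus one excursion per stressor block — raised-cosine rise to the
  state's peak (so the printed peak is attained exactly), then exponential
  decay whose time constant is derived from the printed end-of-block value
  where one exists — all delayed by the 300-s sweat-transport lag. Values
  are clipped to the sensed range 1 nM – 10 µM.

Subject-level random effects (baseline HR, SCL, ST, crest time, circadian
anchors, and a multiplicative effect-size scale) are drawn once per subject
and shared across that subject's sessions; session noise is independent.
Presets: `SubjectVariability()` (defaults), `.low_noise()` (the large-effect
cohort used for separability studies), `.noiseless()` (ground-truth
recovery). Cohorts are bit-reproducible given a seed (`numpy.SeedSequence`
spawning per subject and session).

What the generator does **not** emulate: motion artifacts, electrode
drift and detachment, sweat-rate variability of the microfluidics,
HPA-axis dynamics (responses are phenomenological), non-stationary
baselines within a session, or realistic ECG/pulse morphology variation.
Passing tests therefore demonstrate internal consistency of the pipeline
and recoverability of constructed effects — not performance on real
recordings.

## Sensor models

* **MIP cortisol electrode**: chronoamperometric current falls linearly in
  log10 concentration, I = I_blank − S·log10(c/nM), with the reported PBS
  sensitivity S = 0.2447 µA/decade as the default; calibration fitting is
  ordinary least squares on (log10 c, I); inversion outside the sensed range
  clamps with a warning rather than extrapolating. The non-imprinted control
  is modeled as a near-zero slope (0.005 µA/decade), configurable. Log base
  10 is implied by the decade spacing of the tested concentrations.
* **Restoration state machine**: each electrochemical restoration cycle
  (−0.5 V) records the blank current; `restored` means the blank returned to
  within 5% of the initial value (the recovery ratio is defined on currents;
  a charge-based definition would be equivalent up to the fixed integration
  time), and a drift flag raises when the relative SD of blank currents
  across cycles exceeds the 5% criterion.
* **Pulse pressure sensitivity**: continuous piecewise-linear ΔI/I0 with
  per-range slopes 6.30, 4.55, 3.14 kPa⁻¹ over 0–100, 100–200, 200–340 kPa
  (only per-range slopes are reported; the continuous interpolation is the
  natural completion and keeps the response monotone).
* **Electrode–skin interface**: Z(f) = (R_C ∥ C_C) + (R_sp ∥ C_sp) +
  R_tissue. Component defaults are order-of-magnitude placeholders
  (10 kΩ/100 nF contact, 100 kΩ/10 nF stratum corneum, 500 Ω tissue) meant
  to be fitted to measured spectra; the model guarantees the two frequency
  limits |Z|→R_C+R_sp+R_tissue (f→0) and |Z|→R_tissue (f→∞).

## Feature extraction

* **R peaks**: squared-derivative energy with an 80-ms integration window,
  an adaptive threshold (30% of the 99th percentile), a 250-ms refractory
  period, and refinement to the local ECG maximum. Offset-invariant by
  construction.
* **EDA decomposition**: tonic = zero-phase 4th-order Butterworth low-pass
  at 0.05 Hz; phasic = exact residual (additivity holds to machine
  precision). SCR events are detected on the smoothed phasic *derivative*
  (onset slopes) above 0.08 µS/s with a 0.5-s minimum separation: onset
  detection resolves responses whose decays overlap, which plain
  phasic-peak picking merges. Events closer than the 0.5-s resolution are
  reported as one; tests compare against the resolvable-cluster count.
* **Pulse features**: per-beat percussion peak, intersecting-tangent foot
  (tangent at the steepest upstroke sample intersected with the pre-pulse
  baseline — swappable), crest time = foot→peak, amplitude = foot→peak
  height; tidal and dicrotic waves as later decay maxima, NaN when absent.
* **Wavelet power spectra**: |CWT|² with the Morlet wavelet on 64
  log-spaced frequencies (0.1–8 Hz by default), via PyWavelets.
* **Smoothing**: centered 30-s moving average with edge truncation.
* **Cortisol interpolation**: quadratic spline through the sparse samples,
  exact at knots; < 3 samples falls back to linear with a warning.

## Dataset pipeline

Windows of 5 s with 50% overlap are laid out per schedule segment, so no
window straddles two states (straddling windows are never generated —
dropping them avoids label noise; the window count per segment is
floor((L−W)/stride)+1). The sparse cortisol channel is first shifted 300 s
earlier (sweat-transport lag) and each window carries the aligned sample
nearest its center as a scalar, which the model broadcasts to a constant
channel. Normalization is a per-modality z-score fitted on training
subjects only; jitter augmentation (σ = 0.06 in normalized units, applied
after normalization, per window) appends noisy copies of the continuous
channels only — labels, IDs and the cortisol scalar are never jittered,
and |augmented| = 2·|original|.

An optional **per-session normalization** (`normalize_per_session`)
z-scores each subject-session by its own per-modality statistics before
the global train-fitted z-score. Between-subject baseline offsets (tonic
SCL level, resting temperature, circadian cortisol anchor) do not transfer
across subjects; without this step, subject-independent evaluation folds
whose held-out subject has a large baseline offset collapse to
majority-class predictions. The step uses only each session's own
unlabeled signal statistics — nothing crosses subjects and no labels are
consulted — and is standard practice in cross-subject affect recognition.

## Classifier

Each modality is resampled to a common input length (linear interpolation)
and encoded by a stack of 1-D Inception blocks: parallel convolutions with
kernel lengths 1, 3 and 5 plus a length-3 max-pool path followed by a
1-kernel convolution, all same-padded and concatenated (output channels =
4 × n_filters, temporal length preserved), then global average pooling and
a dense projection to a d-dimensional embedding. Soft attention scores the
five embeddings (u_m = v·tanh(W e_m + b), α = softmax(u)) and fuses them as
Σ α_m e_m; a two-layer dense head yields class logits. Tasks: binary
(rest vs all stressors pooled), five-way stress subtype (rest excluded) and
six-state.

The network, backpropagation and Adam optimizer are implemented directly on
numpy arrays (same-padded convolutions via im2col, analytic gradients for
every layer including the attention); all gradients are verified against
finite differences in the test suite, and the Inception block against a
brute-force direct-convolution oracle. Training is deterministic given a
seed; early stopping monitors the loss on an inner validation subject;
an optional hyperparameter grid is searched on the same inner split.
Defaults: Adam at 3·10⁻³, batch 128, ≤ 10 epochs, patience 3; desk-scale
architecture of one Inception block with 8 filters, d = 16, input length 40
(two blocks and larger widths are configuration, not code changes).
Ablation for interpretability removes a modality at the fusion stage by
zeroing its embedding (zeroing raw inputs instead pushes the encoder off
its training distribution and does not measure the modality's
contribution).

## Evaluation

* **Subject-independent**: leave-one-subject-out cross-validation; per fold,
  one remaining subject is randomly selected for inner validation, scalers
  are fitted on the training subjects only, and the held-out subject's
  windows influence nothing. Folds whose test labels are single-class are
  skipped with a warning. Reported as mean ± SD accuracy and macro-F1
  (macro chosen for class-imbalance robustness; configurable) with a pooled
  confusion matrix. Window-level metrics are primary; segment-level
  majority voting is available (`majority_vote_by_segment`).
* **Subject-dependent**: a base model trained without the target subject is
  fine-tuned on one session of that subject — decision head only, encoder
  verified unchanged by checksum — and tested on the other session.
* **Agreement statistics**: R² is the squared Pearson correlation.
  Bland–Altman uses D_i = y_i − x_i, D̄ the mean, σ_D the sample SD (N−1),
  and limits of agreement D̄ ± 1.96 σ_D. (A printed formula for σ_D omitting
  the square and summation is dimensionally inconsistent; the standard
  sample SD is used.)

## Desk-scale study settings

The full protocol at full sampling rates produces hours of multi-rate
signal per cohort. The `presets` module fixes the desk-scale conditions
used by the learning-sanity evaluation: 15 subjects × 2 sessions on the
full 5-stressor protocol with 90-s blocks, the low-noise variability
preset, reduced rates (ECG 64 Hz — its validity floor — GSR 32 Hz, RAP
64 Hz), non-overlapping 5-s windows, and the small single-block model.
Under these conditions subject-level LOOCV binary accuracy is ~96% and
six-state accuracy ~96%, against a 54.5% majority-class rate and a
label-shuffled control at that chance level. These numbers characterize
the synthetic cohort's separability, not any real-world performance.

## Known limitations

* The classifier is desk-scale: a faithful but small configuration of the
  architecture family, not a replication of the original network's depth,
  and it runs on CPU via numpy — minutes per LOOCV, not suitable for large
  cohorts.
* The pulse upstroke is stylized (linear ramp) so that crest time is
  defined exactly; real pulse feet require more robust foot detectors.
* Cortisol enters the model as a per-window scalar; richer encodings
  (interpolated trajectories, uncertainty from the incubation cadence) are
  not explored.
* The chamber fill time of the microfluidic sensor is exposed as a
  parameter rather than fixed (reported fill durations are mutually
  inconsistent); it does not enter the simulation cadence, which is set by
  the 60-s incubation minimum.
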