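# Methods

## Problem and model

`sleepcam` scores polysomnography (PSG) in 30-s epochs into the five AASM
sleep stages (W, REM, N1, N2, N3) and, unlike most sleep-staging networks,
reports *why*: a class activation map (CAM) that assigns each stage a
signed evidence trace over time within the epoch.

The network has three per-modality feature-extraction blocks operating on
one epoch of signal at the canonical rates — EEG 6×6000 samples (200 Hz),
EOG 2×3000 (100 Hz), EMG 1×6000 (200 Hz). Each block is

    conv(ELU) → conv(ELU) → max-pool → layer-norm (across kernels)

with stride-1, symmetric same-padded convolutions (odd widths only). The
pool sizes are chosen so all three blocks emerge with the same temporal
length and the features can be concatenated along the kernel axis. The
assignment head is a *linear* convolution with one kernel per stage — its
output is the CAM `A ∈ R^{5×T}` — followed by global average pooling (GAP)
over time and a softmax:

    p = softmax( (1/T) Σ_t A[·, t] ).

Because GAP is linear and the head has no activation, the stage
probabilities are exactly the softmax of the time-mean of the CAM; each
decision decomposes additively over time, and high-CAM sub-intervals are
the evidence for the decision. This identity is a structural property and
is asserted to 1e-5 over random-weight models in the tests.

Layer normalization standardizes the feature vector across kernels at each
time point (mean 0, variance 1, then a learnable per-kernel affine). This
makes features amplitude-relative — the "clearness" of a waveform against
the simultaneous background, which is how the AASM manual defines several
characteristic waves. The epsilon stabilizer is 1e-6, small enough that
pre-affine moments deviate from 0/1 by well under 1e-4 at realistic kernel
counts (≥ 4 per block), while still mapping exactly-constant columns to
zero.

Two architectures ship:

| | EEG block | EOG block | EMG block | CAM steps |
|---|---|---|---|---|
| `default_config` | 64/64 kernels, widths 51/25, pool 20 | 32/32, 25/13, pool 10 | 16/16, 51/25, pool 20 | 300 (0.1 s) |
| `reduced_config` | 8/8, widths 25/13, pool 50 | 4/4, 13/7, pool 25 | 4/4, 25/13, pool 50 | 120 (0.25 s) |

Kernel counts scale with how many characteristic-wave types each modality
carries. The reduced architecture is used in all shipped experiments: it
trains in minutes on one CPU and is ample for the synthetic cohorts. CAM
steps must divide the 0.5-s annotation grid (both 0.1 s and 0.25 s do) so
CAM bins align with wave labels.

### Numerical implementation

No deep-learning framework is used: layers are numpy/scipy with explicit
backward passes, validated against central finite differences (float64
mode, relative error < 1e-6). Convolutions are evaluated in the Fourier
domain (zero-padded real FFTs); at widths 13–51 on 3000–6000-sample epochs
this is roughly an order of magnitude faster than im2col matrix products
and avoids the width-fold im2col memory blowup. Weights are He-normal
initialized from a seeded generator; all training, splitting, simulation
and audit randomness flows from explicit seeds, so single-threaded runs
reproduce loss histories bit for bit.

## Preprocessing

Band-pass 0.3–35 Hz for EEG and EOG, 10–100 Hz for EMG, each followed by a
powerline notch (50 Hz default; a 60 Hz/wide-band variant is provided).
Filters are zero-phase (forward–backward) 4th-order Butterworth plus an
IIR notch with Q = 30 — phase-safe so waveform positions survive for the
CAM audit. The EMG upper corner equals Nyquist at 200 Hz, where a digital
band-pass is undefined; a corner at ≥ 0.99× Nyquist drops the low-pass
half and the filter acts as a high-pass. Non-canonical sampling rates are
brought to 200/100/200 Hz by FFT resampling before anything else.
Normalization is per record, per channel (z-score), computed after
filtering; per-epoch normalization is a config choice. Records are cut
into floor(duration/30) epochs; a trailing partial epoch is dropped, and
epochs labelled NS (not scorable) are removed together with their labels
and excluded from training and evaluation.

## Training

Adam on cross-entropy; one iteration = one full pass over the training
epochs. One sixth of the epochs are reserved (seeded, by epoch, not by
record) to compute validation loss. Training stops at 200 iterations or
when the minimum validation loss has not improved for 5 consecutive
iterations, whichever is first, and the weights from the best-validation
iteration are restored (standard early-stopping semantics; the stop index
is exactly min(cap, best + patience)). Defaults follow full-scale practice
(lr 5e-6, batch 256); the shipped small-cohort experiments use lr 1.5e-3,
batch 128, cap 8 — with a few thousand easily separable epochs the loss
plateaus within eight passes, and the cap keeps the full test suite and
acceptance run inside sensible CPU time.

Cross-validation partitions at the record level (no record contributes
epochs to both sides of a fold; the contract asserts this), and fold
confusion matrices are **summed** before computing pooled metrics — never
averaged per fold — so every test epoch counts equally when folds differ
in size.

## Evaluation statistics

With E(s,u) the count of epochs labelled s by the expert and u by the
model, accuracy is Σ_s E(s,s)/M; Cohen's κ = (accuracy − p_e)/(1 − p_e)
with p_e = Σ_s (row_s/M)(col_s/M); per-stage recall and precision are the
diagonal over row and column sums. Stages absent from the reference
(recall) or the predictions (precision) are reported as missing and
flagged — never coerced to 0, which would silently distort macro
summaries. Conventional κ interpretation labels (> 0.8 "almost perfect")
are attached as annotations only. The implementation is checked against a
literal brute-force coding of these formulas to 1e-12 and against
scikit-learn's kappa.

## Explainability audit

For each *true-positive* epoch (prediction = expert label = the stage
under audit) the predicted stage's CAM row is averaged into 60 half-second
bins, and bins are ranked within the epoch by top-percentile (largest CAM
→ percentile near 0; ties share the mean rank — a constant row sits
entirely at 50). Ranked bins pool across epochs into 20 percentile bins of
5%, and each bin reports the fraction of its half-second points that
intersect an annotated wave interval of the requested type (half-open
interval logic, any channel by default). The enrichment factor —
(overlap in the top bins) / (overall prevalence among scored points) —
is exactly 1 for a CAM carrying no location information and 1/prevalence
for a CAM that marks wave intervals perfectly. Restricting to true
positives makes "predicted-stage CAM" and "reference-stage CAM"
coincide, so the audit is insensitive to that ambiguity.

## Synthetic PSG generator

The generator produces fully labelled cohorts so that the whole pipeline —
including the explainability audit, which needs ground-truth wave
locations — is testable without clinical data.

**Hypnogram.** A 5-state Markov chain at 30-s resolution, starting awake.
The default transition matrix is a sticky Metropolis–Hastings chain on the
physiological adjacency graph (the W–N1–N2–N3 depth ladder, REM cycling
with W/N1/N2, and a direct W↔N2 edge for awakenings and rapid re-entry)
with self-transition weight 0.9, constructed so its stationary
distribution *equals* the target stage prior — by default the clinical
overnight mix W 19.8%, REM 13.6%, N1 9.7%, N2 42.8%, N3 14.0%. Mean bout
length is ~10 epochs (5 min). This is a fixture device: it has the right
stage proportions and plausible local transitions but no sleep-cycle
architecture (no ultradian rhythm, no sleep-onset latency model).

**Backgrounds.** Per-channel Gaussian noise with a 1/f amplitude spectrum,
given a 2-Hz knee (1.5-power roll-off below) that mimics the clinical
amplifier high-pass — without it, infra-slow drift would dominate every
PSD and mask the stage emphasis. On top, a stage-typical band emphasis:
alpha (8–13 Hz) awake, theta (4–7 Hz) in N1/REM, broad 2–14 Hz in N2, and
large slow (0.5–2 Hz) activity in N3 with roughly doubled amplitude. EMG
is 20–99 Hz noise whose tone is highest awake (20 µV rms) and collapses in
REM (2 µV, atonia); EOG is low-frequency noise with discrete eye-movement
events injected separately.

**Characteristic waves.** Discrete events are injected additively into
epochs of their associated stage only, at per-stage Poisson rates
(defaults, per epoch: W — alpha 2.5, blink 1.0, REM-type eye movements
0.4, SEM 0.4, arousal 0.2; N1 — vertex 1.0, LAMF 1.5, SEM 0.6, arousal
0.2; N2 — spindle 2.5, K-complex 1.0; N3 — delta 5.0; REM — rapid eye
movements 2.0, sawtooth 1.2, LAMF 1.0, EMG bursts 0.4; rates chosen to be
clinically plausible event densities). Waveforms implement the defining
morphology of each event: spindles are 11–16 Hz with a Hann envelope
peaking at the wave's center; K-complexes are a sharp negative deflection
immediately followed by a positive wave, total duration > 0.5 s; delta
waves are single slow cycles (band configurable, default 0.5–2 Hz) with
peak amplitudes drawn from 85–140 µV, always above the 75 µV slow-wave
criterion; vertex waves are < 0.5-s sharp transients; sawtooth waves are
2–6 Hz; blinks are 0.5–2 Hz same-polarity EOG deflections; SEM is slow
sinusoidal and REMs are rapid random deflections, both anti-phase across
the two EOG channels; arousals are an abrupt 16–30 Hz shift accompanied by
an EMG burst. Every injection produces a typed annotation on the 0.5-s
grid (duration rounded outward), and injected waves stay inside their
epoch, so the stage-compatibility invariant holds by construction. A
configurable fraction (default 5%) of epochs instead receive a large
movement-like artifact and the label NS.

Amplitudes are specified in µV *pre-normalization* so the 75-µV delta
criterion is meaningful; z-scoring happens downstream in preprocessing.

**What passing on synthetic data does and does not show.** The generator's
stages are separable by design (band content, EMG tone, and injected
waves all carry stage information), so held-out accuracy ≥ 0.8 on a
40-record cohort demonstrates that the pipeline — I/O, preprocessing,
model, optimization, evaluation — is wired correctly and that the
generator encodes learnable structure; it says nothing about clinical
accuracy on real PSG, where stage boundaries are vastly noisier. Likewise
the enrichment audit shows the CAM mechanism localizes known injected
evidence; real characteristic waves are subtler.

## Shipped experiment scale

The end-to-end experiment in the test suite and the acceptance script uses
40 one-hour records (≈ 4800 epochs; ~4550 after NS removal), 30 for
training and 10 held out, with the reduced architecture, lr 1.5e-3, batch
128, 8 iterations. This scale trains in a few minutes on one CPU while
leaving wide margins over the accuracy/kappa bars. Typical results across
cohort seeds: held-out accuracy 0.95–1.00, κ 0.94–1.00, top-10% CAM
enrichment ≈ 2–4 for alpha/spindle/delta, and 100% prediction stability
under spindle repositioning.

## Known limitations

- The chain/background/wave generator is not clinically realistic sleep;
  see above.
- Per-epoch context is deliberately absent (single-epoch input); isolated
  epochs whose stage differs from both neighbours are a known weak point
  of GAP-based scoring generally.
- Learning-curve and cross-validation helpers retrain from scratch per
  fold/size; at full architecture scale they are GPU-class jobs and are
  exercised here only at reduced scale.
- EDF support covers signal channels only (no EDF+ annotation channels);
  hypnograms and wave labels travel as CSV.
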