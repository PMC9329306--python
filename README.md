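# sleepcam

Explainable sleep-stage scoring from polysomnography (PSG) with a 1-D
convolutional network that shows its reasoning.

## Who this is for and what it does

Sleep physicians and sleep-research engineers score overnight PSG — six
EEG derivations, two EOG derivations and one submental EMG channel — in
30-second epochs into the five AASM stages (W, REM, N1, N2, N3), guided by
characteristic waves: alpha rhythm for wakefulness, sleep spindles and
K-complexes for N2, high-amplitude slow waves for N3, rapid eye movements
with muscle atonia for REM. Automated scorers reach expert-level agreement
but are mostly black boxes, which limits clinical trust.

`sleepcam` implements a scoring network whose architecture makes the
evidence inspectable. Per modality, signals pass through

    conv(ELU) → conv(ELU) → max-pool → layer-norm (across kernels),

the three feature streams are concatenated, and a *linear* head with one
kernel per stage produces a class activation map (CAM) `A ∈ R^{5×T}`.
Global average pooling and a softmax turn the CAM into stage confidences:

    p = softmax( (1/T) Σ_t A[·, t] ),

so the probability of each stage is *exactly* the softmax of the
time-averaged CAM, and the high-CAM sub-intervals are the model's stated
evidence. Layer normalization across kernels makes features
amplitude-relative (a waveform's "clearness" against the simultaneous
background), mirroring how the AASM manual defines several waves.

The package provides the full experimental loop:

- **psg I/O** — EDF read/write for the 9-channel AASM montage at
  200/100/200 Hz (EEG/EOG/EMG), hypnogram and wave-annotation CSVs;
- **preprocessing** — zero-phase band-pass (0.3–35 Hz EEG/EOG, 10–100 Hz
  EMG) + powerline notch, FFT resampling, per-record z-scoring, 30-s epoch
  segmentation with NS (unscorable) exclusion;
- **model & training** — the network above in pure numpy/scipy (explicit
  gradients, Adam, early stopping on held-out validation loss),
  record-wise cross-validation and learning curves;
- **evaluation** — confusion matrix, accuracy, Cohen's κ, per-stage
  recall/precision, with fold pooling by summed matrices;
- **explainability** — the CAM audit: rank half-second CAM bins within
  each true-positive epoch, measure their overlap with annotated wave
  intervals, and summarize with an enrichment factor (1 = uninformative,
  1/prevalence = perfect localization);
- **synthetic PSG** — a generator producing fully labelled cohorts
  (Markov hypnograms with a clinical stage mix, stage-conditioned
  backgrounds, characteristic waves injected with ground-truth 0.5-s
  labels), so everything above is testable without clinical data.

See `docs/methods.md` for the model, the generator, and every numerical
choice; `examples/` contains one short runnable script per capability.

## Worked example

`python examples/02_train_and_evaluate.py` generates ten one-hour
synthetic records, trains the reduced architecture on eight, and scores
the two unseen records (about three minutes on one CPU):

```
training on 915 epochs from 8 records; testing on 229 epochs from 2 unseen records
stopped at iteration 6 (best validation loss at iteration 6)

confusion matrix (rows = truth, cols = prediction):
         W   REM    N1    N2    N3
   W    81     0     0     0     0
 REM     0    31     0     3     0
  N1     0    13     0    15     0
  N2     0     0     0    81     0
  N3     0     0     0     3     2

accuracy 0.852  kappa 0.784 (substantial)
```

Rows are ground-truth stages, columns the model's predictions; the
off-diagonal cells are the disagreements. At this miniature training scale
every N1 epoch is mistaken for REM or N2 — N1 is the hardest stage for
human raters too, and with 30 training records (the scale used by the test
suite and the acceptance script) held-out accuracy rises to ~0.95 with κ
~0.94 and N1 is recovered. `examples/03_explain_decisions.py` then prints,
for single epochs, which half-second sub-intervals carried the highest CAM
evidence and which annotated waves they overlap, plus the spindle
enrichment factor of the top-10% CAM bins.

## Command line

A thin CLI wires the same library functions for shell use; every run
writes a manifest (seed, config hash, inputs/outputs):

```
sleepcam simulate --seed 1 --n-records 4 --hours 1 --out cohort/
sleepcam train    --records cohort/ --config cfg.yaml --seed 0 --out model.npz
sleepcam score    --model model.npz --record cohort/r0.edf --out pred.csv
sleepcam evaluate --ref cohort/r0_hypnogram.csv --pred pred.csv --out report.json
sleepcam explain  --model model.npz --record cohort/r0.edf \
                  --hypnogram cohort/r0_hypnogram.csv \
                  --waves cohort/r0_waves.csv --out audit/
```

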