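"""Audit what the model looked at: CAM bins vs. annotated waves.

Trains a small model, then (a) prints a reasoning report for one N2 epoch
— the top half-second sub-intervals by CAM value and any annotated waves
they overlap — and (b) computes the percentile-overlap histogram and
enrichment factor for sleep spindles. Run from the repository root:

    python examples/03_explain_decisions.py
"""

import numpy as np

import sleepcam as sc
from sleepcam.explain import merge_histograms
from sleepcam.preprocess import EpochSet, prepare_record

config = sc.SyntheticConfig(n_records=10, record_hours=1.0, seed=3)
records = sc.generate_cohort(config)
sets = [prepare_record(r.record, r.hypnogram) for r in records]
tconfig = sc.TrainingConfig(learning_rate=1.5e-3, max_iterations=6,
                            patience=3, batch_size=128, seed=0)
model = sc.train_model(sc.reduced_config(0), tconfig,
                       EpochSet.concatenate(sets[:8])).model

# --- one epoch's reasoning report --------------------------------------
rec, es = records[8], sets[8]
cams = model.forward(es)
n2_positions = [i for i, lab in enumerate(es.labels) if lab == "N2"]
pos = n2_positions[0]
epoch_index = int(es.epoch_indices[pos])
report = sc.reasoning_report(epoch_index, cams[pos], rec.waves, k=5)
print(f"epoch {epoch_index}: predicted {report.predicted_stage} "
      f"(truth {rec.hypnogram[epoch_index]})")
for iv in report.intervals:
    waves = ", ".join(iv.overlapping_waves) or "-"
    print(f"  [{iv.start_s:7.1f}, {iv.end_s:7.1f}) s  "
          f"CAM {iv.cam_value:+.3f}  waves: {waves}")

# --- spindle enrichment over the two held-out records -------------------
hists = []
for rec, es in zip(records[8:], sets[8:]):
    pairs = list(zip(es.epoch_indices.tolist(), model.forward(es)))
    try:
        hists.append(sc.overlap_histogram(pairs, rec.hypnogram, rec.waves,
                                          "N2", "spindle"))
    except sc.SleepCamError:
        continue
pooled = merge_histograms(hists)
enr = sc.enrichment(pooled, top_percent=10.0)
print(f"\nspindle audit over {pooled.n_epochs} true-positive N2 epochs:")
print(f"  overall spindle prevalence: {pooled.prevalence:.3f} "
      "(fraction of half-second points inside an annotation)")
print(f"  overlap in top-10% CAM bins: "
      f"{pooled.overlap_counts[:2].sum() / max(pooled.counts[:2].sum(), 1):.3f}")
print(f"  enrichment factor: {enr:.2f}")
print("An enrichment of 1 would mean the CAM carries no information about")
print("where spindles are; values above 1 mean the model's highlighted")
print("sub-intervals preferentially cover the annotated spindles. Enrichment")
print("grows with training scale: the 30-record study in the test suite")
print("reaches ~3 for spindles.")
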