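"""Generate a small labelled synthetic PSG cohort and describe it.

Builds four one-hour records with the default generation settings (stage
mix targeting the clinical overnight distribution, characteristic waves
injected per stage), writes them as EDF + CSV, and prints the stage and
wave-type inventories. Run from the repository root:

    python examples/01_simulate_cohort.py
"""

import collections
import tempfile
from pathlib import Path

import sleepcam as sc

out_dir = Path(tempfile.mkdtemp(prefix="sleepcam_cohort_"))
config = sc.SyntheticConfig(n_records=4, record_hours=1.0, seed=1)
records = sc.generate_cohort(config, out_dir=out_dir)

stages = collections.Counter()
waves = collections.Counter()
for rec in records:
    stages.update(rec.hypnogram)
    waves.update(a.wave_type for a in rec.waves)

print(f"wrote {len(records)} records to {out_dir}")
print("stage counts (epochs):", dict(stages))
print("injected waves:", dict(waves))
print()
print("Each record is an EDF with the 9-channel AASM montage at 200/100/200 Hz")
print("plus a hypnogram CSV (one stage per 30-s epoch; NS = unscorable) and a")
print("wave CSV (typed 0.5-s-grid intervals, the ground truth for the CAM audit).")
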