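"""Generate the synthetic study cohort and one raw signal-level trial.

Writes the measure-level cohort (per-stride SLA, step lengths, ML MoS, work
rates; per-breath metabolic rate for 17 subjects over 20 min of split-belt
adaptation) and, for one subject, a raw 2-min trial (markers, per-belt forces
and moments, breaths) to results/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from splitbelt.io import write_table
from splitbelt.model import CohortConfig
from splitbelt.synth import generate_cohort, generate_signal_trial

OUT = Path(__file__).resolve().parents[1] / "results"

cfg = CohortConfig(n_subjects=17, duration=1200.0, seed=1)
cohort = generate_cohort(cfg)
write_table(cohort.data, OUT / "measures.csv", "measures")
subs = pd.DataFrame([{"id": s.id, "mass_kg": s.mass, "height_m": s.height,
                      "leg_length_m": s.leg_length, "vo2peak": s.vo2peak,
                      "gender": s.gender} for s in cohort.subjects])
write_table(subs, OUT / "subjects.csv", "subjects")

trial_cfg = CohortConfig(n_subjects=1, duration=120.0, seed=1)
trial = generate_signal_trial(cohort.subjects[0], trial_cfg)
write_table(trial.markers, OUT / "markers.csv", "markers")
write_table(trial.forces, OUT / "forces.csv", "forces")
write_table(trial.breaths, OUT / "breaths.csv", "breaths")

print(f"cohort: {cfg.n_subjects} subjects x {cfg.duration:.0f} s "
      f"({len(cohort.data)} samples across {cohort.data['measure'].nunique()} measures)")
print(f"signal trial: {len(trial.forces)} force samples at 1 kHz, "
      f"{len(trial.markers)} marker samples at 100 Hz")
print(f"tables written to {OUT}")
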