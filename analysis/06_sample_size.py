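"""Simulation-based minimum-sample-size heuristic.

Simulates cohorts of increasing size from known SLA adaptation parameters,
refits the dual-rate mixed model, and selects the smallest N at which the
spread of the time-constant estimation errors from sizes N..N_max falls to
half the spread below N.  Run here at reduced scale (N = 4..12, 2 replicates
per size, 10-min series) so it completes in about a minute.
"""

import sys
import warnings
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from splitbelt.adaptation_fit import sample_size_simulation
from splitbelt.model import DEFAULT_TRUTH

warnings.filterwarnings("ignore")
OUT = Path(__file__).resolve().parents[1] / "results"

res = sample_size_simulation(DEFAULT_TRUTH["sla"], "sla",
                             n_range=range(4, 13, 2), reps=2, seed=1,
                             duration=600.0)
print(res.table.to_string(index=False))
print(f"selected minimum N = {res.n_selected} "
      f"(criterion {'met' if res.criterion_met else 'NOT met'})")
OUT.mkdir(exist_ok=True)
res.table.to_csv(OUT / "sample_size.csv", index=False)
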