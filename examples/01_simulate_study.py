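"""Generate a synthetic factorial HD-EMG study with planted ground truth.

One subject, 2 knee positions x 2 effort levels x 2 contraction directions,
recorded on the GM grid (13x5, one missing corner) and the two SO arrays,
with the antagonist activation field planted at 0.4 x the agonist field —
so every CAN estimate downstream should land near 0.4.
"""

import json
import tempfile
from pathlib import Path

from coactmap import default_study_spec, make_study

out = Path(tempfile.mkdtemp()) / "study"
spec = default_study_spec(n_subjects=1, alpha=0.4, master_seed=1)
make_study(spec, out)

n_emg = len([p for p in out.glob("*.dat") if not p.stem.endswith("_torque")])
n_torque = len(list(out.glob("*_torque.dat")))
gt = json.loads((out / "ground_truth.json").read_text())
key = str(("GM", "flexed_90", "max_100"))
planted = gt["can_fields"][key][6][2]  # mid-grid channel

print(f"study written to {out}")
print(f"EMG trials: {n_emg}, torque traces: {n_torque}")
print(f"planted CAN at grid centre (GM, knee flexed, maximal): {planted:.2f}")
# 24 EMG trials = 3 detection systems x 8 condition cells; the planted CAN
# of 0.40 is the ground truth every estimator is later judged against.
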