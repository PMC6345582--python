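"""Simulate the demo synthetic observer and persist its trials and activity.

Writes results/demo/{trials.h5, meg.h5} and prints the decision marginal.
The observer has six planted features (two diagnostic of "the nuns", two of
"Voltaire", two nondiagnostic), a nondiagnostic wavefront collapsing at
170 ms, and an integration voxel group that accumulates diagnostic features
between 120 and 200 ms.
"""

import numpy as np

from _common import OUT, SEED, load_dataset

from sir import io
from sir.core import DECISION_LABELS

ds = load_dataset()
io.save_trials(OUT / "trials.h5", ds.trials, seed=SEED)
io.save_activity(OUT / "meg.h5", ds.activity, seed=SEED)

counts = np.bincount(ds.trials.decisions, minlength=3)
print(f"simulated {ds.trials.n_trials} trials, {ds.activity.n_voxels} voxels, "
      f"{ds.activity.n_times} time points")
for name, c in zip(DECISION_LABELS, counts):
    print(f"  {name}: {c} ({c / counts.sum():.1%})")
print(f"planted junction: {ds.truth.junction_ms:.0f} ms")
print(f"wrote {OUT / 'trials.h5'} and {OUT / 'meg.h5'}")
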