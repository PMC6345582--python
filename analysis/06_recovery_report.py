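"""Collate recovery metrics against the planted ground truth.

Reads the artifacts written by scripts 02-05 and summarizes how well each
pipeline stage recovered what was planted; writes results/demo/recovery.json.
"""

import json

import numpy as np

from _common import OUT, load_dataset

from sir import dynamics as dyn
from sir import io, synthetic

ds = load_dataset()
outputs = {
    "diagnostic_maps": {
        c: io.load_diagnostic_map(OUT / f"diagnostic_{c}.h5")
        for c in ("nuns_vs_dk", "voltaire_vs_dk")
    },
    "basis": io.load_basis(OUT / "features.h5"),
}

rep = io.load_representation_matrix(OUT / "repmat.h5")
nondiag_tp = dyn.max_course(rep, "nondiagnostic", window_ms=2.0)
reg = dyn.wavefront_regressions(nondiag_tp, ds.activity.coords)
dist = np.linalg.norm(ds.activity.coords - ds.activity.coords[reg.origin_voxel], axis=1)
_, marker = dyn.junction(nondiag_tp, dist)
outputs["junction_ms"] = marker

red = io.load_redundancy_matrix(OUT / "redundancy.h5")
from sir.behavior import representational_complexity

outputs["complexity"] = representational_complexity(red)

report = synthetic.recovery_report(ds, outputs)
(OUT / "recovery.json").write_text(json.dumps(report, indent=2))
for k, v in report.items():
    print(f"{k}: {v}")
print(f"wrote {OUT / 'recovery.json'}")
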