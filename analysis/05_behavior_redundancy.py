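"""Feature representation for behavior: redundancy, complexity, decision MI.

Computes the co-information redundancy matrix over diagnostic features,
counts representational complexity in five windows spanning 120-220 ms,
computes the <activity; decision> MI map, and decomposes redundancy by
behavioral contrast.  Writes results/demo/{redundancy.h5, complexity.tsv}.
"""

import numpy as np

from _common import OUT, SEED, load_dataset

from sir import behavior as beh
from sir import features as feat
from sir import io

ds = load_dataset()
basis = io.load_basis(OUT / "features.h5")
labels = np.asarray(basis.labels)
diag_idx = np.flatnonzero(np.isin(labels, ["diagnostic_nuns", "diagnostic_voltaire"]))
print(f"diagnostic features: {diag_idx.tolist()} ({labels[diag_idx].tolist()})")

coefs = feat.feature_coefficients(ds.trials.masks, basis)
dcoefs = feat.FeatureCoefficients(coefs.coefs[:, diag_idx])
red = beh.redundancy_matrix(
    dcoefs, ds.activity, ds.trials.decisions, n_perm=100,
    rng=np.random.default_rng([SEED, 7]), feature_labels=labels[diag_idx].tolist(),
)
io.save_redundancy_matrix(OUT / "redundancy.h5", red, seed=SEED)
print(f"redundancy matrix {red.red.shape}, threshold {red.fwer_threshold:.4f} bits")

cmap = beh.representational_complexity(red)
io.export_complexity_tsv(OUT / "complexity.tsv", cmap)
totals = cmap.counts.sum(axis=0)
print("complexity totals per 20 ms window over [120, 220] ms:", totals.tolist())
print(f"complexity peaks in window {int(np.argmax(totals)) + 1} of 5")

mi_map, thr = beh.decision_mi(
    ds.activity, ds.trials.decisions, n_perm=100, rng=np.random.default_rng([SEED, 23])
)
print(f"decision MI: {(mi_map > thr).sum()} significant (voxel, time) cells "
      f"(threshold {thr:.4f} bits)")

for contrast in ("nuns_vs_dk", "voltaire_vs_dk"):
    rc = beh.decision_specific_redundancy(
        dcoefs, ds.activity, ds.trials.decisions, contrast, n_perm=100,
        rng=np.random.default_rng([SEED, 29]),
    )
    per_feature = rc.significant.sum(axis=(1, 2))
    print(f"{contrast}: significant cells per diagnostic feature {per_feature.tolist()}")
print(f"wrote {OUT / 'redundancy.h5'} and {OUT / 'complexity.tsv'}")
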