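# sir — stimulus information representation

`sir` is an information-theoretic pipeline for asking, on single trials, how
the information content of a visual stimulus relates to both neural activity
and perceptual decisions — three variables at once, rather than the usual
two.  It targets experiments in the Bubbles reverse-correlation tradition: an
ambiguous grayscale image is decomposed into one-octave spatial-frequency
(SF) bands and revealed through randomly placed Gaussian apertures; on each
trial an observer reports one of three percepts ("the nuns", "Voltaire",
"don't know") while source-localized MEG-style activity is recorded as a
voxel × time array with two channels (amplitude and its temporal gradient).

The pipeline answers, in order:

1. **Which pixels drive behavior?**  Per-pixel visibility is binarized at
   0.2 and related to the binary behavioral contrast with plug-in mutual
   information (MI), familywise-corrected by the method of maximum statistics
   (the threshold is the 99.9th percentile of the max MI over all pixels and
   bands under label permutation).
2. **Which stimulus features does the brain represent?**  MI images between
   pixel visibility and a reduced activity matrix are factorized with
   non-negative matrix factorization (NMF); the thresholded (15% of max),
   L2-normalized components are the *brain features*.  Per-trial feature
   coefficients (mask · feature) are related to every voxel/time cell with
   Gaussian-copula MI (GCMI), giving the feature × voxel × time
   *representation matrix*.
3. **How do representations evolve?**  Features are classified diagnostic or
   nondiagnostic via 75th/25th-percentile MI rules; per-voxel max-MI courses
   give onsets, offsets, durations, robust onset/duration-vs-distance
   regressions (the traveling wavefront), a windowed de-meaned dot-product
   divergence profile, and the spatio-temporal *junction* where nondiagnostic
   representation collapses.
4. **Which representations support behavior?**  Co-information redundancy

       RED = I(F; D) + I(F; M) − I(F; (M, D))

   for feature F, bivariate voxel activity M, and decision D, computed per
   (diagnostic feature, voxel, time) cell with permutation FWER thresholds;
   *representational complexity* counts, per voxel, the distinct features
   redundantly represented with behavior in five windows spanning 120–220 ms.

A fully specified synthetic observer (`sir.synthetic`) provides ground truth
for every stage — planted templates, a noisy evidence-race decision rule
calibrated to 25% "don't know" responses, and encoding voxels with a planted
wavefront, junction, and feature-accumulation group — so the entire pipeline
is testable without any recordings.

## Worked example

The numbered scripts under `analysis/` run one demo observer (800 trials,
160 voxels, seed 7) end to end, writing artifacts under `results/demo/`:

```bash
cd analysis
python 01_simulate_observer.py
python 02_diagnostic_features.py
python 03_brain_features.py
python 04_wavefront_dynamics.py
python 05_behavior_redundancy.py
python 06_recovery_report.py
```

Output of `03_brain_features.py` (abridged):

```
planted feature -> recovered match:
  nun_face_left      -> component 1 (cosine 0.900, labeled diagnostic_nuns)
  nun_face_right     -> component 5 (cosine 0.878, labeled diagnostic_nuns)
  voltaire_face      -> component 0 (cosine 0.900, labeled diagnostic_voltaire)
  voltaire_eye       -> component 2 (cosine 0.871, labeled diagnostic_voltaire)
  flank_texture      -> component 3 (cosine 0.888, labeled nondiagnostic)
  background_blob    -> component 4 (cosine 0.893, labeled nondiagnostic)
median cosine 0.890
```

NMF recovered all six planted features (cosine similarity ≈ 0.9 after
Hungarian matching) and the percentile rules labeled every one correctly.
`04_wavefront_dynamics.py` then reports:

```
nondiagnostic wavefront: onset slope +0.473 ms/mm (p=3.5e-164),
                         duration slope -0.473 ms/mm (p=3.5e-164)
junction: 25 far voxels, temporal marker 172 ms (planted 170 ms)
diagnostic/nondiagnostic representations similar up to the [170, 180) ms
window, divergent afterwards
```

i.e. representation onset propagates away from the origin voxel while
duration shrinks, and the nondiagnostic wavefront collapses within 2 ms of
the planted 170 ms junction.  `05_behavior_redundancy.py` shows
representational complexity peaking in window 4 (180–200 ms) and
decision-specific redundancy selecting the correct features per percept
(nuns-diagnostic features redundant in the nuns contrast, Voltaire features
in the Voltaire contrast).

A single-command variant of the same pipeline is available as
`sir run-all --seed 7 --out runs/demo`, with per-stage subcommands
(`sir simulate`, `sir diagnostic`, `sir features`, `sir repmat`,
`sir dynamics`, `sir redundancy`).

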