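"""Synthetic observer: planted templates, decisions, and encoding voxel activity.

The generator emulates the structure of the real experiment at desk scale so
every pipeline stage can be validated against known ground truth:

* stimuli are Bubbles masks (Gaussian apertures per SF band, 60 per trial);
* six planted features with disjoint (pixel, band) supports, all within the
  first three SF bands — two diagnostic of "the nuns", two diagnostic of
  "Voltaire", two nondiagnostic;
* decisions follow a noisy evidence race: per-percept evidence is the
  standardized visibility of that percept's templates plus Gaussian noise;
  the maximum decides, unless it falls below a "don't know" threshold
  calibrated so the "don't know" rate matches its target (reference 25%);
* voxel activity encodes feature coefficients through a temporal kernel with
  spatially graded onsets: nondiagnostic-encoding voxels form a wavefront
  whose representation duration shrinks with distance from the origin and
  collapses at the planted junction time, while diagnostic-encoding voxels
  persist past it; a small "integration" voxel group accumulates diagnostic
  features over staggered onsets (the representational-complexity peak);
* the gradient channel is the discrete temporal derivative of the amplitude
  channel (noise included), as in the real bivariate activity measure.

The decision model is a stand-in: the original study measured humans and had
no behavioral model.  Regenerating any dataset with the same seed is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bubbles
from .core import DONT_KNOW, NUNS, VOLTAIRE, SampledTrialSet, SourceActivity

__all__ = [
    "EncodingEntry",
    "GroundTruth",
    "SyntheticDataset",
    "default_ground_truth",
    "simulate_trials",
    "simulate_activity",
    "simulate_dataset",
    "recovery_report",
]


@dataclass
class EncodingEntry:
    """One (voxel, feature) encoding: active on [onset, onset + duration].

    ``envelope_ms`` sets the temporal-kernel timebase; when longer than
    ``duration_ms`` the kernel is truncated at the offset (an abruptly ending
    representation), which is how the nondiagnostic wavefront collapses at the
    junction while staying in phase with its diagnostic twin before it.
    """

    voxel: int
    feature_id: int
    onset_ms: float
    duration_ms: float
    gain: float
    diagnostic: bool
    envelope_ms: float | None = None


@dataclass
class GroundTruth:
    """Everything the synthetic observer is made of."""

    templates: np.ndarray  # (n_features, size, size, n_bands), unit L2 rows
    supports: np.ndarray  # same shape, boolean
    feature_names: list
    diagnostic_flags: np.ndarray  # bool per feature
    percept_of_feature: np.ndarray  # NUNS / VOLTAIRE / -1
    coords: np.ndarray  # (n_voxels, 3) mm
    encoding: list  # of EncodingEntry
    times_ms: np.ndarray
    junction_ms: float
    decision_noise_sd: float = 0.7  # a reliable observer: evidence SNR ~ 1.4
    dont_know_target: float = 0.25
    dont_know_threshold: float | None = None  # None -> calibrated per dataset
    activity_noise_sd: float = 1.0
    kernel: str = "halfcos"
    seed: int = 0

    @property
    def n_features(self) -> int:
        return self.templates.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def mask_size(self) -> int:
        return self.templates.shape[1]

    def templates_flat(self) -> np.ndarray:
        return self.templates.reshape(self.n_features, -1)

    def percept_support(self, percept: int) -> np.ndarray:
        """Union of supports of the features diagnostic of one percept."""
        sel = self.percept_of_feature == percept
        return self.supports[sel].any(axis=0)

    def feature_labels(self) -> list:
        out = []
        for d, p in zip(self.diagnostic_flags, self.percept_of_feature):
            if not d:
                out.append("nondiagnostic")
            else:
                out.append("diagnostic_nuns" if p == NUNS else "diagnostic_voltaire")
        return out


@dataclass
class SyntheticDataset:
    trials: SampledTrialSet
    activity: SourceActivity
    truth: GroundTruth


def _disk(size: int, center, radius: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


# (name, band, center(row, col), radius/size64, diagnostic percept or None)
# all supports sit in the first three SF bands, where aperture scales resolve
# compact features (the coarsest bands carry little localizable information)
_DEFAULT_FEATURES = [
    ("nun_face_left", 0, (22, 18), 6.0, NUNS),
    ("nun_face_right", 0, (22, 46), 6.0, NUNS),
    ("voltaire_face", 2, (40, 32), 12.0, VOLTAIRE),
    ("voltaire_eye", 1, (26, 40), 5.0, VOLTAIRE),
    ("flank_texture", 1, (46, 12), 8.0, None),
    ("background_blob", 0, (10, 32), 9.0, None),
]


def default_ground_truth(
    n_voxels: int = 500,
    mask_size: int = 64,
    n_bands: int = 5,
    junction_ms: float = 170.0,
    time_step_ms: float = 2.0,
    time_span_ms: float = 400.0,
    encoding_fraction: float = 0.7,
    n_integration_voxels: int = 12,
    gain: float = 1.5,
    seed: int = 0,
) -> GroundTruth:
    """The reference synthetic observer.

    Defaults: 64x64 masks over 5 sampled bands, 500 voxels on a 2 ms grid
    spanning 0-400 ms, junction planted at 170 ms.  70% of voxels encode a
    feature (split between the nondiagnostic wavefront, the diagnostic
    wavefront, and the integration group); the rest are pure noise.
    """
    rng = np.random.default_rng([seed, 101])
    scale = mask_size / 64.0
    n_feat = len(_DEFAULT_FEATURES)
    supports = np.zeros((n_feat, mask_size, mask_size, n_bands), dtype=bool)
    names, diag, percept = [], [], []
    for i, (name, band, center, radius, p) in enumerate(_DEFAULT_FEATURES):
        supports[i, :, :, band] = _disk(
            mask_size, (center[0] * scale, center[1] * scale), radius * scale
        )
        names.append(name)
        diag.append(p is not None)
        percept.append(-1 if p is None else p)
    templates = supports.astype(float)
    for i in range(n_feat):
        templates[i] /= np.linalg.norm(templates[i])

    # voxel geometry: origin pole plus a 0-80 mm spread; onset grows with
    # distance from origin (the traveling wavefront)
    coords = rng.uniform(0.0, 80.0, size=(n_voxels, 3))
    coords[0] = 0.0  # origin voxel
    dist = np.linalg.norm(coords, axis=1)
    dmax = dist.max()

    n_encode = int(round(encoding_fraction * n_voxels))
    order = rng.permutation(n_voxels)
    n_int = min(n_integration_voxels, n_encode)
    int_vox = order[:n_int]
    wave_vox = order[n_int:n_encode]
    diag_ids = [i for i in range(n_feat) if diag[i]]
    nondiag_ids = [i for i in range(n_feat) if not diag[i]]

    # Wavefront voxels carry one nondiagnostic and one diagnostic feature from
    # the same distance-graded onset: the two representations overlap spatially
    # before the junction (positive divergence similarity), then the
    # nondiagnostic one ends at the junction while the diagnostic one persists.
    encoding: list = []
    t_end = time_span_ms - time_step_ms
    for j, v in enumerate(wave_vox):
        onset = 60.0 + 60.0 * dist[v] / dmax
        full = (t_end - 20.0) - onset
        encoding.append(
            EncodingEntry(int(v), nondiag_ids[j % len(nondiag_ids)], onset,
                          junction_ms - onset, gain, False, envelope_ms=full)
        )
        encoding.append(
            EncodingEntry(int(v), diag_ids[j % len(diag_ids)], onset, full, gain, True)
        )
    # integration voxels: diagnostic features accumulate with staggered onsets
    # and a common offset before 200 ms -> complexity ramps up then collapses;
    # convergence zones amplify their inputs, hence the higher gain
    stagger = [135.0, 158.0, 181.0, 188.0]
    for v in int_vox:
        for f, onset in zip(diag_ids, stagger):
            encoding.append(
                EncodingEntry(int(v), f, onset, 198.0 - onset, 1.8 * gain, True)
            )

    times = np.arange(0.0, time_span_ms, time_step_ms)
    return GroundTruth(
        templates=templates,
        supports=supports,
        feature_names=names,
        diagnostic_flags=np.array(diag),
        percept_of_feature=np.array(percept),
        coords=coords,
        encoding=encoding,
        times_ms=times,
        junction_ms=junction_ms,
        seed=seed,
    )


def simulate_trials(
    truth: GroundTruth,
    n_trials: int,
    rng: np.random.Generator,
    allow_degenerate: bool = False,
) -> SampledTrialSet:
    """Bubbles masks plus evidence-race decisions for ``n_trials`` trials.

    Masks are generated directly on the analysis grid (sigmas scaled from the
    256 px reference).  Evidence for each percept is the equal-weight average
    of the standardized visibilities of that percept's diagnostic features
    (each template contributes the same evidence weight regardless of its
    support size), plus Gaussian noise; the argmax percept wins if its
    evidence clears the "don't know" threshold (calibrated to the target rate
    when unset).
    """
    if n_trials < 100:
        raise ValueError(f"need at least 100 trials, got {n_trials}")
    size = truth.mask_size
    sigmas = [bubbles.deg_to_px(s, size) for s in bubbles.DEFAULT_SIGMAS_DEG]
    alloc = bubbles.default_aperture_allocation(sigmas_px=sigmas)
    masks = np.empty((n_trials, size, size, truth.templates.shape[-1]), dtype=np.float32)
    seeds = rng.integers(0, 2**31, size=n_trials)
    for t in range(n_trials):
        ms = bubbles.generate_bubble_masks(
            np.random.default_rng(seeds[t]), alloc, sigmas, image_size=size
        )
        masks[t] = ms.stack()

    flat = masks.reshape(n_trials, -1).astype(float)
    coefs = flat @ truth.templates_flat().T
    sd = coefs.std(axis=0)
    sd[sd == 0] = 1.0
    zcoefs = (coefs - coefs.mean(axis=0)) / sd
    percepts = (NUNS, VOLTAIRE)
    ev = np.empty((n_trials, len(percepts)))
    for j, p in enumerate(percepts):
        sel = truth.percept_of_feature == p
        e = zcoefs[:, sel].mean(axis=1)
        ev[:, j] = (e - e.mean()) / e.std()
    ev += truth.decision_noise_sd * rng.standard_normal(ev.shape)
    best = ev.max(axis=1)
    thr = truth.dont_know_threshold
    if thr is None:
        thr = float(np.quantile(best, truth.dont_know_target))
    decisions = np.where(best > thr, np.array(percepts)[np.argmax(ev, axis=1)], DONT_KNOW)
    counts = np.bincount(decisions, minlength=3)
    if counts[NUNS] == 0 or counts[VOLTAIRE] == 0:
        if not allow_degenerate:
            raise ValueError(
                "degenerate decision rule: class counts "
                f"{dict(zip(('nuns', 'voltaire', 'dont_know'), counts.tolist()))}; "
                f"threshold {thr:.3g} exceeds attainable evidence"
            )
    return SampledTrialSet(masks, decisions.astype(np.int64), seeds)


def _kernel(
    times: np.ndarray,
    onset: float,
    duration: float,
    kind: str,
    envelope: float | None = None,
) -> np.ndarray:
    if duration <= 0:
        raise ValueError(f"encoding duration must be positive, got {duration}")
    envelope = duration if envelope is None else max(envelope, duration)
    tau = (times - onset) / envelope
    active = (tau >= 0) & (times < onset + duration)  # half-open [onset, offset)
    if kind == "halfcos":
        return np.where(active, np.sin(np.pi * np.clip(tau, 0, 1)), 0.0)
    if kind == "boxcar":
        return active.astype(float)
    raise ValueError(f"unknown kernel {kind!r}")


def simulate_activity(
    truth: GroundTruth,
    trials: SampledTrialSet,
    rng: np.random.Generator,
    noise_sd: float | None = None,
) -> SourceActivity:
    """Voxel time courses encoding feature coefficients, plus the gradient channel."""
    noise_sd = truth.activity_noise_sd if noise_sd is None else noise_sd
    n = trials.n_trials
    V = truth.n_voxels
    times = truth.times_ms
    T = times.size
    for e in truth.encoding:
        if e.voxel >= V:
            raise ValueError(f"encoding voxel {e.voxel} out of range (n_voxels={V})")
        if e.duration_ms <= 0:
            raise ValueError(f"encoding duration must be positive, got {e.duration_ms}")
    coefs = trials.masks_flat().astype(float) @ truth.templates_flat().T
    sd = coefs.std(axis=0)
    sd[sd == 0] = 1.0
    z = (coefs - coefs.mean(axis=0)) / sd

    # float32 throughout: activity at this scale must not spawn float64 copies
    amp = rng.standard_normal((n, V, T), dtype=np.float32)
    if noise_sd != 1.0:
        amp *= np.float32(noise_sd)
    for e in truth.encoding:
        k = _kernel(times, e.onset_ms, e.duration_ms, truth.kernel, e.envelope_ms)
        if not k.any():
            continue
        amp[:, e.voxel, :] += (
            e.gain * z[:, e.feature_id][:, None] * k[None, :]
        ).astype(np.float32)
    dt = float(times[1] - times[0]) if T > 1 else 1.0
    data = np.empty((n, V, T, 2), dtype=np.float32)
    data[..., 0] = amp
    data[..., 1] = np.gradient(amp, dt, axis=2)
    del amp
    return SourceActivity(data, truth.coords, times)


def simulate_dataset(
    truth: GroundTruth | None = None,
    n_trials: int = 1500,
    seed: int = 0,
    **truth_kwargs,
) -> SyntheticDataset:
    """One synthetic observer end to end, reproducible from ``seed`` alone."""
    if truth is None:
        truth = default_ground_truth(seed=seed, **truth_kwargs)
    trials = simulate_trials(truth, n_trials, np.random.default_rng([seed, 7]))
    activity = simulate_activity(truth, trials, np.random.default_rng([seed, 11]))
    return SyntheticDataset(trials, activity, truth)


def _jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a, b = a.astype(bool).ravel(), b.astype(bool).ravel()
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else float("nan")


def match_features(recovered: np.ndarray, planted: np.ndarray):
    """Hungarian cosine matching of recovered feature rows to planted rows.

    Returns (assignment, cosines): ``assignment[i]`` is the planted row
    matched to recovered row i.
    """
    from scipy.optimize import linear_sum_assignment

    def _norm(X):
        X = X.reshape(X.shape[0], -1).astype(float)
        nn = np.linalg.norm(X, axis=1, keepdims=True)
        nn[nn == 0] = 1.0
        return X / nn

    R, P = _norm(recovered), _norm(planted)
    cos = R @ P.T
    ri, pi = linear_sum_assignment(-cos)
    return pi, cos[ri, pi]


def recovery_report(dataset: SyntheticDataset, outputs: dict) -> dict:
    """Compare pipeline outputs against the planted ground truth.

    ``outputs`` may contain: 'diagnostic_maps' ({contrast: DiagnosticMap}),
    'basis' (BrainFeatureBasis), 'junction_ms' (float), 'complexity'
    (ComplexityMap); a metric is computed for every stage present, and a
    missing stage that the report requires is rejected by name.
    """
    truth = dataset.truth
    if not outputs:
        raise ValueError("no stage outputs supplied")
    report: dict = {}
    if "diagnostic_maps" in outputs:
        jac = {}
        for contrast, percept in (("nuns_vs_dk", NUNS), ("voltaire_vs_dk", VOLTAIRE)):
            dmap = outputs["diagnostic_maps"].get(contrast)
            if dmap is None:
                raise ValueError(f"missing diagnostic map for contrast {contrast!r}")
            sig = dmap.significant.reshape(truth.supports.shape[1:])
            jac[contrast] = _jaccard(sig, truth.percept_support(percept))
        report["template_jaccard"] = jac
    if "basis" in outputs:
        _, cos = match_features(outputs["basis"].features, truth.templates_flat())
        report["feature_cosines"] = cos.tolist()
        report["feature_cosine_median"] = float(np.median(cos))
    if "junction_ms" in outputs:
        report["junction_error_ms"] = float(abs(outputs["junction_ms"] - truth.junction_ms))
    if "complexity" in outputs:
        cm = outputs["complexity"]
        totals = cm.counts.sum(axis=0)
        report["complexity_peak_window"] = int(np.argmax(totals)) + 1
        report["complexity_totals"] = totals.tolist()
    return report
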