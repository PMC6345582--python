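"""Feature representation for behavior: redundancy, complexity, decision MI.

Co-information redundancy RED = I(F;D) + I(F;M) - I(F;(M,D)) is evaluated for
every (diagnostic feature, voxel, time) cell; positive significant values mark
where and when neural activity carries feature information that is shared
with the perceptual decision.  With the chain-rule construction used here
(I(F;M,D) = I(F;D) + I(F;M|D)), RED reduces to I(F;M) - I(F;M|D), so the
permutation null (shuffled decisions, activity and features fixed) only
perturbs the conditional term.

Representational complexity counts, per voxel and time window over the
extended N/M170 course (120-220 ms), how many distinct features are
significantly redundant with behavior — the growth of this count is the
signature of a region constructing a multi-feature decision representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _gauss
from .core import DONT_KNOW, NUNS, VOLTAIRE, SourceActivity
from .features import FeatureCoefficients

__all__ = [
    "RedundancyMatrix",
    "ComplexityMap",
    "redundancy_matrix",
    "decision_specific_redundancy",
    "representational_complexity",
    "median_complexity",
    "decision_mi",
]

_CONTRAST_CLASSES = {
    "three_way": (NUNS, VOLTAIRE, DONT_KNOW),
    "nuns_vs_dk": (NUNS, DONT_KNOW),
    "voltaire_vs_dk": (VOLTAIRE, DONT_KNOW),
}


@dataclass
class RedundancyMatrix:
    """Feature x voxel x time co-information (bits) with FWER threshold."""

    red: np.ndarray
    fwer_threshold: float
    times_ms: np.ndarray
    contrast: str = "three_way"
    feature_labels: list = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.red > self.fwer_threshold


@dataclass
class ComplexityMap:
    """Per-voxel count of distinct redundant features per time window."""

    counts: np.ndarray  # (n_voxels, n_windows) int
    window_bounds_ms: np.ndarray  # (n_windows, 2)


def _classes_and_index(decisions: np.ndarray, contrast: str):
    if contrast not in _CONTRAST_CLASSES:
        raise ValueError(f"unknown contrast {contrast!r}")
    wanted = _CONTRAST_CLASSES[contrast]
    decisions = np.asarray(decisions)
    sel = np.isin(decisions, wanted)
    idx = np.searchsorted(np.asarray(wanted), decisions[sel])
    counts = np.bincount(idx, minlength=len(wanted))
    if (counts == 0).any():
        empty = [w for w, c in zip(wanted, counts) if c == 0]
        raise ValueError(f"contrast {contrast!r}: class(es) {empty} empty")
    return sel, idx, len(wanted)


def redundancy_matrix(
    coefs: FeatureCoefficients,
    activity: SourceActivity,
    decisions: np.ndarray,
    n_perm: int = 200,
    alpha_percentile: float = 95.0,
    rng: np.random.Generator | None = None,
    contrast: str = "three_way",
    bias_correct: bool = True,
    feature_labels: list | None = None,
) -> RedundancyMatrix:
    """Co-information per (feature, voxel, time) with max-statistic threshold.

    ``coefs`` should contain only the diagnostic features (the first axis of
    the result).  The permutation null shuffles decisions across trials
    (features and activity fixed) and takes the 95th percentile of the
    per-permutation maximum over the whole 3D matrix.
    """
    C = np.asarray(coefs.coefs, dtype=float)
    if C.ndim != 2 or C.shape[1] == 0:
        raise ValueError("no feature coefficients supplied")
    sel, idx, ncls = _classes_and_index(decisions, contrast)
    C = C[sel]
    n, k = C.shape
    if activity.n_trials != np.asarray(decisions).shape[0]:
        raise ValueError("activity and decisions are not trial-aligned")
    amp, grad = activity.channels_flat()
    Zc = _gauss.gaussianize(C)
    Za = _gauss.gaussianize(amp[sel])
    Zb = _gauss.gaussianize(grad[sel])
    mi_fm = _gauss.mi_bivar_map(Zc, Za, Zb, bias_correct=bias_correct)
    mi_cond = _gauss.mi_bivar_map_conditional(Zc, Za, Zb, idx, ncls, bias_correct)
    red = mi_fm - mi_cond
    rng = np.random.default_rng() if rng is None else rng
    if n_perm:
        perm_index = np.stack([rng.permutation(n) for _ in range(n_perm)])
        perm_max = _gauss.redundancy_perm_max(
            Zc, Za, Zb, idx, ncls, perm_index, mi_fm, bias_correct
        )
        thr = float(np.percentile(perm_max, alpha_percentile))
    else:
        thr = float("inf")
    red = red.reshape(k, activity.n_voxels, activity.n_times)
    return RedundancyMatrix(
        red, thr, np.asarray(activity.times_ms), contrast,
        feature_labels or ["diagnostic"] * k,
    )


def decision_specific_redundancy(
    coefs: FeatureCoefficients,
    activity: SourceActivity,
    decisions: np.ndarray,
    contrast: str,
    n_perm: int = 200,
    alpha_percentile: float = 95.0,
    rng: np.random.Generator | None = None,
    bias_correct: bool = True,
    feature_labels: list | None = None,
) -> RedundancyMatrix:
    """Redundancy restricted to one two-class behavioral contrast.

    ``contrast`` must be 'nuns_vs_dk' or 'voltaire_vs_dk'; the trials of the
    excluded percept are dropped before any computation.
    """
    if contrast == "three_way":
        raise ValueError("use redundancy_matrix for the three-way contrast")
    return redundancy_matrix(
        coefs, activity, decisions, n_perm, alpha_percentile, rng, contrast,
        bias_correct, feature_labels,
    )


def default_complexity_windows(
    start_ms: float = 120.0, stop_ms: float = 220.0, n_windows: int = 5
) -> np.ndarray:
    """Contiguous equal-width windows spanning the extended N/M170 course."""
    edges = np.linspace(start_ms, stop_ms, n_windows + 1)
    return np.column_stack([edges[:-1], edges[1:]])


def representational_complexity(
    red: RedundancyMatrix, windows: np.ndarray | None = None
) -> ComplexityMap:
    """Count distinct significantly redundant features per voxel and window.

    A feature counts in a window when it has at least one significant cell at
    a time point t with lo <= t < hi (the final window includes its upper
    bound).
    """
    windows = default_complexity_windows() if windows is None else np.asarray(windows, float)
    times = np.asarray(red.times_ms, dtype=float)
    if windows.min() < times[0] - 1e-9 or windows.max() > times[-1] + 1e-9:
        raise ValueError(
            f"windows [{windows.min()}, {windows.max()}] outside the matrix time "
            f"span [{times[0]}, {times[-1]}]"
        )
    sig = red.significant  # (k, V, T)
    nv = sig.shape[1]
    counts = np.zeros((nv, len(windows)), dtype=int)
    for w, (lo, hi) in enumerate(windows):
        last = w == len(windows) - 1
        tsel = (times >= lo) & ((times <= hi) if last else (times < hi))
        if tsel.any():
            counts[:, w] = sig[:, :, tsel].any(axis=2).sum(axis=0)
    return ComplexityMap(counts, windows)


def median_complexity(maps: list) -> ComplexityMap:
    """Median complexity count across observers (same voxel grid and windows)."""
    if not maps:
        raise ValueError("no complexity maps supplied")
    stack = np.stack([m.counts for m in maps])
    return ComplexityMap(np.median(stack, axis=0), maps[0].window_bounds_ms)


def decision_mi(
    activity: SourceActivity,
    decisions: np.ndarray,
    n_perm: int = 200,
    alpha_percentile: float = 95.0,
    rng: np.random.Generator | None = None,
    bias_correct: bool = True,
):
    """MI <voxel activity; three-way decision> per voxel and time, thresholded.

    Returns (mi_map (V, T), threshold).  Mixed continuous-discrete estimator
    on the bivariate (amplitude, gradient); FWER by decision shuffling.
    """
    decisions = np.asarray(decisions)
    classes = np.unique(decisions)
    if classes.size < 2:
        raise ValueError("need at least two decision classes")
    _, idx = np.unique(decisions, return_inverse=True)
    ncls = classes.size
    counts = np.bincount(idx)
    if counts.min() < 4:
        raise ValueError(f"smallest class has {counts.min()} trials (< 4)")
    amp, grad = activity.channels_flat()
    if np.ptp(amp, axis=0).max() == 0:
        raise ValueError("activity is constant across trials; MI undefined")
    Za = _gauss.gaussianize(amp)
    Zb = _gauss.gaussianize(grad)
    mi = _gauss.mi_bivar_discrete_map(Za, Zb, idx, ncls, bias_correct)
    rng = np.random.default_rng() if rng is None else rng
    if n_perm:
        perm_index = np.stack([rng.permutation(idx.size) for _ in range(n_perm)])
        perm_max = _gauss.discrete_mi_perm_max(
            Za, Zb, idx, ncls, perm_index, bias_correct
        )
        thr = float(np.percentile(perm_max, alpha_percentile))
    else:
        thr = float("inf")
    return mi.reshape(activity.n_voxels, activity.n_times), thr
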