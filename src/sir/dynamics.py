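"""Representation dynamics: wavefronts, divergence, and the occipital junction.

From a representation matrix, each voxel gets a time course of maximum MI
over the diagnostic (or nondiagnostic) feature subset in fixed time windows.
A voxel's representation onset is the first significant window, its offset
the last, duration = offset - onset.  The spatial progression of onsets and
durations against distance from the earliest-onset voxel is summarized by
robust regressions; the divergence of the diagnostic and nondiagnostic voxel
patterns is the de-meaned dot product per window against a shuffle null; the
junction is the latest offset among the farthest-traveling nondiagnostic
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import RepresentationMatrix

__all__ = [
    "MaxRepresentationCourse",
    "DivergenceProfile",
    "WavefrontRegressions",
    "max_course",
    "divergence",
    "wavefront_regressions",
    "junction",
]


@dataclass
class MaxRepresentationCourse:
    """Per-voxel max-MI course over a feature subset, in fixed time windows.

    Onset is the start of the first window whose max MI exceeds the
    representation threshold; offset is the end of the last such window
    (so an isolated significant window has duration == window width).
    Voxels never significant carry NaN onset/offset/duration.
    """

    curve: np.ndarray  # (n_voxels, n_windows)
    window_starts_ms: np.ndarray
    window_ms: float
    threshold: float
    subset: str
    onset_ms: np.ndarray = field(init=False)
    offset_ms: np.ndarray = field(init=False)

    def __post_init__(self):
        sig = self.curve > self.threshold
        nv, nw = sig.shape
        any_sig = sig.any(axis=1)
        first = np.argmax(sig, axis=1)
        last = nw - 1 - np.argmax(sig[:, ::-1], axis=1)
        self.onset_ms = np.where(any_sig, self.window_starts_ms[first], np.nan)
        self.offset_ms = np.where(
            any_sig, self.window_starts_ms[last] + self.window_ms, np.nan
        )

    @property
    def duration_ms(self) -> np.ndarray:
        return self.offset_ms - self.onset_ms


@dataclass
class DivergenceProfile:
    similarity: np.ndarray  # per window
    null_low: np.ndarray
    null_high: np.ndarray
    window_starts_ms: np.ndarray

    @property
    def significant(self) -> np.ndarray:
        return (self.similarity < self.null_low) | (self.similarity > self.null_high)


@dataclass
class WavefrontRegressions:
    onset_slope: float
    onset_intercept: float
    onset_slope_se: float
    onset_slope_p: float
    duration_slope: float
    duration_intercept: float
    duration_slope_se: float
    duration_slope_p: float
    excluded_fraction: float
    origin_voxel: int
    distances_mm: np.ndarray
    included: np.ndarray  # boolean over the voxels with defined onsets


def max_course(
    rep: RepresentationMatrix,
    subset: str,
    window_ms: float = 10.0,
    threshold: float | None = None,
) -> MaxRepresentationCourse:
    """Max unthresholded MI over a feature subset per voxel and time window.

    ``subset`` is 'diagnostic' (both percepts), 'nondiagnostic', or a
    specific label from the basis.
    """
    labels = np.asarray(rep.feature_labels)
    if subset == "diagnostic":
        sel = np.isin(labels, ["diagnostic_nuns", "diagnostic_voltaire"])
    else:
        sel = labels == subset
    if not sel.any():
        raise ValueError(f"feature subset {subset!r} is empty")
    mi = rep.mi[sel]  # (kf, V, T)
    times = np.asarray(rep.times_ms, dtype=float)
    t0 = times[0]
    span = times[-1] - t0
    n_windows = max(int(np.ceil((span + 1e-9) / window_ms)), 1)
    starts = t0 + window_ms * np.arange(n_windows)
    widx = np.minimum(((times - t0) / window_ms).astype(int), n_windows - 1)
    curve = np.zeros((mi.shape[1], n_windows))
    vox_max = mi.max(axis=0)  # (V, T)
    for w in range(n_windows):
        cols = widx == w
        curve[:, w] = vox_max[:, cols].max(axis=1) if cols.any() else 0.0
    return MaxRepresentationCourse(curve, starts, window_ms, rep.fwer_threshold, subset)


def divergence(
    diag: MaxRepresentationCourse,
    nondiag: MaxRepresentationCourse,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    low_pct: float = 0.625,
    high_pct: float = 99.9375,
    joint_shuffle: bool = False,
) -> DivergenceProfile:
    """Windowwise de-meaned dot-product similarity of the two voxel patterns.

    The null shuffles entries across the voxel dimension of both vectors
    (independently by default; ``joint_shuffle`` applies one permutation to
    both).  Default percentile bounds implement a Bonferroni-corrected
    two-tailed test at 0.05 over 40 windows.
    """
    if diag.curve.shape != nondiag.curve.shape:
        raise ValueError("courses must share voxel set and windows")
    rng = np.random.default_rng() if rng is None else rng
    nv, nw = diag.curve.shape
    sim = np.empty(nw)
    lo = np.empty(nw)
    hi = np.empty(nw)
    for w in range(nw):
        u = diag.curve[:, w]
        v = nondiag.curve[:, w]
        sim[w] = _demeaned_dot(u, v)
        if not (u.any() or v.any()):
            sim[w] = 0.0
        null = np.empty(n_boot)
        for b in range(n_boot):
            pu = rng.permutation(nv)
            pv = pu if joint_shuffle else rng.permutation(nv)
            null[b] = _demeaned_dot(u[pu], v[pv])
        lo[w] = np.percentile(null, low_pct)
        hi[w] = np.percentile(null, high_pct)
    return DivergenceProfile(sim, lo, hi, diag.window_starts_ms)


def _demeaned_dot(u: np.ndarray, v: np.ndarray) -> float:
    return float((u - u.mean()) @ (v - v.mean()))


def wavefront_regressions(
    course: MaxRepresentationCourse,
    voxel_coords: np.ndarray,
    outlier_sd: float = 3.0,
    min_voxels: int = 10,
) -> WavefrontRegressions:
    """Robust regressions of onset and duration against distance from origin.

    Origin is the earliest-onset voxel (first index on ties).  Voxels whose
    onset lies more than ``outlier_sd`` standard deviations from the median
    onset are excluded.  Fits are iteratively reweighted least squares with a
    Tukey bisquare weight; slope p-values from the asymptotic normal
    approximation of the IRLS estimate.
    """
    import statsmodels.api as sm

    coords = np.asarray(voxel_coords, dtype=float)
    onset = course.onset_ms
    dur = course.duration_ms
    defined = np.isfinite(onset)
    if defined.sum() < min_voxels:
        raise ValueError(
            f"only {int(defined.sum())} voxels with defined onsets (< {min_voxels})"
        )
    onset_d = onset[defined]
    dur_d = dur[defined]
    coords_d = coords[defined]
    sd = onset_d.std()
    med = np.median(onset_d)
    keep = np.abs(onset_d - med) <= outlier_sd * sd if sd > 0 else np.ones_like(onset_d, bool)
    if keep.sum() < min_voxels:
        raise ValueError("outlier exclusion left too few voxels")
    origin_local = int(np.argmin(onset_d[keep]))
    origin_voxel = int(np.flatnonzero(defined)[np.flatnonzero(keep)[origin_local]])
    dist = np.linalg.norm(coords_d - coords[origin_voxel], axis=1)
    x = dist[keep]
    if np.ptp(x) == 0:
        raise ValueError("zero-variance distances; regression ill-posed")
    if np.ptp(onset_d[keep]) == 0:
        raise ValueError("all onsets identical; regression ill-posed")

    def _rlm(y):
        X = sm.add_constant(x)
        fit = sm.RLM(y, X, M=sm.robust.norms.TukeyBiweight()).fit()
        from scipy.stats import norm

        slope, se = float(fit.params[1]), float(fit.bse[1])
        p = float(2 * norm.sf(abs(slope / se))) if se > 0 else 0.0
        return slope, float(fit.params[0]), se, p

    os_, oi, ose, op = _rlm(onset_d[keep])
    ds, di, dse, dp = _rlm(dur_d[keep])
    return WavefrontRegressions(
        os_, oi, ose, op, ds, di, dse, dp,
        excluded_fraction=float(1.0 - keep.sum() / defined.sum()),
        origin_voxel=origin_voxel,
        distances_mm=dist,
        included=keep,
    )


def junction(
    course_nondiag: MaxRepresentationCourse,
    distances_mm: np.ndarray,
    distance_percentile: float = 75.0,
):
    """Spatio-temporal junction from the farthest nondiagnostic voxels.

    Returns (far_voxel_indices, temporal_marker_ms): voxels with distance
    strictly above the 75th percentile (linear-interpolation percentile) of
    distances of all nondiagnostic voxels with defined offsets, and the
    latest representation offset among them.  With a single qualifying voxel
    set (e.g. one voxel total) that voxel is the junction.
    """
    offs = course_nondiag.offset_ms
    defined = np.isfinite(offs)
    if not defined.any():
        raise ValueError("no nondiagnostic voxels with defined offsets")
    distances_mm = np.asarray(distances_mm, dtype=float)
    if distances_mm.shape[0] != offs.shape[0]:
        raise ValueError("distances must align with the course's voxels")
    idx = np.flatnonzero(defined)
    if idx.size == 1:
        return idx, float(offs[idx[0]])
    d = distances_mm[idx]
    cut = np.percentile(d, distance_percentile)
    far = idx[d > cut]
    if far.size == 0:  # all distances equal: fall back to the full set
        far = idx
    return far, float(np.nanmax(offs[far]))
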