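"""Brain features: NMF basis from MI images, coefficients, representation matrix.

The full per-pixel coupling between stimulus samples and every voxel/time cell
is intractable, so the stimulus features represented in neural activity are
derived in three steps: (1) pixelwise MI images against a reduced activity
matrix (a small number of components x coarse time grid); (2) non-negative
matrix factorization of the vectorized MI images into a small basis of
pixel-weight patterns ("brain features"), thresholded at 15% of each
feature's max and L2-normalized; (3) per-trial feature coefficients (dot
product of the trial's mask stack with each feature) related by
Gaussian-copula MI to the bivariate (amplitude, gradient) activity of every
voxel and time point, familywise-thresholded by permutation maximum
statistics — the representation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _gauss
from .core import DONT_KNOW, NUNS, VOLTAIRE, SourceActivity

__all__ = [
    "MIImageStack",
    "BrainFeatureBasis",
    "FeatureCoefficients",
    "RepresentationMatrix",
    "reduce_activity_pca",
    "reduced_mi_images",
    "nmf_basis",
    "select_nmf_k",
    "feature_coefficients",
    "representation_matrix",
    "classify_features",
    "kmeans_basis",
]

FEATURE_LABELS = ("diagnostic_nuns", "diagnostic_voltaire", "nondiagnostic", "unclassified")


@dataclass
class MIImageStack:
    """Vectorized MI images: (n_cells, n_pixels*n_bands), entries >= 0."""

    images: np.ndarray
    cell_index: list  # (component_id, time_id) per row
    image_shape: tuple  # (size, size, n_bands)


@dataclass
class BrainFeatureBasis:
    """L2-normalized nonnegative pixel-weight images, one row per feature."""

    features: np.ndarray  # (k, n_pixels*n_bands)
    image_shape: tuple
    labels: list = field(default_factory=list)
    reconstruction_error: float = float("nan")
    threshold_frac: float = 0.15

    @property
    def k(self) -> int:
        return self.features.shape[0]


@dataclass
class FeatureCoefficients:
    """Per-trial feature visibility scalars: (n_trials, k)."""

    coefs: np.ndarray


@dataclass
class RepresentationMatrix:
    """Feature x voxel x time MI (bits) with a maximum-statistic threshold."""

    mi: np.ndarray  # (k, n_voxels, n_times)
    fwer_threshold: float
    times_ms: np.ndarray
    feature_labels: list = field(default_factory=list)

    @property
    def significant(self) -> np.ndarray:
        return self.mi > self.fwer_threshold


def reduce_activity_pca(
    activity: SourceActivity, n_components: int = 60, n_times: int = 75
) -> np.ndarray:
    """Linear reduction of the amplitude channel to (n_trials, C, n_times).

    PCA across voxels (fit on trial-time samples), time axis subsampled to
    ``n_times`` points.  Any linear reduction works for the MI-image step; an
    ICA decomposition can be supplied instead by the caller.
    """
    from sklearn.decomposition import PCA

    amp = activity.data[..., 0]  # (n, V, T)
    n, V, T = amp.shape
    n_components = min(n_components, V, n * T)
    x = amp.transpose(0, 2, 1).reshape(n * T, V)
    pca = PCA(n_components=n_components, svd_solver="randomized", random_state=0)
    comp = pca.fit_transform(x).reshape(n, T, n_components).transpose(0, 2, 1)
    t_idx = np.unique(np.linspace(0, T - 1, min(n_times, T)).astype(int))
    return comp[:, :, t_idx]


def reduced_mi_images(
    trial_masks: np.ndarray,
    reduced_activity: np.ndarray,
    bias_correct: bool = True,
) -> MIImageStack:
    """Pixelwise MI image for every (component, reduced-time) activity cell.

    ``trial_masks``: (n_trials, size, size, n_bands) visibility masks;
    ``reduced_activity``: (n_trials, C, Tr).  Returns C*Tr vectorized images
    of per-pixel Gaussian-copula MI, floored at 0 (NMF input must be
    nonnegative; small negative bias-corrected estimates are noise).
    """
    m = np.asarray(trial_masks)
    if m.ndim != 4:
        raise ValueError(f"expected (n, size, size, bands) masks, got {m.shape}")
    n = m.shape[0]
    act = np.asarray(reduced_activity, dtype=float)
    if act.shape[0] != n:
        raise ValueError(
            f"trial mismatch: {n} mask trials vs {act.shape[0]} activity trials"
        )
    image_shape = m.shape[1:]
    Zm = _gauss.gaussianize(m.reshape(n, -1))
    Zm -= Zm.mean(axis=0, keepdims=True)  # center once; reused for every cell
    vz = np.einsum("ij,ij->j", Zm, Zm)
    okz = vz > 1e-12
    from .infotheory import gaussian_mi_bias

    bias = gaussian_mi_bias(n, 1, 1) if bias_correct else 0.0
    C, Tr = act.shape[1], act.shape[2]
    images = np.empty((C * Tr, Zm.shape[1]))
    cell_index = []
    row = 0
    for c in range(C):
        Za = _gauss.gaussianize(act[:, c, :])  # (n, Tr)
        Za -= Za.mean(axis=0, keepdims=True)
        va = np.einsum("ij,ij->j", Za, Za)
        cross = Zm.T @ Za  # (pixels, Tr)
        for t in range(Tr):
            ok = okz & (va[t] > 1e-12)
            r2 = np.zeros(Zm.shape[1])
            r2[ok] = np.clip(cross[ok, t] ** 2 / (vz[ok] * va[t]), 0.0, 1.0 - 1e-12)
            images[row] = np.where(ok, -0.5 * np.log2(1.0 - r2) - bias, 0.0)
            cell_index.append((c, t))
            row += 1
    return MIImageStack(np.maximum(images, 0.0), cell_index, image_shape)


def select_nmf_k(
    stack: MIImageStack,
    k_max: int = 25,
    min_improvement: float = 0.01,
    rng: np.random.Generator | None = None,
) -> int:
    """Elbow rule: smallest k whose relative error improvement drops below 1%."""
    seed = int((np.random.default_rng() if rng is None else rng).integers(2**31))
    prev = None
    for k in range(1, k_max + 1):
        err = _fit_nmf(stack.images, k, seed)[2]
        if prev is not None and (prev - err) / max(prev, 1e-30) < min_improvement:
            return k - 1
        prev = err
    return k_max


def _fit_nmf(X: np.ndarray, k: int, seed: int, max_iter: int = 400):
    from sklearn.decomposition import NMF

    model = NMF(
        n_components=k,
        init="nndsvda",
        solver="cd",
        max_iter=max_iter,
        random_state=seed,
        tol=1e-5,
    )
    W = model.fit_transform(X)
    return W, model.components_, float(model.reconstruction_err_)


def nmf_basis(
    stack: MIImageStack,
    k: int,
    rng: np.random.Generator | None = None,
    threshold_frac: float = 0.15,
    max_iter: int = 400,
) -> BrainFeatureBasis:
    """NMF of the MI-image stack -> thresholded, L2-normalized brain features.

    Pixels below ``threshold_frac`` of each feature's maximum (across all SF
    bands) are zeroed before normalization.
    """
    X = stack.images
    if k <= 0:
        raise ValueError(f"k must be positive, got {k}")
    if k > min(X.shape):
        raise ValueError(f"k={k} exceeds min(stack shape)={min(X.shape)}")
    if not np.any(X > 0):
        raise ValueError("MI image stack is all zero; nothing to factorize")
    if np.any(X < 0):
        raise ValueError("MI image stack must be nonnegative")
    seed = int((np.random.default_rng() if rng is None else rng).integers(2**31))
    _, H, err = _fit_nmf(X, k, seed, max_iter)
    feats = H.copy()
    for i in range(k):
        mx = feats[i].max()
        if mx <= 0:
            continue
        feats[i][feats[i] < threshold_frac * mx] = 0.0
        feats[i] /= np.linalg.norm(feats[i])
    return BrainFeatureBasis(
        feats, stack.image_shape, ["unclassified"] * k, err, threshold_frac
    )


def feature_coefficients(
    trial_masks: np.ndarray, basis: BrainFeatureBasis
) -> FeatureCoefficients:
    """Spatial filtering: coefficient[t, f] = <mask_t, feature_f>."""
    m = np.asarray(trial_masks)
    flat = m.reshape(m.shape[0], -1) if m.ndim == 4 else m
    if flat.shape[1] != basis.features.shape[1]:
        raise ValueError(
            f"mask dimension {flat.shape[1]} != feature dimension "
            f"{basis.features.shape[1]}"
        )
    return FeatureCoefficients(flat.astype(float) @ basis.features.T)


def representation_matrix(
    coefs: FeatureCoefficients,
    activity: SourceActivity,
    n_perm: int = 200,
    alpha_percentile: float = 95.0,
    rng: np.random.Generator | None = None,
    bias_correct: bool = True,
    feature_labels: list | None = None,
) -> RepresentationMatrix:
    """GCMI <feature coefficient; (amplitude, gradient)> per (feature, voxel, time).

    The FWER threshold is the ``alpha_percentile`` of the maximum MI over the
    whole 3D matrix across ``n_perm`` random reassignments of coefficients to
    trials (one shared permutation per iteration across features).
    """
    C = np.asarray(coefs.coefs, dtype=float)
    n, k = C.shape
    if activity.n_trials != n:
        raise ValueError(f"trial mismatch: {n} coefficients vs {activity.n_trials} trials")
    amp, grad = activity.channels_flat()
    Zc = _gauss.gaussianize(C)
    Za = _gauss.gaussianize(amp)
    Zb = _gauss.gaussianize(grad)
    rng = np.random.default_rng() if rng is None else rng
    perm_index = np.stack([rng.permutation(n) for _ in range(n_perm)]) if n_perm else None
    if perm_index is None:
        mi = _gauss.mi_bivar_map(Zc, Za, Zb, bias_correct=bias_correct)
        thr = float("inf")
    else:
        mi, perm_max = _gauss.mi_bivar_map(Zc, Za, Zb, perm_index, bias_correct)
        thr = float(np.percentile(perm_max, alpha_percentile))
    mi = mi.reshape(k, activity.n_voxels, activity.n_times)
    return RepresentationMatrix(
        mi, thr, np.asarray(activity.times_ms), feature_labels or ["unclassified"] * k
    )


def classify_features(
    coefs: FeatureCoefficients,
    decisions: np.ndarray,
    hi_percentile: float = 75.0,
    lo_percentile: float = 25.0,
) -> list:
    """Label each feature diagnostic ("nuns"/"voltaire") or nondiagnostic.

    Per feature, three MI values: <coef; nuns vs dk> on nuns+dk trials,
    <coef; voltaire vs dk> on voltaire+dk trials, and <coef; all three>.
    A feature is diagnostic of a percept when its two-class MI strictly
    exceeds the 75th percentile of that MI's distribution over features, and
    nondiagnostic when its three-class MI falls strictly below the 25th
    percentile.  Ties at a percentile stay unclassified; if both rules fire,
    diagnostic wins (with a warning).
    """
    import warnings

    from .infotheory import mi_gcd

    C = np.asarray(coefs.coefs, dtype=float)
    n, k = C.shape
    if k < 4:
        raise ValueError(f"percentile rule needs >= 4 features, got {k}")
    decisions = np.asarray(decisions)
    if np.unique(decisions).size < 3:
        raise ValueError("all three decision classes must be present")
    sel_n = (decisions == NUNS) | (decisions == DONT_KNOW)
    sel_v = (decisions == VOLTAIRE) | (decisions == DONT_KNOW)
    mi_n = np.array([mi_gcd(C[sel_n, f], decisions[sel_n]).value for f in range(k)])
    mi_v = np.array([mi_gcd(C[sel_v, f], decisions[sel_v]).value for f in range(k)])
    mi_3 = np.array([mi_gcd(C[:, f], decisions).value for f in range(k)])
    hi_n = np.percentile(mi_n, hi_percentile)
    hi_v = np.percentile(mi_v, hi_percentile)
    lo_3 = np.percentile(mi_3, lo_percentile)
    labels = []
    for f in range(k):
        diag_n = mi_n[f] > hi_n
        diag_v = mi_v[f] > hi_v
        nondiag = mi_3[f] < lo_3
        if (diag_n or diag_v) and nondiag:
            warnings.warn(
                f"feature {f} satisfies both diagnostic and nondiagnostic rules; "
                "diagnostic takes precedence"
            )
            nondiag = False
        if diag_n and diag_v:
            # stronger contrast wins
            labels.append(
                "diagnostic_nuns" if mi_n[f] - hi_n >= mi_v[f] - hi_v else "diagnostic_voltaire"
            )
        elif diag_n:
            labels.append("diagnostic_nuns")
        elif diag_v:
            labels.append("diagnostic_voltaire")
        elif nondiag:
            labels.append("nondiagnostic")
        else:
            labels.append("unclassified")
    return labels


def kmeans_basis(
    all_features: np.ndarray,
    k: int = 25,
    n_restarts: int = 1000,
    rng: np.random.Generator | None = None,
):
    """Cosine k-means over pooled observer features -> (assignments, centroids).

    Rows are L2-normalized, so Euclidean k-means on the unit sphere orders
    solutions identically to cosine dissimilarity; best of ``n_restarts``
    random initializations.  Centroids are returned re-normalized.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(all_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < k:
        raise ValueError(f"need at least k={k} feature rows, got shape {X.shape}")
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    Xn = X / norms
    seed = int((np.random.default_rng() if rng is None else rng).integers(2**31))
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(Xn)
    cent = km.cluster_centers_
    cn = np.linalg.norm(cent, axis=1, keepdims=True)
    cn[cn == 0] = 1.0
    return km.labels_, cent / cn
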