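"""Vectorized Gaussian-copula MI kernels.

The public estimators in :mod:`sir.infotheory` are scalar and audited; the
mapping stages (MI images over 20,480 pixels, representation matrices over
voxels x time, permutation nulls) need the same quantities over 1e4-1e6
columns at once.  These kernels compute them from sufficient statistics via
matrix products.  They operate on already rank-gaussianized scores; columns
with zero variance yield MI exactly 0 (the convention for never-visible
pixels / flat channels).

Everything here is deterministic given its inputs; permutations are supplied
by the caller as index arrays.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtri
from scipy.stats import rankdata

from .infotheory import gaussian_mi_bias, _ent_bias_ln

_EPS = 1e-12
_LN2 = np.log(2.0)


def gaussianize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Rank-gaussianize along ``axis`` (average ranks, Phi^-1((r-0.5)/n)).

    Constant columns map to all-zero scores (MI contributions vanish), unlike
    the strict scalar API which rejects them — mask pixels that are never
    revealed are a normal occurrence in mapping stages.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.shape[axis]
    r = rankdata(x, method="average", axis=axis)
    return ndtri((r - 0.5) / n)


def _center(z: np.ndarray) -> np.ndarray:
    return z - z.mean(axis=0, keepdims=True)


def mi_scalar_map(zc: np.ndarray, Z: np.ndarray, bias_correct: bool = True) -> np.ndarray:
    """MI (bits) between one gaussianized scalar and each column of Z.

    zc: (n,) scores; Z: (n, m) scores.  Returns (m,).
    """
    n = zc.shape[0]
    c = _center(zc)
    Zc = _center(Z)
    vc = c @ c
    vz = np.einsum("ij,ij->j", Zc, Zc)
    cz = Zc.T @ c
    denom = vc * vz
    r2 = np.zeros_like(vz)
    ok = denom > _EPS
    r2[ok] = np.clip(cz[ok] ** 2 / denom[ok], 0.0, 1.0 - 1e-12)
    mi = -0.5 * np.log2(1.0 - r2)
    if bias_correct:
        mi = np.where(ok, mi - gaussian_mi_bias(n, 1, 1), 0.0)
    else:
        mi = np.where(ok, mi, 0.0)
    return mi


def _cov_terms(A: np.ndarray, B: np.ndarray):
    """Per-column (co)variance terms for a bivariate variable (centered inputs)."""
    vaa = np.einsum("ij,ij->j", A, A)
    vbb = np.einsum("ij,ij->j", B, B)
    vab = np.einsum("ij,ij->j", A, B)
    return vaa, vbb, vab


def mi_bivar_map(
    C: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    perm_index: np.ndarray | None = None,
    bias_correct: bool = True,
):
    """MI (bits) between each column of C and the bivariate (A, B) per column.

    C: (n, k) gaussianized coefficients; A, B: (n, m) gaussianized activity
    channels (e.g. amplitude and temporal gradient flattened over voxel/time).
    Returns ``mi`` of shape (k, m).  If ``perm_index`` (P, n) is given, also
    returns ``perm_max`` of shape (P,): the max MI over (k, m) per permuted
    coefficient assignment — the maximum-statistic null.
    """
    n, k = C.shape
    Cc = _center(C)
    Ac, Bc = _center(A), _center(B)
    vaa, vbb, vab = _cov_terms(Ac, Bc)
    det2 = vaa * vbb - vab**2
    vcc = np.einsum("ij,ij->j", Cc, Cc)  # (k,)
    bias = gaussian_mi_bias(n, 1, 2) if bias_correct else 0.0

    def _mi_from_cross(vca: np.ndarray, vcb: np.ndarray) -> np.ndarray:
        # vca, vcb: (k, m) cross terms; symmetric 3x3 determinant, order (c,a,b)
        det3 = (
            vcc[:, None] * det2[None, :]
            - vca**2 * vbb[None, :]
            + 2.0 * vca * vcb * vab[None, :]
            - vcb**2 * vaa[None, :]
        )
        num = vcc[:, None] * det2[None, :]
        ok = (num > _EPS) & (det3 > _EPS)
        mi = np.zeros_like(det3)
        ratio = np.ones_like(det3)
        ratio[ok] = np.clip(det3[ok] / num[ok], 1e-15, 1.0)
        mi[ok] = -0.5 * np.log2(ratio[ok]) - bias
        return mi

    vca = Cc.T @ Ac  # (k, m)
    vcb = Cc.T @ Bc
    mi = _mi_from_cross(vca, vcb)
    if perm_index is None:
        return mi
    perm_max = np.empty(perm_index.shape[0])
    for p, idx in enumerate(perm_index):
        Cp = Cc[idx]
        perm_max[p] = _mi_from_cross(Cp.T @ Ac, Cp.T @ Bc).max()
    return mi, perm_max


def _logdet2(vaa, vbb, vab):
    det = vaa * vbb - vab**2
    out = np.full(det.shape, -np.inf)
    ok = det > _EPS
    out[ok] = np.log(det[ok])
    return out, ok


def mi_bivar_discrete_map(
    A: np.ndarray,
    B: np.ndarray,
    class_idx: np.ndarray,
    n_classes: int,
    bias_correct: bool = True,
) -> np.ndarray:
    """MI (bits) between the bivariate (A, B) per column and a discrete label.

    Model-based: H(X) - sum_c p(c) H(X|c), Gaussian entropies per column.
    Returns (m,).
    """
    n = A.shape[0]
    Ac, Bc = _center(A), _center(B)
    ld_full, ok_full = _logdet2(*_cov_terms(Ac, Bc))
    # ddof handling: use sums of squares; the (m-1) normalizations cancel in
    # entropy differences only if matched, so carry them explicitly.
    ld_full = ld_full - 2.0 * np.log(n - 1)
    h_full = 0.5 * ld_full
    if bias_correct:
        h_full = h_full - _ent_bias_ln(n, 2)
    h_cond = np.zeros(A.shape[1])
    ok = ok_full.copy()
    for c in range(n_classes):
        sel = class_idx == c
        m = int(sel.sum())
        Acl, Bcl = _center(A[sel]), _center(B[sel])
        ld, okc = _logdet2(*_cov_terms(Acl, Bcl))
        ld = ld - 2.0 * np.log(m - 1)
        h = 0.5 * ld
        if bias_correct:
            h = h - _ent_bias_ln(m, 2)
        h_cond += (m / n) * h
        ok &= okc
    mi = np.where(ok, (h_full - h_cond) / _LN2, 0.0)
    return mi


def mi_bivar_map_conditional(
    C: np.ndarray,
    A: np.ndarray,
    B: np.ndarray,
    class_idx: np.ndarray,
    n_classes: int,
    bias_correct: bool = True,
) -> np.ndarray:
    """Class-weighted conditional MI I(C; (A,B) | class) per (k, m) cell."""
    n = C.shape[0]
    out = np.zeros((C.shape[1], A.shape[1]))
    for c in range(n_classes):
        sel = class_idx == c
        m = int(sel.sum())
        mi_c = mi_bivar_map(C[sel], A[sel], B[sel], bias_correct=bias_correct)
        out += (m / n) * mi_c
    return out


def _perm_class_indicators(class_idx: np.ndarray, n_classes: int, perm_index: np.ndarray):
    """Per-class 0/1 membership matrices (n, P) for a stack of permutations."""
    labels = class_idx[perm_index.T]  # (n, P)
    return [(labels == c).astype(np.float64) for c in range(n_classes)]


def redundancy_perm_max(
    Zc: np.ndarray,
    Za: np.ndarray,
    Zb: np.ndarray,
    class_idx: np.ndarray,
    n_classes: int,
    perm_index: np.ndarray,
    mi_fm: np.ndarray,
    bias_correct: bool = True,
) -> np.ndarray:
    """Max co-information over (feature, column) per decision permutation.

    Batched sufficient-statistic computation: per-class trial sums of the
    activity moments and coefficient cross-moments are matrix products with
    0/1 membership matrices, so all permutations are processed through BLAS.
    Class sizes are permutation-invariant, hence so are the bias terms.
    """
    n, k = Zc.shape
    m = Za.shape[1]
    P = perm_index.shape[0]
    Y = _perm_class_indicators(class_idx, n_classes, perm_index)
    counts = [int(Yc[:, 0].sum()) for Yc in Y]
    # class-dependent, feature-independent activity moments: (m, P) each
    stats = []
    for Yc in Y:
        Sa = Za.T @ Yc
        Sb = Zb.T @ Yc
        Saa = (Za**2).T @ Yc
        Sbb = (Zb**2).T @ Yc
        Sab = (Za * Zb).T @ Yc
        stats.append((Sa, Sb, Saa, Sbb, Sab))
    perm_max = np.full(P, -np.inf)
    for f in range(k):
        c = Zc[:, f]
        cA = (c[:, None] * Za)
        cB = (c[:, None] * Zb)
        cond = np.zeros((m, P))
        ok_all = np.ones((m, P), dtype=bool)
        for cls, (Yc, (Sa, Sb, Saa, Sbb, Sab)) in enumerate(zip(Y, stats)):
            nc = counts[cls]
            Sc = c @ Yc  # (P,)
            Scc = (c**2) @ Yc
            Sca = cA.T @ Yc
            Scb = cB.T @ Yc
            vaa = Saa - Sa**2 / nc
            vbb = Sbb - Sb**2 / nc
            vab = Sab - Sa * Sb / nc
            vca = Sca - Sc[None, :] * Sa / nc
            vcb = Scb - Sc[None, :] * Sb / nc
            vcc = (Scc - Sc**2 / nc)[None, :]
            det2 = vaa * vbb - vab**2
            det3 = (
                vcc * det2 - vca**2 * vbb + 2.0 * vca * vcb * vab - vcb**2 * vaa
            )
            num = vcc * det2
            ok = (num > _EPS) & (det3 > _EPS)
            ok_all &= ok
            ratio = np.where(ok, np.clip(det3 / np.maximum(num, _EPS), 1e-15, 1.0), 1.0)
            bias = gaussian_mi_bias(nc, 1, 2) if bias_correct else 0.0
            mi_c = np.where(ok, -0.5 * np.log2(ratio) - bias, 0.0)
            cond += (nc / n) * mi_c
        red = np.where(ok_all, mi_fm[f][:, None] - cond, 0.0)
        perm_max = np.maximum(perm_max, red.max(axis=0))
    return perm_max


def discrete_mi_perm_max(
    Za: np.ndarray,
    Zb: np.ndarray,
    class_idx: np.ndarray,
    n_classes: int,
    perm_index: np.ndarray,
    bias_correct: bool = True,
) -> np.ndarray:
    """Max of the <activity; decision> MI map per decision permutation."""
    n = Za.shape[0]
    P = perm_index.shape[0]
    Ac, Bc = _center(Za), _center(Zb)
    ld_full, ok_full = _logdet2(*_cov_terms(Ac, Bc))
    h_full = 0.5 * (ld_full - 2.0 * np.log(n - 1))
    if bias_correct:
        h_full = h_full - _ent_bias_ln(n, 2)
    Y = _perm_class_indicators(class_idx, n_classes, perm_index)
    h_cond = np.zeros((Za.shape[1], P))
    ok_all = np.tile(ok_full[:, None], (1, P))
    for Yc in Y:
        nc = int(Yc[:, 0].sum())
        Sa = Za.T @ Yc
        Sb = Zb.T @ Yc
        vaa = (Za**2).T @ Yc - Sa**2 / nc
        vbb = (Zb**2).T @ Yc - Sb**2 / nc
        vab = (Za * Zb).T @ Yc - Sa * Sb / nc
        det = vaa * vbb - vab**2
        ok = det > _EPS
        ok_all &= ok
        h = 0.5 * (np.log(np.maximum(det, _EPS)) - 2.0 * np.log(nc - 1))
        if bias_correct:
            h = h - _ent_bias_ln(nc, 2)
        h_cond += (nc / n) * h
    mi = np.where(ok_all, (h_full[:, None] - h_cond) / _LN2, 0.0)
    return mi.max(axis=0)


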