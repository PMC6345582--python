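"""Diagnostic features of behavior: pixelwise MI maps with FWER correction.

Per-pixel visibility (the downsampled bubble mask value) is binarized at 0.2
into "no to low" vs "low to full" visibility; plug-in MI between that bit and
the binary perceptual contrast ("nuns" vs "don't know", or "Voltaire" vs
"don't know", the third response excluded) maps the pixels whose visibility
drives the decision.  Significance is familywise-corrected with the method of
maximum statistics: the observed map is compared against the percentile of
the maximum MI over all pixels and bands under label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DECISION_LABELS, DONT_KNOW, NUNS, VOLTAIRE

__all__ = [
    "DECISION_LABELS",
    "NUNS",
    "VOLTAIRE",
    "DONT_KNOW",
    "CONTRASTS",
    "VisibilityTable",
    "DiagnosticMap",
    "binarize_visibility",
    "binary_mi_map",
    "diagnostic_map",
    "fwer_threshold",
]
CONTRASTS = {
    "nuns_vs_dk": (NUNS, DONT_KNOW),
    "voltaire_vs_dk": (VOLTAIRE, DONT_KNOW),
}


@dataclass
class VisibilityTable:
    """Binarized per-pixel visibility: (n_trials, n_pixels, n_bands) in {0,1}."""

    bits: np.ndarray
    threshold: float = 0.2


@dataclass
class DiagnosticMap:
    """Per-pixel MI (bits) for one behavioral contrast, with FWER threshold."""

    mi: np.ndarray  # (n_pixels, n_bands)
    fwer_threshold: float
    contrast: str
    n_trials: int = 0

    @property
    def significant(self) -> np.ndarray:
        return self.mi > self.fwer_threshold


def binarize_visibility(mask_stack: np.ndarray, threshold: float = 0.2) -> VisibilityTable:
    """Binarize mask visibility: bit = 1 iff value strictly exceeds threshold.

    A value exactly at the threshold falls in the "no to low visibility" bin
    (deterministic boundary convention).  ``mask_stack`` is
    (n_trials, size, size, n_bands) or already flattened
    (n_trials, n_pixels, n_bands).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    m = np.asarray(mask_stack)
    if m.ndim == 4:
        n, h, w, b = m.shape
        m = m.reshape(n, h * w, b)
    elif m.ndim != 3:
        raise ValueError(f"expected 3D or 4D mask stack, got shape {m.shape}")
    return VisibilityTable((m > threshold).astype(np.uint8), threshold)


def binary_mi_map(bits: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Plug-in MI (bits) between each binary column and a binary label.

    ``bits``: (n_trials, n_cols) in {0,1}; ``y``: (n_trials,) in {0,1} — or
    (n_trials, P) for P label columns at once (the permutation fast path),
    returning (n_cols, P).
    """
    bits = np.asarray(bits, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = bits.shape[0]
    squeeze = y.ndim == 1
    Y = y[:, None] if squeeze else y
    n1 = bits.sum(axis=0)  # (cols,)
    m1 = Y.sum(axis=0)  # (P,)
    n11 = bits.T @ Y  # (cols, P)
    n10 = n1[:, None] - n11
    n01 = m1[None, :] - n11
    n00 = n - n1[:, None] - m1[None, :] + n11
    table = np.stack([n00, n01, n10, n11], axis=0) / n  # (4, cols, P)
    px1 = n1[:, None] / n
    py1 = m1[None, :] / n
    marg = np.stack(
        [(1 - px1) * (1 - py1), (1 - px1) * py1, px1 * (1 - py1), px1 * py1], axis=0
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = table * np.log2(table / marg)
    mi = np.nansum(terms, axis=0)
    mi = np.maximum(mi, 0.0)
    return mi[:, 0] if squeeze else mi


def _contrast_select(decisions: np.ndarray, contrast: str):
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    a, b = CONTRASTS[contrast]
    decisions = np.asarray(decisions)
    sel = (decisions == a) | (decisions == b)
    y = (decisions[sel] == a).astype(np.uint8)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"contrast {contrast!r} has an empty response class")
    return sel, y


def diagnostic_map(
    vis: VisibilityTable,
    decisions: np.ndarray,
    contrast: str,
    n_perm: int = 10_000,
    percentile: float = 99.9,
    rng: np.random.Generator | None = None,
) -> DiagnosticMap:
    """MI map of one behavioral contrast with maximum-statistic FWER threshold.

    Trials from the excluded third response never enter the computation.
    Default permutation settings match the behavioral analysis (10,000
    permutations, 99.9th percentile, i.e. FWER p < 0.001 one-tailed).
    """
    sel, y = _contrast_select(decisions, contrast)
    bits = vis.bits[sel]
    n, n_pix, n_bands = bits.shape
    flat = bits.reshape(n, n_pix * n_bands)
    mi = binary_mi_map(flat, y).reshape(n_pix, n_bands)
    rng = np.random.default_rng() if rng is None else rng
    # permute in blocks to bound the (cols x P) workspace
    thr = _max_stat_threshold(flat, y, n_perm, percentile, rng)
    return DiagnosticMap(mi, thr, contrast, n)


def _max_stat_threshold(flat, y, n_perm, percentile, rng, block=200):
    maxes = np.empty(n_perm)
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        Y = np.empty((y.size, b), dtype=np.uint8)
        for j in range(b):
            Y[:, j] = rng.permutation(y)
        maxes[done : done + b] = binary_mi_map(flat, Y).max(axis=0)
        done += b
    return float(np.percentile(maxes, percentile))


def fwer_threshold(
    stat_images_fn,
    labels: np.ndarray,
    n_perm: int,
    percentile: float,
    rng: np.random.Generator,
) -> float:
    """Generic maximum-statistic FWER threshold.

    ``stat_images_fn(permuted_labels)`` must return the statistic over all
    tests (any array shape); the threshold is the given percentile of the
    per-permutation maximum.  Percentiles use linear interpolation between
    order statistics.
    """
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("labels are degenerate (single class)")
    if n_perm < 100:
        raise ValueError(f"n_perm must be >= 100, got {n_perm}")
    if not 0.0 < percentile < 100.0:
        raise ValueError(f"percentile must lie in (0, 100), got {percentile}")
    maxes = np.empty(n_perm)
    for p in range(n_perm):
        maxes[p] = np.max(stat_images_fn(rng.permutation(labels)))
    return float(np.percentile(maxes, percentile))
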