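"""Bubbles stimulus sampling: octave SF decomposition, Gaussian-aperture masks.

The sampling scheme reveals random fragments of a grayscale base image
independently within spatial-frequency bands.  A 256x256 image spanning
5.72 deg of visual angle is decomposed into six one-octave SF bands with
upper cutoffs [128, 64, 32, 16, 8, 4] cycles/image; bands 1-5 are sampled
through masks built from randomly placed Gaussian apertures (sigmas 0.13,
0.27, 0.54, 1.08, 2.15 deg, coarser apertures for coarser bands), while the
6th (lowest) band is always fully present.  60 apertures per trial keeps the
revealed information roughly constant across trials.

Coordinate convention: 0-based pixel indices, row-major, origin top-left.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

__all__ = [
    "DEFAULT_CUTOFFS_CPI",
    "DEFAULT_SIGMAS_DEG",
    "IMAGE_DEG",
    "SFDecomposition",
    "BubbleMaskSet",
    "StimulusImage",
    "decompose_sf",
    "generate_bubble_masks",
    "compose_stimulus",
    "downsample_masks",
    "default_aperture_allocation",
    "deg_to_px",
]

DEFAULT_CUTOFFS_CPI = [128, 64, 32, 16, 8, 4]
DEFAULT_SIGMAS_DEG = [0.13, 0.27, 0.54, 1.08, 2.15]
IMAGE_DEG = 5.72  # visual angle spanned by the 256 px reference image
TOTAL_APERTURES = 60


def deg_to_px(deg: float, image_size: int = 256, image_deg: float = IMAGE_DEG) -> float:
    """Convert degrees of visual angle to pixels on the reference grid."""
    return deg * image_size / image_deg


@dataclass
class SFDecomposition:
    """One-octave spatial-frequency bands of a grayscale image.

    ``band_images`` sum exactly to the base image: bands 1..5 are telescoping
    band-passes, band 6 is the residual low-pass (including the DC level).
    """

    band_images: list
    cutoffs_cpi: list

    @property
    def n_bands(self) -> int:
        return len(self.band_images)

    def reconstruct(self) -> np.ndarray:
        return np.sum(self.band_images, axis=0)


@dataclass
class BubbleMaskSet:
    """Per-band visibility masks in [0, 1] (1 = fully visible)."""

    masks: list
    aperture_centers: list
    sigmas_px: list

    @property
    def total_apertures(self) -> int:
        return sum(len(c) for c in self.aperture_centers)

    def stack(self) -> np.ndarray:
        """(size, size, n_bands) array view of the masks."""
        return np.stack(self.masks, axis=-1)


@dataclass
class StimulusImage:
    pixels: np.ndarray
    trial_id: int = 0


def _lowpass_transfer(size: int, cutoff_cpi: float, order: int = 6) -> np.ndarray:
    """Zero-phase even-order Butterworth low-pass in the frequency domain."""
    f = np.fft.fftfreq(size) * size  # cycles/image
    fx, fy = np.meshgrid(f, f)
    radius = np.hypot(fx, fy)
    return 1.0 / (1.0 + (radius / cutoff_cpi) ** (2 * order))


def decompose_sf(
    base_image: np.ndarray,
    cutoffs_cpi=None,
    filter_order: int = 6,
) -> SFDecomposition:
    """Decompose a square grayscale image into octave SF bands.

    Band k (k < n) carries energy between cutoff[k]/2 and cutoff[k]
    cycles/image; the last band is the residual low-pass so the bands sum
    back to the original exactly.
    """
    base_image = np.asarray(base_image, dtype=float)
    if base_image.ndim != 2 or base_image.shape[0] != base_image.shape[1]:
        raise ValueError(
            f"base image must be square 2D grayscale, got shape {base_image.shape}"
        )
    size = base_image.shape[0]
    if size & (size - 1):
        raise ValueError(f"image size {size} is not a power of two")
    cutoffs = list(DEFAULT_CUTOFFS_CPI if cutoffs_cpi is None else cutoffs_cpi)
    if len(cutoffs) < 2:
        raise ValueError("need at least 2 cutoffs")
    if any(hi <= lo for hi, lo in zip(cutoffs, cutoffs[1:])):
        raise ValueError(f"cutoffs must be strictly descending, got {cutoffs}")

    spec = np.fft.fft2(base_image)
    nyquist = size / 2
    # Telescoping low-pass bank; the top band passes everything up to Nyquist.
    lowpassed = []
    for c in cutoffs:
        if c >= nyquist:
            lowpassed.append(base_image.copy())
        else:
            lowpassed.append(np.real(np.fft.ifft2(spec * _lowpass_transfer(size, c, filter_order))))
    bands = []
    for k in range(len(cutoffs) - 1):
        bands.append(lowpassed[k] - lowpassed[k + 1])
    bands.append(lowpassed[-1])  # residual low-pass incl. DC = the constant band
    return SFDecomposition(bands, cutoffs)


def default_aperture_allocation(
    total: int = TOTAL_APERTURES, sigmas_px=None
) -> list:
    """Split the aperture budget so expected revealed area matches across bands.

    Counts are proportional to 1/sigma^2 (each aperture reveals ~sigma^2 area),
    at least one per band, remainder to the finest bands.
    """
    if sigmas_px is None:
        sigmas_px = [deg_to_px(s) for s in DEFAULT_SIGMAS_DEG]
    w = 1.0 / np.asarray(sigmas_px, dtype=float) ** 2
    raw = total * w / w.sum()
    counts = np.maximum(np.floor(raw).astype(int), 1)
    k = 0
    while counts.sum() > total:  # floor+min-1 overshoot: trim largest counts
        counts[np.argmax(counts)] -= 1
    while counts.sum() < total:
        counts[k % len(counts)] += 1
        k += 1
    return counts.tolist()


def generate_bubble_masks(
    rng: np.random.Generator,
    n_apertures_per_band=None,
    sigmas_px=None,
    image_size: int = 256,
    combine: str = "max",
    edge_padding: bool = False,
) -> BubbleMaskSet:
    """Random Gaussian-aperture masks, one per sampled SF band.

    Each mask is the pointwise maximum (default) of its band's apertures,
    value 1 at a center decaying as exp(-r^2 / (2 sigma^2)); ``combine='sum'``
    sums then clips to 1.  Centers are uniform over the image; with
    ``edge_padding`` they are kept one sigma away from the borders.
    """
    if sigmas_px is None:
        sigmas_px = [deg_to_px(s, image_size) for s in DEFAULT_SIGMAS_DEG]
    sigmas_px = [float(s) for s in sigmas_px]
    if any(s <= 0 for s in sigmas_px):
        raise ValueError("aperture sigma must be positive")
    if not all(a < b for a, b in zip(sigmas_px, sigmas_px[1:])):
        raise ValueError(f"sigmas must be strictly increasing, got {sigmas_px}")
    if n_apertures_per_band is None:
        n_apertures_per_band = default_aperture_allocation(sigmas_px=sigmas_px)
    counts = [int(c) for c in n_apertures_per_band]
    if len(counts) != len(sigmas_px):
        raise ValueError("one aperture count per band required")
    if sum(counts) == 0:
        raise ValueError("at least one aperture is required in some band")

    yy, xx = np.mgrid[0:image_size, 0:image_size].astype(float)
    masks, centers = [], []
    for count, sigma in zip(counts, sigmas_px):
        if count == 0:
            masks.append(np.zeros((image_size, image_size)))
            centers.append([])
            continue
        lo, hi = (sigma, image_size - sigma) if edge_padding else (0.0, image_size)
        cx = rng.uniform(lo, hi, size=count)
        cy = rng.uniform(lo, hi, size=count)
        g = np.exp(
            -((xx[None] - cx[:, None, None]) ** 2 + (yy[None] - cy[:, None, None]) ** 2)
            / (2.0 * sigma**2)
        )
        if combine == "max":
            mask = g.max(axis=0)
        elif combine == "sum":
            mask = np.minimum(g.sum(axis=0), 1.0)
        else:
            raise ValueError(f"unknown combine rule {combine!r}")
        masks.append(np.clip(mask, 0.0, 1.0))
        centers.append(list(zip(cx.tolist(), cy.tolist())))
    return BubbleMaskSet(masks, centers, sigmas_px)


def compose_stimulus(
    decomp: SFDecomposition, masks: BubbleMaskSet, trial_id: int = 0
) -> StimulusImage:
    """Sparse stimulus: masked bands 1..5 summed, plus the constant last band."""
    n_sampled = len(masks.masks)
    if decomp.n_bands != n_sampled + 1:
        raise ValueError(
            f"decomposition has {decomp.n_bands} bands; expected {n_sampled + 1}"
        )
    shape = decomp.band_images[0].shape
    for m in masks.masks:
        if m.shape != shape:
            raise ValueError(f"mask grid {m.shape} != image grid {shape}")
    pixels = np.zeros(shape)
    for band, mask in zip(decomp.band_images[:-1], masks.masks):
        pixels += mask * band
    pixels += decomp.band_images[-1]
    return StimulusImage(pixels, trial_id)


def downsample_masks(masks: BubbleMaskSet, target_size: int = 64) -> BubbleMaskSet:
    """Bilinear downsampling of the masks to the analysis resolution."""
    src = masks.masks[0].shape[0]
    if target_size > src:
        raise ValueError(f"target size {target_size} exceeds source {src}; no upsampling")
    scale = src / target_size
    out = [
        np.clip(
            resize(m, (target_size, target_size), order=1, anti_aliasing=False,
                   preserve_range=True),
            0.0,
            1.0,
        )
        for m in masks.masks
    ]
    centers = [[(x / scale, y / scale) for x, y in c] for c in masks.aperture_centers]
    sigmas = [s / scale for s in masks.sigmas_px]
    return BubbleMaskSet(out, centers, sigmas)
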