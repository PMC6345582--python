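"""Shared containers: sampled trials and source-space activity.

Decision coding used throughout: 0 = "nuns", 1 = "voltaire", 2 = "dont_know",
treated everywhere as an unordered categorical variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NUNS",
    "VOLTAIRE",
    "DONT_KNOW",
    "DECISION_LABELS",
    "SampledTrialSet",
    "SourceActivity",
]

NUNS, VOLTAIRE, DONT_KNOW = 0, 1, 2
DECISION_LABELS = ("nuns", "voltaire", "dont_know")


@dataclass
class SampledTrialSet:
    """Per-trial bubble masks (analysis resolution) and decision labels.

    masks: (n_trials, size, size, n_bands) float32 in [0, 1]
    decisions: (n_trials,) int codes (see DECISION_LABELS)
    seeds: per-trial RNG seeds used to generate the masks (provenance)
    """

    masks: np.ndarray
    decisions: np.ndarray
    seeds: np.ndarray | None = None

    @property
    def n_trials(self) -> int:
        return self.masks.shape[0]

    @property
    def mask_size(self) -> int:
        return self.masks.shape[1]

    @property
    def n_bands(self) -> int:
        return self.masks.shape[-1]

    def masks_flat(self) -> np.ndarray:
        """(n_trials, size*size*n_bands) view used by MI and dot-product stages."""
        return self.masks.reshape(self.n_trials, -1)


@dataclass
class SourceActivity:
    """Source-space neural activity, two channels per sample.

    data: (n_trials, n_voxels, n_times, 2) — channel 0 amplitude, channel 1
    the instantaneous temporal gradient of the amplitude.
    coords: (n_voxels, 3) positions in mm (MNI-like space).
    times_ms: (n_times,) post-stimulus sample times.
    """

    data: np.ndarray
    coords: np.ndarray
    times_ms: np.ndarray

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def channels_flat(self):
        """Amplitude and gradient flattened to (n_trials, n_voxels*n_times)."""
        n = self.n_trials
        return (
            np.ascontiguousarray(self.data[..., 0]).reshape(n, -1),
            np.ascontiguousarray(self.data[..., 1]).reshape(n, -1),
        )
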