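"""HDF5 / PNG / TSV persistence for pipeline artifacts.

Trial sets and activity are stored as dense HDF5 datasets (masks
(n, size, size, bands), decisions, seeds; activity (n, V, T, 2) with coords
and times), not per-trial groups — dense datasets are what h5py handles well
at thousands of trials.  Every file carries the seed and a config hash in its
root attributes when written through the pipeline.
"""

from __future__ import annotations

import numpy as np

from .behavior import ComplexityMap, RedundancyMatrix
from .core import SampledTrialSet, SourceActivity
from .diagnostic import DiagnosticMap
from .features import BrainFeatureBasis, RepresentationMatrix

__all__ = [
    "read_image",
    "write_image",
    "save_trials",
    "load_trials",
    "save_activity",
    "load_activity",
    "save_diagnostic_map",
    "load_diagnostic_map",
    "save_basis",
    "load_basis",
    "save_representation_matrix",
    "load_representation_matrix",
    "save_redundancy_matrix",
    "load_redundancy_matrix",
    "export_voxel_dynamics_tsv",
    "export_complexity_tsv",
]


def read_image(path) -> np.ndarray:
    """8-bit grayscale PNG -> float array in [0, 1]."""
    from skimage.io import imread

    img = imread(path)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=-1)
    return img.astype(float) / 255.0


def write_image(path, img: np.ndarray) -> None:
    from skimage.io import imsave

    lo, hi = float(np.min(img)), float(np.max(img))
    scaled = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    imsave(path, (255 * scaled).astype(np.uint8), check_contrast=False)


def _attrs(group, **kwargs):
    for k, v in kwargs.items():
        if v is not None:
            group.attrs[k] = v


def save_trials(path, trials: SampledTrialSet, **attrs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=trials.masks, compression="gzip", shuffle=True)
        f.create_dataset("decisions", data=trials.decisions)
        if trials.seeds is not None:
            f.create_dataset("seeds", data=trials.seeds)
        _attrs(f, **attrs)


def load_trials(path) -> SampledTrialSet:
    import h5py

    with h5py.File(path, "r") as f:
        return SampledTrialSet(
            f["masks"][()],
            f["decisions"][()],
            f["seeds"][()] if "seeds" in f else None,
        )


def save_activity(path, activity: SourceActivity, **attrs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=activity.data, compression="gzip", shuffle=True)
        f.create_dataset("coords", data=activity.coords)
        f.create_dataset("times_ms", data=activity.times_ms)
        _attrs(f, **attrs)


def load_activity(path) -> SourceActivity:
    import h5py

    with h5py.File(path, "r") as f:
        return SourceActivity(f["data"][()], f["coords"][()], f["times_ms"][()])


def save_diagnostic_map(path, dmap: DiagnosticMap, **attrs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("mi", data=dmap.mi)
        f.create_dataset("significant", data=dmap.significant)
        f.attrs["fwer_threshold"] = dmap.fwer_threshold
        f.attrs["contrast"] = dmap.contrast
        f.attrs["n_trials"] = dmap.n_trials
        _attrs(f, **attrs)


def load_diagnostic_map(path) -> DiagnosticMap:
    import h5py

    with h5py.File(path, "r") as f:
        return DiagnosticMap(
            f["mi"][()],
            float(f.attrs["fwer_threshold"]),
            str(f.attrs["contrast"]),
            int(f.attrs["n_trials"]),
        )


def save_basis(path, basis: BrainFeatureBasis, **attrs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=basis.features, compression="gzip")
        f.create_dataset("labels", data=np.array(basis.labels, dtype="S"))
        f.attrs["image_shape"] = basis.image_shape
        f.attrs["reconstruction_error"] = basis.reconstruction_error
        f.attrs["threshold_frac"] = basis.threshold_frac
        _attrs(f, **attrs)


def load_basis(path) -> BrainFeatureBasis:
    import h5py

    with h5py.File(path, "r") as f:
        return BrainFeatureBasis(
            f["features"][()],
            tuple(int(v) for v in f.attrs["image_shape"]),
            [s.decode() for s in f["labels"][()]],
            float(f.attrs["reconstruction_error"]),
            float(f.attrs["threshold_frac"]),
        )


def save_representation_matrix(path, rep: RepresentationMatrix, **attrs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("mi", data=rep.mi, compression="gzip")
        f.create_dataset("times_ms", data=rep.times_ms)
        f.create_dataset("feature_labels", data=np.array(rep.feature_labels, dtype="S"))
        f.attrs["fwer_threshold"] = rep.fwer_threshold
        _attrs(f, **attrs)


def load_representation_matrix(path) -> RepresentationMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        return RepresentationMatrix(
            f["mi"][()],
            float(f.attrs["fwer_threshold"]),
            f["times_ms"][()],
            [s.decode() for s in f["feature_labels"][()]],
        )


def save_redundancy_matrix(path, red: RedundancyMatrix, **attrs) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("red", data=red.red, compression="gzip")
        f.create_dataset("times_ms", data=red.times_ms)
        f.create_dataset("feature_labels", data=np.array(red.feature_labels, dtype="S"))
        f.attrs["fwer_threshold"] = red.fwer_threshold
        f.attrs["contrast"] = red.contrast
        _attrs(f, **attrs)


def load_redundancy_matrix(path) -> RedundancyMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        return RedundancyMatrix(
            f["red"][()],
            float(f.attrs["fwer_threshold"]),
            f["times_ms"][()],
            str(f.attrs["contrast"]),
            [s.decode() for s in f["feature_labels"][()]],
        )


def export_voxel_dynamics_tsv(path, course, coords, region_labels=None) -> None:
    """Per-voxel onset/offset/duration table (optionally with region labels)."""
    import pandas as pd

    coords = np.asarray(coords)
    df = pd.DataFrame(
        {
            "voxel_id": np.arange(coords.shape[0]),
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "onset_ms": course.onset_ms,
            "offset_ms": course.offset_ms,
            "duration_ms": course.duration_ms,
        }
    )
    if region_labels is not None:
        df["region_label"] = region_labels
    df.to_csv(path, sep="\t", index=False)


def export_complexity_tsv(path, cmap: ComplexityMap) -> None:
    import pandas as pd

    nv, nw = cmap.counts.shape
    rows = [
        {"voxel_id": v, "window_idx": w, "count": int(cmap.counts[v, w])}
        for v in range(nv)
        for w in range(nw)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
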