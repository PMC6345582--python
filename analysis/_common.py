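"""Shared settings for the numbered analysis scripts (one demo observer)."""

from pathlib import Path

SEED = 7
N_TRIALS = 800
N_VOXELS = 160
OUT = Path(__file__).resolve().parent.parent / "results" / "demo"
OUT.mkdir(parents=True, exist_ok=True)


def load_dataset():
    """The demo observer, regenerated deterministically from SEED."""
    from sir import synthetic

    return synthetic.simulate_dataset(n_trials=N_TRIALS, seed=SEED, n_voxels=N_VOXELS)
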