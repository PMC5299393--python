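import numpy as np
import pandas as pd
import pytest

from oscillofuse.config import ArtifactConfig, NoiseConfig, SimConfig
from oscillofuse.preprocess import EpochSet
from oscillofuse.simulate import build_ground_truth, simulate_eeg, simulate_task


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """Desk-scale session: 1 subject, 1 block x 20 trials, 500 Hz EEG."""
    return SimConfig(
        n_subjects=1,
        n_blocks=1,
        trials_per_block=20,
        eeg_sfreq=500.0,
        n_scans_per_block=110,
        grid_shape=(8, 8, 8),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_session(small_cfg):
    trials = simulate_task(small_cfg)
    gt = build_ground_truth(trials, small_cfg)
    rec, gt = simulate_eeg(trials, small_cfg, ground_truth=gt)
    return trials, gt, rec


def make_epochs(
    data: np.ndarray,
    sfreq: float = 500.0,
    tmin_ms: float = -1800.0,
    conditions=None,
) -> EpochSet:
    """Wrap a (trials, channels, samples) array as an EpochSet."""
    n = data.shape[0]
    if conditions is None:
        conditions = ["large_gain"] * n
    meta = pd.DataFrame(
        {
            "subject": 0,
            "block": 0,
            "trial": np.arange(n),
            "condition": conditions,
        }
    )
    return EpochSet(
        data=np.asarray(data, dtype=float),
        sfreq=sfreq,
        ch_names=[f"ch{i}" for i in range(data.shape[1])],
        ch_types=["eeg"] * data.shape[1],
        tmin_ms=tmin_ms,
        metadata=meta,
        rejected=np.zeros(n, dtype=bool),
        reasons=[[] for _ in range(n)],
    )
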