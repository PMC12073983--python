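import numpy as np
import pytest

from hfoarea.containers import ChannelMeta, Epoch, Recording
from hfoarea.synthetic import cohort_from_cells, pink_noise

# Published multicentre contingency numbers used as fixed inputs:
# among 146 conclusive patients, 74 ILAE1 (31 with completely resected area)
# and 72 ILAE2-6 (14 completely resected); 14 of 160 datasets inconclusive,
# 6 of them ILAE1.
STUDY_CELLS = {"TN": 31, "FP": 43, "FN": 14, "TP": 58}
STUDY_INCONCLUSIVE = {"n": 14, "ilae1": 6}


@pytest.fixture(scope="session")
def study_cohort():
    """The published cohort reconstructed from its printed cell counts."""
    return cohort_from_cells(
        tn=STUDY_CELLS["TN"],
        fp=STUDY_CELLS["FP"],
        fn=STUDY_CELLS["FN"],
        tp=STUDY_CELLS["TP"],
        n_inconclusive=STUDY_INCONCLUSIVE["n"],
        inconclusive_ilae1=STUDY_INCONCLUSIVE["ilae1"],
    )


def make_epoch(samples: np.ndarray, fs: float = 2000.0, names=None, t_start=0.0) -> Epoch:
    samples = np.atleast_2d(samples)
    names = names or [f"S{i + 1:02d}" for i in range(samples.shape[0])]
    return Epoch(
        samples=samples,
        fs=fs,
        epoch_index=0,
        t_start=t_start,
        channel_names=names,
        valid_mask=np.ones(samples.shape[0], dtype=bool),
    )


def make_recording(n_channels=2, duration_s=310.0, fs=2000.0, seed=0, meta=None) -> Recording:
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    samples = np.stack([pink_noise(n, 1.0, 10.0, rng) for _ in range(n_channels)])
    channels = meta or [ChannelMeta(name=f"S{i + 1:02d}", electrode=None) for i in range(n_channels)]
    return Recording(samples, fs, channels)
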