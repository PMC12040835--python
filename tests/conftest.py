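import numpy as np
import pytest

from delmar import BrainMask, MultiEchoSignal, make_ground_truth, make_multiecho_dataset


@pytest.fixture(scope="session")
def small_mask() -> BrainMask:
    """Full 6x6x6 grid (216 voxels)."""
    return BrainMask.from_array(np.ones((6, 6, 6), dtype=bool))


@pytest.fixture(scope="session")
def tiny_signal(small_mask) -> MultiEchoSignal:
    """Deterministic 3-echo toy signal, 10 time points."""
    rng = np.random.default_rng(42)
    data = rng.standard_normal((10, small_mask.n_voxels, 3))
    return MultiEchoSignal(data=data, echo_times=np.array([10.0, 25.0, 40.0]),
                           mask=small_mask)


@pytest.fixture(scope="session")
def small_truth():
    """Planted hierarchy at reduced scale: 6 canonical / 2 meta networks."""
    return make_ground_truth(n_canonical=6, n_meta=2, n_timepoints=80,
                             mask=_mask12(), seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_truth):
    signal, truth = make_multiecho_dataset(small_truth)
    return signal, truth


def _mask12() -> BrainMask:
    return BrainMask.from_array(np.ones((12, 12, 12), dtype=bool))
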