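import numpy as np
import pytest

from tvconn.forward import build_head_model, compute_leadfield
from tvconn.ground_truth import build_attention_model, simulate_trials


@pytest.fixture(scope="session")
def model():
    return build_attention_model()


@pytest.fixture(scope="session")
def small_head():
    """A coarse spherical head model shared by forward/inverse tests."""
    return build_head_model(n_vertices=300, n_electrodes=24)


@pytest.fixture(scope="session")
def small_leadfield(small_head):
    head, sources, sensors = small_head
    return compute_leadfield(head, sources, sensors)


@pytest.fixture(scope="session")
def few_trials(model):
    trials, params = simulate_trials(model, 8, seed=11)
    return trials, params


def fit_stationary_mvar(data: np.ndarray, order: int) -> np.ndarray:
    """Independent least-squares MVAR oracle on concatenated trials.

    data: (trials, m, N); returns A (order, m, m) with A[k, i, j] the lag-k+1
    coefficient from sender j to receiver i.
    """
    r, m, n = data.shape
    targets, designs = [], []
    for t in range(r):
        y = data[t]
        targets.append(y[:, order:].T)
        designs.append(
            np.concatenate(
                [y[:, order - k: n - k].T for k in range(1, order + 1)], axis=1
            )
        )
    target = np.concatenate(targets)
    design = np.concatenate(designs)
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    return coef.reshape(order, m, m).transpose(0, 2, 1)
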