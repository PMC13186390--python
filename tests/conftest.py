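import numpy as np
import pytest

from fomo.model import (
    CoreParams,
    DirectionParams,
    ModelConfig,
    SelectionState,
    Stimulus,
)
from fomo.simulate import GroupParams, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def square_stimulus():
    """Four items on a unit square, two of each class."""
    return Stimulus.from_arrays(
        x=[0.0, 1.0, 0.0, 1.0],
        y=[0.0, 0.0, 1.0, 1.0],
        item_class=["A", "B", "A", "B"],
    )


@pytest.fixture
def neutral_params():
    return CoreParams(0.0, 0.0, 0.0, 0.0)


@pytest.fixture
def neutral_direction():
    return DirectionParams(theta=(0.0, 0.0, 0.0, 0.0), kappa=20.0)


def random_stimulus(rng, n_items=12):
    xy = rng.uniform(0, 200, size=(n_items, 2))
    classes = rng.choice(["A", "B"], size=n_items)
    return Stimulus.from_arrays(xy[:, 0], xy[:, 1], classes)


def random_state(rng, stimulus, n_selected=None):
    n = stimulus.n_items
    if n_selected is None:
        n_selected = int(rng.integers(2, n - 1))
    order = rng.permutation(n)[:n_selected]
    return SelectionState.from_selected(stimulus, order.tolist())


@pytest.fixture
def small_dataset():
    """A small two-condition study, strong biases, quick to fit."""
    gp = GroupParams(
        core_mean=[[0.5, 1.5, 1.0, 0.5]] * 2,
        core_sd=0.3,
        theta_mean=[[1.0, 0.0, 1.0, 0.0]] * 2,
        theta_sd=0.3,
    )
    return simulate_dataset(
        gp,
        n_participants=6,
        n_trials=6,
        n_items=20,
        n_cols=5,
        n_rows=4,
        version="v1.3",
        seed=5,
    )
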