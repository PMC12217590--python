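"""Shared fixtures: tiny discrete observation sets and toy models."""

import numpy as np
import pytest

from rgm.frontends import DiscreteObservation
from rgm.structure import fast_structure_learn


def make_obs(codes, alphabet=None, groups=None, grid=None):
    codes = np.asarray(codes, dtype=np.int64)
    n_ch = codes.shape[1]
    if alphabet is None:
        alphabet = np.full(n_ch, int(codes.max()) + 1)
    if groups is None:
        groups = [[c] for c in range(n_ch)]
    if grid is None:
        grid = (1, len(groups))
    return DiscreteObservation(
        codes=codes, alphabet=np.asarray(alphabet, dtype=np.int64),
        channel_groups=groups, grid_shape=grid,
    )


@pytest.fixture
def periodic_obs():
    """Two channels repeating an 8-step cycle twice (16 steps)."""
    rng = np.random.default_rng(7)
    cycle = rng.integers(0, 3, size=(8, 2))
    # make all cycle steps distinct so the orbit is unambiguous
    cycle[:, 0] = np.arange(8) % 3
    cycle[:, 1] = np.arange(8) // 3
    codes = np.tile(cycle, (2, 1))
    return make_obs(codes, alphabet=[3, 3])


@pytest.fixture
def periodic_model(periodic_obs):
    """Two-level temporal model: 2 channels -> 1 group, then R=2."""
    return fast_structure_learn(
        periodic_obs, R_schedule=[1, 2], merge_schedule=[[[0, 1]]],
    )


@pytest.fixture
def exemplar_obs():
    """Five distinct 3-channel exemplars (static images stand-in)."""
    codes = np.array(
        [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [1, 1, 1]], dtype=np.int64
    )
    return make_obs(codes, alphabet=[2, 2, 2])


@pytest.fixture
def exemplar_model(exemplar_obs):
    return fast_structure_learn(
        exemplar_obs, R_schedule=[1, 1], merge_schedule=[[[0, 1, 2]]], temporal=False
    )
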