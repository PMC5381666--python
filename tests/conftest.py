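"""Shared fixtures: small hand-built trees and alignments."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from termswitch import IndexedTree

# deterministic hypothesis runs: same examples on every invocation
settings.register_profile(
    "ci", derandomize=True, max_examples=60, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture
def cherry_tree():
    """Two leaves a, b at distance 0.1 each from the root."""
    return IndexedTree(parent=[-1, 0, 0], blen=[0.0, 0.1, 0.1],
                       names=["root", "a", "b"])


@pytest.fixture
def ladder_tree():
    """Seven nodes: root -> (n1 -> (n3 -> (l5, l6), l4), l2).

    Branch lengths above nodes 1..6: 0.02, 0.05, 0.02, 0.03, 0.01, 0.04.
    """
    return IndexedTree(
        parent=[-1, 0, 0, 1, 1, 3, 3],
        blen=[0.0, 0.02, 0.05, 0.02, 0.03, 0.01, 0.04],
        names=["n0", "n1", "l2", "n3", "l4", "l5", "l6"])


@pytest.fixture
def five_leaf_tree():
    """Balanced-ish 5-leaf tree used by reconstruction tests."""
    return IndexedTree(
        parent=[-1, 0, 0, 1, 1, 2, 2, 6, 6],
        blen=[0.0, 0.04, 0.03, 0.02, 0.05, 0.06, 0.01, 0.02, 0.03],
        names=["r", "u", "v", "a", "b", "c", "w", "d", "e"])


def make_joint(tree, states):
    """Joint-state codes array from a list of dinucleotide strings or None."""
    from termswitch.switches import pair_code
    out = np.full(tree.n_nodes, -1, dtype=np.int64)
    for i, s in enumerate(states):
        if s is not None:
            out[i] = pair_code(s)
    return out


@pytest.fixture
def joint_builder():
    return make_joint
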