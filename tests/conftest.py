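"""Shared fixtures and independent oracles.

The enumeration oracles deliberately avoid the pruning/rerooting code paths:
they sum over all joint internal-state assignments with per-edge transition
probabilities taken from a generic matrix exponential, so they stay valid
even if the closed-form ER matrix or the recursion were wrong.
"""

from itertools import product

import numpy as np
import pytest
from scipy.linalg import expm

from callspace import PhyloTree, simulate_yule_tree


def er_generator(q: float, S: int) -> np.ndarray:
    Q = np.full((S, S), q)
    np.fill_diagonal(Q, -(S - 1) * q)
    return Q


def expm_transition(q: float, t: float, S: int) -> np.ndarray:
    """Generic matrix-exponential transition matrix (oracle)."""
    return expm(er_generator(q, S) * t)


def _edge_mats(tree: PhyloTree, q: float, S: int) -> dict[int, np.ndarray]:
    return {v: expm_transition(q, tree.edge_length[v], S)
            for v in range(tree.n_nodes) if v != tree.root}


def _joint_probability(tree: PhyloTree, node_state: dict[int, int],
                       P: dict[int, np.ndarray], S: int) -> float:
    p = 1.0 / S
    for v, mat in P.items():
        p *= mat[node_state[tree.parent[v]] - 1, node_state[v] - 1]
    return p


def enum_log_likelihood(tree: PhyloTree, states: dict[str, int],
                        q: float, S: int) -> float:
    """Likelihood by exhaustive enumeration over internal assignments."""
    internals = tree.internal_nodes
    P = _edge_mats(tree, q, S)
    total = 0.0
    for assign in product(range(1, S + 1), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for v in tree.tips:
            st[v] = states[tree.label[v]]
        total += _joint_probability(tree, st, P, S)
    return float(np.log(total))


def enum_marginals(tree: PhyloTree, states: dict[str, int],
                   q: float, S: int) -> dict[int, np.ndarray]:
    """Per-node posteriors by exhaustive enumeration."""
    internals = tree.internal_nodes
    P = _edge_mats(tree, q, S)
    post = {v: np.zeros(S) for v in range(tree.n_nodes)}
    for assign in product(range(1, S + 1), repeat=len(internals)):
        st = dict(zip(internals, assign))
        for v in tree.tips:
            st[v] = states[tree.label[v]]
        p = _joint_probability(tree, st, P, S)
        for v in range(tree.n_nodes):
            post[v][st[v] - 1] += p
    return {v: vec / vec.sum() for v, vec in post.items()}


def random_instance(rng: np.random.Generator, n_tips: int | None = None,
                    S: int = 4):
    """Random small tree (jittered branch lengths) + random tip states."""
    if n_tips is None:
        n_tips = int(rng.integers(2, 7))
    tree = simulate_yule_tree(n_tips, 1.0, rng)
    tree.edge_length = tree.edge_length * rng.uniform(0.2, 2.0, tree.n_nodes)
    tree.edge_length[tree.root] = 0.0
    states = {l: int(rng.integers(1, S + 1)) for l in tree.tip_labels}
    q = float(rng.uniform(0.05, 2.0))
    return tree, states, q


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)


@pytest.fixture
def cherry():
    """Two-tip tree (A:1,B:1)."""
    from callspace import read_newick
    return read_newick("(A:1,B:1);")
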