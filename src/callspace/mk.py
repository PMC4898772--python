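"""Equal-rates Mk model: likelihood, rate fitting, marginal ancestral states.

The character is the number of notes per advertisement call, treated as a
discrete nominal trait with ``S`` states (default 4).  Under the equal-rates
(ER / "MK1") model every transition between distinct states occurs at the
same instantaneous rate ``q``, so the generator is ``Q = q(J - S·I)/1`` with
off-diagonal ``q`` and diagonal ``-(S-1)q``, and the transition matrix has
the closed form

    P_ii(t) = 1/S + (S-1)/S · exp(-S q t)
    P_ij(t) = 1/S -     1/S · exp(-S q t)        (i != j)

Likelihoods use Felsenstein's pruning algorithm with per-node scaling; the
root prior is uniform ``1/S`` (the ER stationary distribution).  Marginal
ancestral states are the rerooting-method posteriors: the distribution at a
node obtained by rerooting the (reversible) chain there, computed in one
up-pass plus one down-pass.
"""

from __future__ import annotations

import collections
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .tree import PhyloTree, validate_tip_states

__all__ = [
    "MkFit",
    "ChangeSummary",
    "CladeSummary",
    "er_transition_probability",
    "prune_log_likelihood",
    "fit_mk_rate",
    "marginal_ancestral_states",
    "summarize_over_trees",
    "count_changes",
    "aggregate_change_summaries",
]

LOG10_Q_BOUNDS = (-6.0, 3.0)


@dataclass
class MkFit:
    """Maximum-likelihood fit of the single ER rate parameter."""

    q: float
    S: int
    log_likelihood: float
    converged: bool


@dataclass
class ChangeSummary:
    """Counts of inferred state changes on one tree, keyed (from, to)."""

    counts: dict[tuple[int, int], int]
    n_edges: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class CladeSummary:
    """Mean marginal vector for one rooted clade across a tree sample."""

    tipset: frozenset[str]
    mean_marginal: np.ndarray
    coverage: float  # fraction of trees containing this clade
    n_trees: int = field(default=0)


def er_transition_probability(q: float, t: float, S: int) -> np.ndarray:
    """Closed-form ER transition matrix ``P(t) = expm(Q t)``.

    Rows sum to 1, the matrix is symmetric, and ``P(0) = I``.
    """
    if q < 0:
        raise ValueError("rate q must be nonnegative")
    if t < 0:
        raise ValueError("branch length t must be nonnegative")
    if S < 2:
        raise ValueError("state count S must be >= 2")
    e = np.exp(-S * q * t)
    off = (1.0 - e) / S
    P = np.full((S, S), off)
    np.fill_diagonal(P, 1.0 / S + (S - 1) / S * e)
    return P


def _tip_state_array(tree: PhyloTree, states: dict[str, int], S: int) -> np.ndarray:
    """Per-node conditional likelihood initialisation (indicators at tips)."""
    validate_tip_states(tree, states)
    partial = np.ones((tree.n_nodes, S))
    for v in tree.tips:
        s = states[tree.label[v]]  # 1-based
        if not 1 <= s <= S:
            raise ValueError(f"tip state {s} outside 1..{S}")
        partial[v] = 0.0
        partial[v, s - 1] = 1.0
    return partial


def _edge_matrices(tree: PhyloTree, q: float, S: int) -> np.ndarray:
    P = np.empty((tree.n_nodes, S, S))
    for v in range(tree.n_nodes):
        if v == tree.root:
            P[v] = np.eye(S)
        else:
            P[v] = er_transition_probability(q, tree.edge_length[v], S)
    return P


def _up_pass(tree: PhyloTree, partial: np.ndarray, P: np.ndarray):
    """Pruning up-pass: subtree conditionals with per-node log scaling.

    Returns (up, log_scale_total) where ``up[v]`` is the scaled conditional
    likelihood of the data below ``v`` given the state at ``v``.
    """
    up = partial.copy()
    log_scale = 0.0
    for v in tree.postorder():
        if not tree.children[v]:
            continue
        acc = np.ones(up.shape[1])
        for c in tree.children[v]:
            acc = acc * (P[c] @ up[c])
        m = acc.max()
        if m <= 0:
            raise FloatingPointError("zero likelihood at an internal node")
        up[v] = acc / m
        log_scale += np.log(m)
    return up, log_scale


def prune_log_likelihood(
    tree: PhyloTree, states: dict[str, int], q: float, S: int = 4
) -> float:
    """Log-likelihood of the tip states under ER(q), uniform root prior."""
    partial = _tip_state_array(tree, states, S)
    P = _edge_matrices(tree, q, S)
    up, log_scale = _up_pass(tree, partial, P)
    lik = np.sum(up[tree.root] / S)
    return float(np.log(lik) + log_scale)


def fit_mk_rate(tree: PhyloTree, states: dict[str, int], S: int = 4) -> MkFit:
    """Maximise the ER likelihood over ``q`` by Brent search on log10(q).

    The bracket log10(q) in [-6, 3] covers any sane branch-length scale.
    If all tips share one state the likelihood is monotone decreasing in
    ``q``; the lower bound is returned with ``converged=False``.
    """
    observed = {states[l] for l in tree.tip_labels}
    lo, hi = LOG10_Q_BOUNDS
    if len(observed) <= 1:
        q = 10.0 ** lo
        return MkFit(q=q, S=S, log_likelihood=prune_log_likelihood(tree, states, q, S),
                     converged=False)

    def neg_ll(log10_q: float) -> float:
        return -prune_log_likelihood(tree, states, 10.0 ** log10_q, S)

    res = minimize_scalar(neg_ll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    q_hat = float(10.0 ** res.x)
    at_bound = res.x < lo + 1e-6 or res.x > hi - 1e-6
    return MkFit(q=q_hat, S=S, log_likelihood=float(-res.fun),
                 converged=bool(res.success and not at_bound))


def marginal_ancestral_states(
    tree: PhyloTree, states: dict[str, int], q: float, S: int = 4
) -> dict[int, np.ndarray]:
    """Marginal posterior state probabilities at every node (rerooting method).

    For the reversible ER chain with its stationary (uniform) root prior the
    marginal at a node equals the root posterior of the tree rerooted at
    that node; it is computed here by the equivalent up-pass/down-pass
    message scheme.  Tip vectors are indicators on the observed state.
    """
    partial = _tip_state_array(tree, states, S)
    P = _edge_matrices(tree, q, S)
    up, _ = _up_pass(tree, partial, P)

    # down[v]: likelihood of everything outside v's subtree, as a function of
    # the state at v, times the root prior; scaled per node.
    down = np.empty_like(up)
    down[tree.root] = 1.0 / S
    marginals: dict[int, np.ndarray] = {}
    for v in tree.preorder():
        vec = down[v] * up[v]
        tot = vec.sum()
        if tot <= 0:
            raise FloatingPointError("zero marginal normaliser")
        marginals[v] = vec / tot
        if not tree.children[v]:
            continue
        msgs = [P[c] @ up[c] for c in tree.children[v]]
        for k, c in enumerate(tree.children[v]):
            sib = down[v].copy()
            for j, m in enumerate(msgs):
                if j != k:
                    sib = sib * m
            # P is symmetric so P[c].T == P[c]
            d = P[c] @ sib
            m = d.max()
            down[c] = d / m if m > 0 else d
    return marginals


def summarize_over_trees(
    trees: list[PhyloTree],
    states: dict[str, int],
    S: int = 4,
    rate_policy: str = "per-tree-ML",
    q: float | None = None,
) -> dict[frozenset[str], CladeSummary]:
    """Average marginal reconstructions across a posterior sample of trees.

    Internal nodes are matched across trees by their rooted bipartition
    (frozenset of subtended tip labels).  For each clade found in at least
    one tree the summary holds the mean marginal vector over the trees that
    contain it, and the fraction of trees containing it (coverage) — the way
    node support is reported on a maximum-clade-credibility tree.

    rate_policy: ``"per-tree-ML"`` refits q on every tree; ``"fixed"``
    uses the supplied ``q`` on all trees (faster on large samples).
    """
    if not trees:
        raise ValueError("empty tree list")
    tipset0 = frozenset(trees[0].tip_labels)
    sums: dict[frozenset[str], np.ndarray] = {}
    counts: collections.Counter = collections.Counter()
    if rate_policy not in ("per-tree-ML", "fixed"):
        raise ValueError(f"unknown rate_policy {rate_policy!r}")
    if rate_policy == "fixed" and q is None:
        raise ValueError("rate_policy='fixed' requires q")
    for tree in trees:
        if frozenset(tree.tip_labels) != tipset0:
            raise ValueError("trees have inconsistent tip sets")
        q_t = fit_mk_rate(tree, states, S).q if rate_policy == "per-tree-ML" else q
        marg = marginal_ancestral_states(tree, states, q_t, S)
        tipsets = tree.clade_tipsets()
        for v in tree.internal_nodes:
            key = tipsets[v]
            counts[key] += 1
            if key in sums:
                sums[key] += marg[v]
            else:
                sums[key] = marg[v].copy()
    n = len(trees)
    return {
        key: CladeSummary(tipset=key, mean_marginal=sums[key] / counts[key],
                          coverage=counts[key] / n, n_trees=counts[key])
        for key in sums
    }


def assign_states(
    tree: PhyloTree, marginals: dict[int, np.ndarray]
) -> dict[int, int]:
    """Max-marginal state per node (1-based).

    Ties are broken toward the parent's assigned state when it is among the
    tied maxima; root ties (and ties not involving the parent state) go to
    the lowest state index.
    """
    assign: dict[int, int] = {}
    for v in tree.preorder():
        vec = marginals[v]
        best = vec.max()
        tied = np.flatnonzero(vec >= best - 1e-12)
        if v != tree.root:
            p_state = assign[tree.parent[v]] - 1
            if p_state in tied:
                assign[v] = p_state + 1
                continue
        assign[v] = int(tied[0]) + 1
    return assign


def count_changes(
    tree: PhyloTree, marginals: dict[int, np.ndarray]
) -> ChangeSummary:
    """Count state changes along edges under the max-marginal assignment.

    Each edge whose endpoint assignments differ contributes one change keyed
    ``(parent_state, child_state)``.  This is a reproducible stand-in for
    eyeballing change summaries on reconstructed trees; joint or stochastic
    mapping alternatives are deliberately out of scope, but the assignment
    step (:func:`assign_states`) is isolated so they could be swapped in.
    """
    assign = assign_states(tree, marginals)
    counts: collections.Counter = collections.Counter()
    n_edges = 0
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        n_edges += 1
        a, b = assign[tree.parent[v]], assign[v]
        if a != b:
            counts[(a, b)] += 1
    return ChangeSummary(counts=dict(counts), n_edges=n_edges)


def aggregate_change_summaries(
    summaries: list[ChangeSummary],
) -> dict[str, object]:
    """Mean and modal change counts per transition across a tree sample."""
    keys = sorted({k for s in summaries for k in s.counts})
    per_key = {
        k: [s.counts.get(k, 0) for s in summaries] for k in keys
    }
    totals = [s.total for s in summaries]
    mode_total = collections.Counter(totals).most_common(1)[0][0] if totals else 0
    return {
        "transitions": {
            f"{a}->{b}": {
                "mean": float(np.mean(v)),
                "mode": int(collections.Counter(v).most_common(1)[0][0]),
            }
            for (a, b), v in per_key.items()
        },
        "total_mean": float(np.mean(totals)) if totals else 0.0,
        "total_mode": int(mode_total),
        "n_trees": len(summaries),
    }
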