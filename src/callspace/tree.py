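"""Rooted phylogenetic trees and Newick / tabular input-output.

The in-memory container (:class:`PhyloTree`) is a flat, index-based rooted
tree: parent pointers, child lists and one branch length per non-root node.
It is the substrate every likelihood computation in this package runs on.
Newick parsing and serialisation are delegated to :mod:`dendropy`, which
handles quoted labels, bracketed comments and the usual dialect quirks;
internal node labels are ignored for computation.

Conventions
-----------
* Exactly one root; a branch length on the root, if present in the input,
  is discarded (standard convention).
* Polytomies are preserved, never arbitrarily resolved.
* Tip labels must be unique and non-empty; matching against trait / trial
  tables is exact and case-sensitive, and mismatches raise rather than
  silently dropping tips.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "NewickError",
    "read_newick",
    "read_newick_list",
    "write_newick",
    "read_trait_csv",
    "read_trials_csv",
    "validate_tip_states",
    "TRIAL_COLUMNS",
]

TRIAL_COLUMNS = ("population", "stimulus_notes", "stimulus_freq_khz", "response")


class NewickError(ValueError):
    """Malformed Newick input (unbalanced parentheses, missing lengths...)."""


@dataclass
class PhyloTree:
    """Rooted tree with branch lengths, stored as flat parallel arrays.

    Nodes are integer indices ``0..n_nodes-1``.  ``parent[i]`` is ``-1``
    exactly for the root; ``children[i]`` lists the child indices of node
    ``i`` (empty for tips); ``edge_length[i]`` is the length of the branch
    above node ``i`` (0.0 and unused for the root); ``label[i]`` is the tip
    label, or ``None`` for unlabelled internal nodes.
    """

    parent: np.ndarray
    children: list[list[int]]
    edge_length: np.ndarray
    label: list[str | None]
    root: int
    _postorder: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        self.edge_length = np.asarray(self.edge_length, dtype=float)
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1 or roots[0] != self.root:
            raise ValueError("tree must have exactly one root (parent == -1)")
        if np.any(self.edge_length[self._nonroot_mask()] < 0):
            raise ValueError("branch lengths must be nonnegative")
        labels = self.tip_labels
        if len(set(labels)) != len(labels) or any(not l for l in labels):
            raise ValueError("tip labels must be unique and nonempty")

    def _nonroot_mask(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.root] = False
        return mask

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tips(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def internal_nodes(self) -> list[int]:
        return [i for i in range(self.n_nodes) if self.children[i]]

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    @property
    def tip_labels(self) -> list[str]:
        return [self.label[i] or "" for i in self.tips]

    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children always before parents)."""
        if self._postorder is None:
            order: list[int] = []
            stack = [self.root]
            while stack:  # iterative reverse-preorder then flip
                v = stack.pop()
                order.append(v)
                stack.extend(self.children[v])
            self._postorder = np.array(order[::-1], dtype=int)
        return self._postorder

    def preorder(self) -> np.ndarray:
        return self.postorder()[::-1]

    def clade_tipsets(self) -> dict[int, frozenset[str]]:
        """Map each node to the frozenset of tip labels it subtends."""
        sets: dict[int, frozenset[str]] = {}
        for v in self.postorder():
            if not self.children[v]:
                sets[v] = frozenset([self.label[v]])  # type: ignore[list-item]
            else:
                acc: frozenset[str] = frozenset()
                for c in self.children[v]:
                    acc = acc | sets[c]
                sets[v] = acc
        return sets

    def bipartitions(self) -> set[frozenset[str]]:
        """Rooted bipartitions: tip-label sets of all internal nodes."""
        sets = self.clade_tipsets()
        return {sets[v] for v in self.internal_nodes}

    def node_depths(self) -> np.ndarray:
        """Path length from the root to each node."""
        depth = np.zeros(self.n_nodes)
        for v in self.preorder():
            if v != self.root:
                depth[v] = depth[self.parent[v]] + self.edge_length[v]
        return depth

    def copy(self) -> "PhyloTree":
        return PhyloTree(
            parent=self.parent.copy(),
            children=[list(c) for c in self.children],
            edge_length=self.edge_length.copy(),
            label=list(self.label),
            root=self.root,
        )


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> PhyloTree:
    nodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=int)
    children: list[list[int]] = [[] for _ in nodes]
    lengths = np.zeros(len(nodes))
    labels: list[str | None] = [None] * len(nodes)
    for i, nd in enumerate(nodes):
        if nd.parent_node is not None:
            p = index[id(nd.parent_node)]
            parent[i] = p
            children[p].append(i)
            if nd.edge.length is None:
                clade = ",".join(
                    sorted(lf.taxon.label for lf in nd.leaf_iter() if lf.taxon)
                ) or "(unlabelled)"
                raise NewickError(f"missing branch length on the clade ({clade})")
            if nd.edge.length < 0:
                raise NewickError("negative branch length in Newick input")
            lengths[i] = nd.edge.length
        if nd.is_leaf():
            if nd.taxon is None or not nd.taxon.label:
                raise NewickError("unlabelled tip in Newick input")
            labels[i] = nd.taxon.label
    return PhyloTree(parent=parent, children=children, edge_length=lengths,
                     label=labels, root=0)


def read_newick(text: str) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`.

    Quoted labels are supported, ``[...]`` comments stripped, internal node
    labels ignored.  Branch lengths are required on every non-root edge; a
    root branch length is ignored.  Raises :class:`NewickError` on malformed
    input, naming the offending clade for a missing length.
    """
    text = text.strip()
    if not text:
        raise NewickError("empty Newick string")
    if text.count("(") != text.count(")"):
        raise NewickError("unbalanced parentheses in Newick string")
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise NewickError(f"could not parse Newick: {exc}") from exc
    if dtree.seed_node is None or (dtree.seed_node.is_leaf()
                                   and dtree.seed_node.taxon is None):
        raise NewickError("Newick string contains no tree")
    return _from_dendropy(dtree)


def read_newick_list(text: str) -> list[PhyloTree]:
    """Read a multi-tree file: one Newick string per non-empty line."""
    trees = [read_newick(line) for line in text.splitlines() if line.strip()]
    if not trees:
        raise NewickError("no trees found")
    return trees


def _needs_quoting(label: str) -> bool:
    return any(ch in label for ch in " \t()[]{}:;,'\"")


def _format_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_newick(tree: PhyloTree) -> str:
    """Serialise to Newick; branch lengths printed to 10 significant digits."""

    out = io.StringIO()

    def emit(v: int) -> None:
        if tree.children[v]:
            out.write("(")
            for k, c in enumerate(tree.children[v]):
                if k:
                    out.write(",")
                emit(c)
            out.write(")")
        else:
            out.write(_format_label(tree.label[v] or ""))
        if v != tree.root:
            out.write(":" + format(tree.edge_length[v], ".10g"))

    emit(tree.root)
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Trait and trial tables
# ---------------------------------------------------------------------------


def read_trait_csv(path_or_buf, n_states: int = 4) -> dict[str, int]:
    """Read a ``tip_label,state`` CSV into a tip-state mapping.

    States must be integers in ``1..n_states`` (note counts per call).
    """
    df = pd.read_csv(path_or_buf, comment="#")
    missing = {"tip_label", "state"} - set(df.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")
    states: dict[str, int] = {}
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        label = str(row.tip_label)
        try:
            s = int(row.state)
        except (TypeError, ValueError):
            raise ValueError(f"non-integer state at row {row_num}") from None
        if not 1 <= s <= n_states:
            raise ValueError(
                f"state {s} at row {row_num} outside 1..{n_states}")
        if label in states:
            raise ValueError(f"duplicate tip label {label!r} at row {row_num}")
        states[label] = s
    return states


def validate_tip_states(tree: PhyloTree, states: dict[str, int]) -> None:
    """Require an exact, case-sensitive match between tree tips and states."""
    tips = set(tree.tip_labels)
    missing = tips - set(states)
    extra = set(states) - tips
    if missing or extra:
        raise ValueError(
            "tree/trait label mismatch: "
            f"tips without state {sorted(missing)}, "
            f"states without tip {sorted(extra)}"
        )


def read_trials_csv(path_or_buf) -> pd.DataFrame:
    """Read and validate a phonotaxis trial table.

    Expected columns: ``population`` (string), ``stimulus_notes`` (integer
    note count of the playback stimulus), ``stimulus_freq_khz`` (positive
    carrier mid-frequency in kHz), ``response`` (1 = male approached the
    speaker, 0 = failed to recognise the stimulus).  Rows violating the
    contract raise ``ValueError`` naming the offending row.
    """
    df = pd.read_csv(path_or_buf, comment="#")
    missing = set(TRIAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    df = df[list(TRIAL_COLUMNS)].copy()
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        if row.response not in (0, 1):
            raise ValueError(
                f"response {row.response!r} at row {row_num} is not 0/1")
        if not row.stimulus_freq_khz > 0:
            raise ValueError(
                f"nonpositive stimulus_freq_khz at row {row_num}")
        if int(row.stimulus_notes) != row.stimulus_notes or row.stimulus_notes < 1:
            raise ValueError(
                f"stimulus_notes {row.stimulus_notes!r} at row {row_num} "
                "is not a positive integer")
    df["stimulus_notes"] = df["stimulus_notes"].astype(int)
    df["response"] = df["response"].astype(int)
    df["population"] = df["population"].astype(str)
    return df
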