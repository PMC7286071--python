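"""Weighted binary Fitch parsimony with ACCTRAN/DELTRAN resolution.

Characters are binary (modification ON/OFF) with equal, undirected change
costs, so the parsimony length of a pattern is computed with the two-state
min-cost recurrence, which handles multifurcations exactly.  All passes are
vectorized across site patterns; pattern weights (bp) multiply lengths into
the weighted parsimony score.

Ambiguity among most-parsimonious reconstructions (MPRs) is resolved
deterministically: ACCTRAN prefers a state different from the parent when
both choices stay minimal (changes pushed toward the root), DELTRAN prefers
the parent's state (changes delayed toward the tips).  A root-state tie is
resolved to OFF.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .cell_type_tree import CellTypeTree, Node

ACCTRAN = "ACCTRAN"
DELTRAN = "DELTRAN"

GAIN = "GAIN"  # OFF -> ON
LOSS = "LOSS"  # ON -> OFF

_BIG = np.int64(1) << 40


@dataclass
class TreeIndex:
    """Postorder array view of a rooted tree for vectorized passes."""

    nodes: list[Node]          # postorder; root last
    parent: np.ndarray         # index into nodes; -1 for root
    leaf_col: np.ndarray       # sample column per node; -1 for internal
    labels: list[str]

    @classmethod
    def build(cls, root: Node, sample_ids: list[str]) -> "TreeIndex":
        nodes = list(root.postorder())
        pos = {id(n): i for i, n in enumerate(nodes)}
        col = {s: j for j, s in enumerate(sample_ids)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        leaf_col = np.full(len(nodes), -1, dtype=np.int64)
        for i, n in enumerate(nodes):
            if n.parent is not None:
                parent[i] = pos[id(n.parent)]
            if n.is_leaf:
                if n.label not in col:
                    raise ValueError(f"leaf {n.label!r} has no state column")
                leaf_col[i] = col[n.label]
        return cls(
            nodes=nodes,
            parent=parent,
            leaf_col=leaf_col,
            labels=[n.label for n in nodes],
        )

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


def _up_costs(index: TreeIndex, states: np.ndarray) -> np.ndarray:
    """Min changes in the subtree below each node given the node's state.

    Returns ``up`` of shape (n_nodes, P, 2); leaves cost 0 for their
    observed state and effectively-infinite otherwise.
    """
    n_nodes = index.n_nodes
    n_pat = states.shape[0]
    up = np.zeros((n_nodes, n_pat, 2), dtype=np.int64)
    for i in range(n_nodes):
        c = index.leaf_col[i]
        if c >= 0:
            s = states[:, c].astype(np.int64)
            up[i, :, 0] = s * _BIG
            up[i, :, 1] = (1 - s) * _BIG
    # children accumulate into parents; postorder guarantees children first
    for i in range(n_nodes - 1):
        p = index.parent[i]
        child = up[i]
        up[p, :, 0] += np.minimum(child[:, 0], child[:, 1] + 1)
        up[p, :, 1] += np.minimum(child[:, 1], child[:, 0] + 1)
    return up


def fitch_lengths(index: TreeIndex, states: np.ndarray) -> np.ndarray:
    """Parsimony length per pattern (vector over P patterns)."""
    up = _up_costs(index, states)
    return up[-1].min(axis=1)


def fitch_score(root: Node, sample_ids: list[str], pattern: np.ndarray) -> int:
    """Parsimony length of a single binary pattern on a rooted tree.

    The score is invariant to root placement (undirected equal costs).
    """
    index = TreeIndex.build(root, sample_ids)
    states = np.asarray(pattern, dtype=np.uint8).reshape(1, -1)
    return int(fitch_lengths(index, states)[0])


def weighted_score(root: Node, matrix) -> int:
    """Weighted parsimony score: sum of pattern_weight x pattern length.

    Constant patterns have zero length and are skipped.
    """
    variable = matrix.is_variable
    if not variable.any():
        return 0
    index = TreeIndex.build(root, matrix.sample_ids)
    lengths = fitch_lengths(index, matrix.patterns[variable])
    return int((lengths * matrix.weights[variable]).sum())


def mpr_state_sets(index: TreeIndex, states: np.ndarray) -> np.ndarray:
    """Per-node MPR state sets: (n_nodes, P, 2) boolean, True when the state
    appears in at least one most-parsimonious labeling."""
    up = _up_costs(index, states)
    n_nodes, n_pat = index.n_nodes, states.shape[0]
    down = np.zeros((n_nodes, n_pat, 2), dtype=np.int64)
    # rest-of-tree cost for each node state, computed root-down
    for i in range(n_nodes - 2, -1, -1):
        p = index.parent[i]
        child = up[i]
        contrib = np.stack(
            [
                np.minimum(child[:, 0], child[:, 1] + 1),
                np.minimum(child[:, 1], child[:, 0] + 1),
            ],
            axis=1,
        )
        parent_total = up[p] + down[p] - contrib  # parent cost without this child
        down[i, :, 0] = np.minimum(parent_total[:, 0], parent_total[:, 1] + 1)
        down[i, :, 1] = np.minimum(parent_total[:, 1], parent_total[:, 0] + 1)
    total = up + down
    best = total.min(axis=2, keepdims=True)
    return total == best


def resolve(index: TreeIndex, states: np.ndarray, algorithm: str = ACCTRAN) -> np.ndarray:
    """A single MPR labeling per pattern: (n_nodes, P) uint8.

    Root ties resolve to OFF; elsewhere ACCTRAN prefers the state opposite
    to the parent and DELTRAN the parent's state whenever both keep the
    labeling minimal.
    """
    if algorithm not in (ACCTRAN, DELTRAN):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    up = _up_costs(index, states)
    n_nodes, n_pat = index.n_nodes, states.shape[0]
    labeling = np.zeros((n_nodes, n_pat), dtype=np.uint8)
    root = n_nodes - 1
    # root: minimal total cost, tie -> 0 (OFF)
    labeling[root] = (up[root, :, 1] < up[root, :, 0]).astype(np.uint8)
    for i in range(n_nodes - 2, -1, -1):
        p = index.parent[i]
        ps = labeling[p].astype(np.int64)
        cost0 = up[i, :, 0] + (ps != 0)
        cost1 = up[i, :, 1] + (ps != 1)
        pick1 = cost1 < cost0
        tie = cost1 == cost0
        if algorithm == ACCTRAN:
            labeling[i] = np.where(tie, 1 - ps, pick1.astype(np.int64)).astype(np.uint8)
        else:
            labeling[i] = np.where(tie, ps, pick1.astype(np.int64)).astype(np.uint8)
    return labeling


@dataclass
class AncestralReconstruction:
    """Resolved ancestral states and per-edge changes for every pattern."""

    algorithm: str
    tree: CellTypeTree
    index: TreeIndex
    pattern_ids: np.ndarray       # indices into the matrix patterns
    node_states: np.ndarray       # (n_nodes, P_variable) uint8
    lengths: np.ndarray           # Fitch length per variable pattern
    weights: np.ndarray           # bp weight per variable pattern
    constant_on: np.ndarray       # pattern ids of constant-ON patterns

    @property
    def parsimony_score(self) -> int:
        return int((self.lengths * self.weights).sum())

    def node_index(self, label: str) -> int:
        return self.index.labels.index(label)

    def states_for_node(self, label: str, n_patterns: int) -> np.ndarray:
        """Full-length per-pattern 0/1 state vector at one internal node
        (constant patterns included)."""
        full = np.zeros(n_patterns, dtype=np.uint8)
        full[self.pattern_ids] = self.node_states[self.node_index(label)]
        full[self.constant_on] = 1
        return full

    def edge_changes(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per edge name: boolean (gain, loss) arrays over variable patterns.

        The two half-edges at the root are merged into the single unrooted
        branch between the root's children.
        """
        idx = self.index
        n_nodes = idx.n_nodes
        root = n_nodes - 1
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        root_children = [i for i in range(n_nodes - 1) if idx.parent[i] == root]
        merge_root = len(root_children) == 2
        for i in range(n_nodes - 1):
            parent_states = self.node_states[idx.parent[i]]
            child_states = self.node_states[i]
            gain = (parent_states == 0) & (child_states == 1)
            loss = (parent_states == 1) & (child_states == 0)
            name = self.tree.edge_name(idx.nodes[i])
            if merge_root and idx.parent[i] == root:
                if name in out:
                    prev_gain, prev_loss = out[name]
                    gain, loss = prev_gain | gain, prev_loss | loss
            out[name] = (gain, loss)
        return out


def reconstruct(
    matrix, tree: CellTypeTree, algorithm: str = ACCTRAN
) -> AncestralReconstruction:
    """Run the two-pass reconstruction over all variable patterns."""
    index = TreeIndex.build(tree.root, matrix.sample_ids)
    variable = matrix.is_variable
    pattern_ids = np.nonzero(variable)[0]
    states = matrix.patterns[variable]
    if states.shape[0]:
        labeling = resolve(index, states, algorithm)
        lengths = fitch_lengths(index, states)
    else:
        labeling = np.zeros((index.n_nodes, 0), dtype=np.uint8)
        lengths = np.zeros(0, dtype=np.int64)
    constant_on = np.nonzero(~variable & (matrix.patterns.max(axis=1) == 1))[0] if matrix.n_patterns else np.zeros(0, dtype=np.int64)
    return AncestralReconstruction(
        algorithm=algorithm,
        tree=tree,
        index=index,
        pattern_ids=pattern_ids,
        node_states=labeling,
        lengths=lengths,
        weights=matrix.weights[variable],
        constant_on=constant_on,
    )


def map_changes(recon: AncestralReconstruction) -> pd.DataFrame:
    """Long-format per-edge, per-pattern change calls."""
    rows = []
    for edge, (gain, loss) in recon.edge_changes().items():
        for kind, mask in ((GAIN, gain), (LOSS, loss)):
            for k in np.nonzero(mask)[0]:
                rows.append(
                    {
                        "edge": edge,
                        "pattern_id": int(recon.pattern_ids[k]),
                        "change": kind,
                        "weight_bp": int(recon.weights[k]),
                    }
                )
    return pd.DataFrame(rows, columns=["edge", "pattern_id", "change", "weight_bp"])


def aggregate_changes(
    recon: AncestralReconstruction, modification: str = "", classes: str | None = None
) -> pd.DataFrame:
    """Per-branch GAIN ("ON") / LOSS ("OFF") bp table.

    Rows are (modification, change direction); columns are branch names.
    ``classes`` restricts to INTER or INTRA edges.
    """
    idx = recon.index
    tree = recon.tree
    cols: dict[str, dict[str, int]] = {}
    for i in range(idx.n_nodes - 1):
        node = idx.nodes[i]
        if classes is not None and tree.edge_class(node) != classes:
            continue
        cols.setdefault(tree.edge_name(node), {"ON": 0, "OFF": 0})
    for edge, (gain, loss) in recon.edge_changes().items():
        if edge not in cols:
            continue
        cols[edge]["ON"] += int(recon.weights[gain].sum())
        cols[edge]["OFF"] += int(recon.weights[loss].sum())
    table = pd.DataFrame(cols)
    table.insert(0, "change", ["ON", "OFF"])
    table.insert(0, "modification", modification)
    return table


def brute_force_oracle(
    root: Node, sample_ids: list[str], pattern: np.ndarray
) -> tuple[int, list[tuple[int, ...]]]:
    """Exhaustively enumerate all MPR labelings (test oracle, small trees).

    Returns the minimum change count and every labeling achieving it, as
    state tuples in postorder node order — the same order used by
    :class:`TreeIndex`, so oracle labelings align with :func:`resolve`
    output rows.
    """
    nodes = list(root.postorder())
    internal = [n for n in nodes if not n.is_leaf]
    if len(internal) > 16:
        raise ValueError("tree too large for exhaustive enumeration")
    col = {s: j for j, s in enumerate(sample_ids)}
    leaf_state = {
        id(n): int(pattern[col[n.label]]) for n in nodes if n.is_leaf
    }
    best = None
    labelings: list[tuple[int, ...]] = []
    for assignment in product((0, 1), repeat=len(internal)):
        state = dict(leaf_state)
        for n, s in zip(internal, assignment):
            state[id(n)] = s
        changes = sum(
            1
            for n in nodes
            if n.parent is not None and state[id(n)] != state[id(n.parent)]
        )
        if best is None or changes < best:
            best = changes
            labelings = []
        if changes == best:
            labelings.append(tuple(state[id(n)] for n in nodes))
    return best, labelings
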