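"""Cell-type trees: newick I/O, monophyly/backbone constraints, branch
classes, and constrained parsimony tree search.

A cell-type tree plays the role of a species tree for differentiation:
leaves are samples of differentiated cells, internal nodes are progenitor
states.  The inter-type topology (the hematopoiesis backbone) is fixed and
each cell type's samples are constrained to be monophyletic; only the
within-type arrangements are searched.

Branch classes follow the differentiation reading: an edge strictly inside
one cell type's clade is INTRA (tissue/individual/subtype variation);
every other edge — type stems and the lineage backbone — is INTER.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np

INTER = "INTER"
INTRA = "INTRA"

#: The traditional hierarchical model of hematopoiesis over eight cell types.
HEMATOPOIESIS_BACKBONE = "(((Er,Me)ErMe,((Eo,Ne)EoNe,Mo)EoNeMo)M,(Nk,T,B)L)root;"


class Node:
    """Lightweight rooted-tree node; leaves carry sample ids as labels."""

    __slots__ = ("label", "children", "parent")

    def __init__(self, label: str | None = None, children=None):
        self.label = label
        self.children: list[Node] = []
        self.parent: Node | None = None
        for child in children or []:
            self.add_child(child)

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def remove_child(self, child: "Node") -> None:
        self.children.remove(child)
        child.parent = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self):
        for child in self.children:
            yield from child.postorder()
        yield self

    def preorder(self):
        yield self
        for child in self.children:
            yield from child.preorder()

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> frozenset:
        return frozenset(n.label for n in self.leaves())

    def copy(self) -> "Node":
        clone = Node(self.label)
        for child in self.children:
            clone.add_child(child.copy())
        return clone

    def __repr__(self):
        return f"Node({self.label!r}, leaves={len(self.leaves())})"


def parse_newick(text: str) -> Node:
    """Parse newick (multifurcations and internal labels allowed)."""
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels: {exc}") from exc
    except Exception as exc:  # malformed newick (unbalanced parentheses, ...)
        raise ValueError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            return Node(dnode.taxon.label if dnode.taxon else dnode.label)
        node = Node(dnode.label)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    labels = [n.label for n in root.leaves()]
    if None in labels:
        raise ValueError("newick contains an unlabeled leaf")
    dupes = {x for x in labels if labels.count(x) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return root


def render_newick(root: Node) -> str:
    """Serialize a tree, preserving internal-node labels."""
    buf = io.StringIO()

    def write(node: Node):
        if node.is_leaf:
            buf.write(node.label)
            return
        buf.write("(")
        for i, child in enumerate(node.children):
            if i:
                buf.write(",")
            write(child)
        buf.write(")")
        if node.label:
            buf.write(node.label)

    write(root)
    buf.write(";")
    return buf.getvalue()


@dataclass
class ConstraintSet:
    """Fixed backbone over cell types plus per-type monophyly groups."""

    backbone_newick: str
    samples_by_type: dict[str, list[str]]

    def __post_init__(self):
        backbone = parse_newick(self.backbone_newick)
        types = {n.label for n in backbone.leaves()}
        declared = set(self.samples_by_type)
        if types != declared:
            raise ValueError(
                f"backbone leaves {sorted(types)} != declared types {sorted(declared)}"
            )
        empty = [t for t, s in self.samples_by_type.items() if not s]
        if empty:
            raise ValueError(f"cell types with zero samples: {empty}")
        seen: set[str] = set()
        for samples in self.samples_by_type.values():
            overlap = seen & set(samples)
            if overlap:
                raise ValueError(f"samples in more than one type: {sorted(overlap)}")
            seen |= set(samples)

    @property
    def backbone(self) -> Node:
        return parse_newick(self.backbone_newick)


@dataclass
class CellTypeTree:
    """A rooted cell-type tree plus the sample-to-type map and edge classes."""

    root: Node
    sample_to_type: dict[str, str]
    edge_classes: dict[int, str] = field(default_factory=dict)  # id(node) -> class

    def __post_init__(self):
        if not self.edge_classes:
            self.edge_classes = classify_branches(self.root, self.sample_to_type)

    @property
    def types(self) -> set[str]:
        return set(self.sample_to_type.values())

    def nodes(self):
        return list(self.root.postorder())

    def internal_nodes(self):
        return [n for n in self.root.postorder() if not n.is_leaf]

    def edge_class(self, child: Node) -> str:
        return self.edge_classes[id(child)]

    def type_mrca(self, cell_type: str) -> Node:
        samples = {s for s, t in self.sample_to_type.items() if t == cell_type}
        return mrca(self.root, samples)

    def edge_name(self, child: Node) -> str:
        """Name of the edge above ``child``; the two root half-edges share
        one merged name (e.g. M-L), matching the unrooted branch."""
        parent = child.parent
        if parent is self.root and len(self.root.children) == 2:
            a, b = self.root.children
            return f"{_node_name(a)}-{_node_name(b)}"
        return f"{_node_name(parent)}-{_node_name(child)}"

    def newick(self) -> str:
        return render_newick(self.root)


def _node_name(node: Node) -> str:
    return node.label if node.label else f"n{id(node) % 100000}"


def mrca(root: Node, labels: set[str]) -> Node:
    """Most recent common ancestor of a set of leaf labels."""
    want = set(labels)
    best = None

    def below(node: Node) -> frozenset:
        nonlocal best
        if node.is_leaf:
            got = frozenset([node.label]) & want
        else:
            got = frozenset().union(*(below(c) for c in node.children))
        if got == want and best is None:
            best = node
        return got

    below(root)
    if best is None:
        raise ValueError(f"labels not all present: {sorted(want)}")
    return best


def check_monophyly(root: Node, sample_to_type: dict[str, str]) -> None:
    """Raise (naming the type) if any cell type's samples are not a clade."""
    by_type: dict[str, set[str]] = {}
    for sample, ctype in sample_to_type.items():
        by_type.setdefault(ctype, set()).add(sample)
    for ctype, samples in by_type.items():
        node = mrca(root, samples)
        if node.leaf_labels() != frozenset(samples):
            raise ValueError(f"cell type {ctype!r} is not monophyletic")


def classify_branches(root: Node, sample_to_type: dict[str, str]) -> dict[int, str]:
    """Classify every edge (keyed by child node id) as INTER or INTRA.

    Edges strictly below a cell type's MRCA are INTRA; type stems, the
    backbone, and the root half-edges are INTER.
    """
    check_monophyly(root, sample_to_type)
    by_type: dict[str, set[str]] = {}
    for sample, ctype in sample_to_type.items():
        by_type.setdefault(ctype, set()).add(sample)
    intra_nodes: set[int] = set()
    for samples in by_type.values():
        top = mrca(root, samples)
        for node in top.postorder():
            if node is not top:
                intra_nodes.add(id(node))
    classes: dict[int, str] = {}
    for node in root.postorder():
        if node.parent is None:
            continue
        classes[id(node)] = INTRA if id(node) in intra_nodes else INTER
    return classes


def expand_backbone(
    constraints: ConstraintSet,
    intra_subtrees: dict[str, Node] | None = None,
    rng: np.random.Generator | None = None,
) -> Node:
    """Replace each backbone type leaf by a clade over its samples.

    ``intra_subtrees`` supplies a fixed within-type topology per type;
    otherwise single samples attach directly and multi-sample types get a
    random (seeded) caterpillar arrangement.
    """
    rng = rng or np.random.default_rng(1)
    root = constraints.backbone
    for leaf in list(root.leaves()):
        ctype = leaf.label
        samples = list(constraints.samples_by_type[ctype])
        if intra_subtrees and ctype in intra_subtrees:
            sub = intra_subtrees[ctype].copy()
            if sub.leaf_labels() != frozenset(samples):
                raise ValueError(f"intra subtree for {ctype!r} has wrong samples")
        elif len(samples) == 1:
            sub = Node(samples[0])
        else:
            order = list(rng.permutation(samples))
            sub = Node(None, [Node(order[0]), Node(order[1])])
            for sample in order[2:]:
                sub = Node(None, [sub, Node(sample)])
        # the clade keeps the type name on its stem node when it is internal
        if sub.is_leaf:
            leaf.label = sub.label
        else:
            leaf.label = ctype
            for child in sub.children:
                leaf.add_child(child)
    _autolabel(root)
    return root


def _autolabel(root: Node) -> None:
    """Give anonymous internal nodes deterministic names for reporting."""
    counter = 0
    for node in root.preorder():
        if not node.is_leaf and not node.label:
            counter += 1
            node.label = f"node{counter}"


def build_tree(
    constraints: ConstraintSet,
    intra_subtrees: dict[str, Node] | None = None,
    seed: int = 1,
) -> CellTypeTree:
    """Build the full sample tree from backbone constraints (no search)."""
    root = expand_backbone(
        constraints, intra_subtrees, rng=np.random.default_rng(seed)
    )
    sample_to_type = {
        s: t for t, ss in constraints.samples_by_type.items() for s in ss
    }
    return CellTypeTree(root=root, sample_to_type=sample_to_type)


def splits(root: Node) -> set[frozenset]:
    """Non-trivial clades (leaf-label sets) of a rooted tree."""
    all_leaves = root.leaf_labels()
    out = set()
    for node in root.postorder():
        labels = node.leaf_labels()
        if 1 < len(labels) < len(all_leaves):
            out.add(labels)
    return out


# ---------------------------------------------------------------------------
# Constrained heuristic search
# ---------------------------------------------------------------------------


def _tree_score(root: Node, matrix) -> int:
    from .parsimony import weighted_score

    return weighted_score(root, matrix)


def _prune(node: Node) -> Node:
    """Detach ``node``; suppress its parent if left with a single child.

    Returns the root of the clade after pruning (parent chain preserved).
    """
    parent = node.parent
    parent.remove_child(node)
    if len(parent.children) == 1 and parent.parent is not None:
        grand = parent.parent
        only = parent.children[0]
        parent.remove_child(only)
        idx = grand.children.index(parent)
        grand.remove_child(parent)
        grand.children.insert(idx, only)
        only.parent = grand
    return node


def _regraft(subtree: Node, edge_child: Node) -> None:
    """Insert ``subtree`` on the edge above ``edge_child``."""
    parent = edge_child.parent
    idx = parent.children.index(edge_child)
    parent.remove_child(edge_child)
    joint = Node(None, [edge_child, subtree])
    joint.parent = parent
    parent.children.insert(idx, joint)


def _reroot_copy(root: Node, target: Node) -> Node:
    """A new rooted copy of ``root`` with the root placed on the edge above
    ``target``.  Degree-2 remnants of the old root are suppressed."""

    def down(n: Node) -> Node:
        clone = Node(n.label)
        for child in n.children:
            clone.add_child(down(child))
        return clone

    def up(n: Node, exclude: Node) -> Node:
        kids = [down(k) for k in n.children if k is not exclude]
        if n.parent is not None:
            kids.append(up(n.parent, n))
        if len(kids) == 1:
            return kids[0]
        node = Node(None)
        for k in kids:
            node.add_child(k)
        return node

    new = Node(None)
    new.add_child(down(target))
    new.add_child(up(target.parent, target))
    return new


def _rerootings(subtree: Node) -> list[Node]:
    """Distinct rootings of a detached subtree (the TBR reconnection side)."""
    leaves = subtree.leaf_labels()
    if subtree.is_leaf or len(leaves) <= 2:
        return [subtree]
    out = [subtree]
    seen = {
        frozenset([subtree.children[0].leaf_labels(), leaves - subtree.children[0].leaf_labels()])
    }
    for node in list(subtree.postorder()):
        if node is subtree:
            continue
        part = frozenset([node.leaf_labels(), leaves - node.leaf_labels()])
        if part in seen:
            continue
        seen.add(part)
        out.append(_reroot_copy(subtree, node))
    return out


def _find_by_leafset(scope: Node, labels: frozenset) -> Node:
    for node in scope.postorder():
        if node.leaf_labels() == labels:
            return node
    raise ValueError("node not found by leaf set")


def _clade_neighbors(root: Node, samples: set[str]):
    """Yield TBR rearrangements of one type clade as whole-tree copies.

    Each move bisects an edge inside the clade, reroots the detached part
    on any of its edges, and reconnects it on any remaining within-clade
    edge (including the clade stem) — monophyly holds by construction.
    """
    clade = mrca(root, samples)
    cut_sets = [n.leaf_labels() for n in clade.postorder() if n is not clade]
    for cut_labels in cut_sets:
        remaining = frozenset(samples - set(cut_labels))
        if not remaining:
            continue
        base = root.copy()
        cut = _find_by_leafset(_find_by_leafset(base, frozenset(samples)), cut_labels)
        detached = _prune(cut)
        rem_root = _find_by_leafset(base, remaining)
        targets = [n.leaf_labels() for n in rem_root.postorder()]
        for rooted in _rerootings(detached):
            for target_labels in targets:
                cand = base.copy()
                _regraft(rooted.copy(), _find_by_leafset(cand, target_labels))
                yield cand


def constrained_search(
    matrix,
    constraints: ConstraintSet,
    seed: int = 1,
    max_rounds: int = 200,
) -> CellTypeTree:
    """Heuristic parsimony search over the unconstrained (within-type) parts.

    Random-addition-sequence stepwise insertion inside each type clade,
    then TBR swaps restricted to within-clade edges with first-improvement
    acceptance, iterated to a local optimum.  Proposals breaking monophyly
    or the fixed backbone are never generated.  Deterministic given
    ``seed``; accepted swaps never increase the weighted parsimony score.
    """
    rng = np.random.default_rng(seed)
    sample_to_type = {
        s: t for t, ss in constraints.samples_by_type.items() for s in ss
    }

    # --- random-addition stepwise insertion, one type at a time ------------
    root = constraints.backbone
    type_leaf = {leaf.label: leaf for leaf in root.leaves()}
    pending: dict[str, list[str]] = {}
    for ctype, samples in constraints.samples_by_type.items():
        order = [samples[i] for i in rng.permutation(len(samples))]
        leaf = type_leaf[ctype]
        if len(order) == 1:
            leaf.label = order[0]
            pending[ctype] = []
        else:
            leaf.label = None
            leaf.add_child(Node(order[0]))
            leaf.add_child(Node(order[1]))
            pending[ctype] = order[2:]
    for ctype, rest in pending.items():
        for sample in rest:
            placed = set(constraints.samples_by_type[ctype]) & root.leaf_labels()
            clade = mrca(root, placed)
            best, best_score = None, None
            for edge_child in [n for n in clade.postorder() if n is not clade]:
                _regraft(Node(sample), edge_child)
                score = _tree_score(root, matrix)
                if best_score is None or score < best_score:
                    best_score, best = score, edge_child
                _undo_regraft(edge_child)
            _regraft(Node(sample), best)

    # --- TBR to local optimum ----------------------------------------------
    current = _tree_score(root, matrix)
    for _ in range(max_rounds):
        improved = False
        for ctype, samples in constraints.samples_by_type.items():
            if len(samples) < 3:
                continue
            for cand in _clade_neighbors(root, set(samples)):
                score = _tree_score(cand, matrix)
                if score < current:
                    root, current = cand, score
                    improved = True
                    break
            if improved:
                break
        if not improved:
            break

    # rebuild with canonical labels from the backbone + found intra topologies
    intra_subtrees = {}
    for ctype, samples in constraints.samples_by_type.items():
        if len(samples) > 1:
            intra_subtrees[ctype] = mrca(root, set(samples)).copy()
            intra_subtrees[ctype].label = None
    return build_tree(constraints, intra_subtrees, seed=seed)


def _undo_regraft(edge_child: Node) -> None:
    """Reverse :func:`_regraft`: remove the joint node above ``edge_child``."""
    joint = edge_child.parent
    parent = joint.parent
    idx = parent.children.index(joint)
    other = [c for c in joint.children if c is not edge_child][0]
    joint.remove_child(edge_child)
    joint.remove_child(other)
    parent.remove_child(joint)
    parent.children.insert(idx, edge_child)
    edge_child.parent = parent
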