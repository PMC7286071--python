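"""Gene-set over-representation per branch group (compareCluster analog).

Changed segments are grouped by branch (all inter-type branches pooled,
each inter-type branch separately, and each cell type's intra-type
branches), mapped to genes via body/promoter overlap, and tested for
over-representation against GMT gene sets with the hypergeometric upper
tail and Benjamini-Hochberg control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cell_type_tree import INTER
from .change_annotation import GeneModel
from .parsimony import GAIN, AncestralReconstruction


@dataclass
class GeneSetDB:
    """Named gene sets over a gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    min_size: int = 5
    max_size: int = 500
    dropped: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_gmt(
        cls, path, universe: set[str], min_size: int = 5, max_size: int = 500
    ) -> "GeneSetDB":
        """Read GMT (set name, description, genes...) and harmonize to the
        universe; out-of-universe ids are dropped with a warning."""
        raw: dict[str, set[str]] = {}
        with open(path) as fh:
            for line in fh:
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 3:
                    continue
                raw[fields[0]] = set(fields[2:]) - {""}
        return cls.harmonize(raw, universe, min_size, max_size)

    @classmethod
    def harmonize(
        cls, raw: dict[str, set[str]], universe: set[str], min_size=5, max_size=500
    ) -> "GeneSetDB":
        sets = {}
        dropped = {}
        for name, genes in raw.items():
            outside = genes - universe
            if outside:
                dropped[name] = len(outside)
            kept = genes & universe
            if min_size <= len(kept) <= max_size:
                sets[name] = kept
        if dropped:
            warnings.warn(
                f"dropped out-of-universe gene ids from {len(dropped)} sets",
                stacklevel=2,
            )
        return cls(sets=sets, universe=set(universe), min_size=min_size,
                   max_size=max_size, dropped=dropped)


class GeneIntervalIndex:
    """Overlap queries of segments against gene bodies + promoter windows."""

    def __init__(self, genes: list[GeneModel], promoter_window: int = 3000):
        self.promoter_window = promoter_window
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, list[str]]] = {}
        per_chrom: dict[str, list[tuple[int, int, str]]] = {}
        for gene in genes:
            lo = min(gene.start, gene.tss - promoter_window)
            hi = max(gene.end, gene.tss + promoter_window + 1)
            per_chrom.setdefault(gene.chrom, []).append((max(0, lo), hi, gene.gene_id))
        for chrom, rows in per_chrom.items():
            rows.sort()
            starts = np.array([r[0] for r in rows])
            ends = np.array([r[1] for r in rows])
            self.by_chrom[chrom] = (starts, ends, [r[2] for r in rows])

    def overlapping(self, chrom: str, start: int, end: int) -> set[str]:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return set()
        starts, ends, ids = entry
        # candidate genes: start < end_of_segment and end > start_of_segment
        hi = int(np.searchsorted(starts, end, side="left"))
        hits = np.nonzero(ends[:hi] > start)[0]
        return {ids[k] for k in hits}


def assign_genes(
    segments_by_group: dict[str, list[tuple[str, int, int]]],
    genes: list[GeneModel],
    promoter_window: int = 3000,
) -> dict[str, set[str]]:
    """Gene set per branch group: a gene is assigned when at least one
    changed segment overlaps its body or promoter window (TSS +/- window)."""
    index = GeneIntervalIndex(genes, promoter_window)
    out = {}
    for group, segments in segments_by_group.items():
        hit: set[str] = set()
        for chrom, start, end in segments:
            hit |= index.overlapping(chrom, start, end)
        out[group] = hit
    return out


def branch_groups(
    recon: AncestralReconstruction, matrix, direction: str = GAIN
) -> dict[str, list[tuple[str, int, int]]]:
    """Changed segments per reporting group, following the per-branch
    exclusivity reading: a pattern contributes to a branch's group only if
    that branch carries its only change(s) of the requested direction and
    no other branch changes at all; "Inter (all)" pools patterns whose
    changes are confined to inter-type branches.
    """
    tree = recon.tree
    idx = recon.index
    n_var = recon.node_states.shape[1]
    edge_hits: dict[str, np.ndarray] = {}
    inter_any = np.zeros(n_var, dtype=bool)
    intra_any = np.zeros(n_var, dtype=bool)
    changed_any = np.zeros(n_var, dtype=bool)
    for edge, (gain, loss) in recon.edge_changes().items():
        changed = gain | loss
        wanted = gain if direction == GAIN else loss
        edge_hits.setdefault(edge, np.zeros(n_var, dtype=bool))
        edge_hits[edge] |= wanted
        changed_any |= changed
    for i in range(idx.n_nodes - 1):
        node = idx.nodes[i]
        parent_states = recon.node_states[idx.parent[i]]
        changed = parent_states != recon.node_states[i]
        if tree.edge_class(node) == INTER:
            inter_any |= changed
        else:
            intra_any |= changed

    groups: dict[str, np.ndarray] = {}
    groups["Inter (all)"] = inter_any & ~intra_any & _any_direction(recon, direction)
    edge_class = {}
    for i in range(idx.n_nodes - 1):
        node = idx.nodes[i]
        edge_class[tree.edge_name(node)] = tree.edge_class(node)
    n_changes = np.zeros(n_var, dtype=np.int64)
    for edge, (gain, loss) in recon.edge_changes().items():
        n_changes += (gain | loss).astype(np.int64)
    for edge, hits in edge_hits.items():
        if edge_class.get(edge) == INTER:
            groups[edge] = hits & (n_changes == 1)
    for ctype in sorted(tree.types):
        top = tree.type_mrca(ctype)
        mask = np.zeros(n_var, dtype=bool)
        for i in range(idx.n_nodes - 1):
            node = idx.nodes[i]
            if tree.edge_class(node) == INTER:
                continue
            if _is_descendant(node, top):
                parent_states = recon.node_states[idx.parent[i]]
                child_states = recon.node_states[i]
                wanted = (
                    (parent_states == 0) & (child_states == 1)
                    if direction == GAIN
                    else (parent_states == 1) & (child_states == 0)
                )
                mask |= wanted
        groups[f"Intra {ctype}"] = mask & intra_any & ~inter_any

    out: dict[str, list[tuple[str, int, int]]] = {}
    for group, mask in groups.items():
        pattern_ids = set(int(p) for p in recon.pattern_ids[mask])
        if not pattern_ids:
            out[group] = []
            continue
        segs = []
        for chrom, (bounds, sidx) in matrix.segments.items():
            for k in np.nonzero(np.isin(sidx, list(pattern_ids)))[0]:
                segs.append((chrom, int(bounds[k]), int(bounds[k + 1])))
        out[group] = segs
    return out


def _any_direction(recon: AncestralReconstruction, direction: str) -> np.ndarray:
    n_var = recon.node_states.shape[1]
    mask = np.zeros(n_var, dtype=bool)
    for _, (gain, loss) in recon.edge_changes().items():
        mask |= gain if direction == GAIN else loss
    return mask


def _is_descendant(node, ancestor) -> bool:
    while node is not None:
        if node is ancestor:
            return True
        node = node.parent
    return False


def ora_test(group_genes: set[str], gene_set: set[str], universe: set[str]) -> float:
    """Hypergeometric upper-tail over-representation p-value: P(X >= k)."""
    if not group_genes:
        raise ValueError("empty gene group")
    if not gene_set <= universe:
        raise ValueError("gene set extends beyond the universe")
    m = len(universe)
    n_set = len(gene_set)
    n_group = len(group_genes & universe)
    k = len(group_genes & gene_set)
    return float(stats.hypergeom.sf(k - 1, m, n_set, n_group))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrichment_table(
    genes_by_group: dict[str, set[str]],
    db: GeneSetDB,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Long-format ORA results across (group, set) pairs with BH control.

    BH adjustment is applied within each group (one family per cluster,
    as compareCluster does).
    """
    rows = []
    for group, group_genes in genes_by_group.items():
        group_in_universe = group_genes & db.universe
        if not group_in_universe:
            continue
        for name, gene_set in db.sets.items():
            k = len(group_in_universe & gene_set)
            rows.append(
                {
                    "group": group,
                    "gene_set": name,
                    "k": k,
                    "group_size": len(group_in_universe),
                    "set_size": len(gene_set),
                    "universe_size": len(db.universe),
                    "p": ora_test(group_in_universe, gene_set, db.universe),
                    "gene_ratio": k / len(group_in_universe),
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "group",
            "gene_set",
            "k",
            "group_size",
            "set_size",
            "universe_size",
            "p",
            "gene_ratio",
        ],
    )
    if len(table):
        table["p_adj"] = np.nan
        for group, sub in table.groupby("group"):
            table.loc[sub.index, "p_adj"] = bh_adjust(sub["p"].to_numpy())
        table["significant"] = table["p_adj"] < alpha
    else:
        table["p_adj"] = pd.Series(dtype=float)
        table["significant"] = pd.Series(dtype=bool)
    return table
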