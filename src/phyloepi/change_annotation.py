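"""TSS-relative annotation of reconstructed changes and the inter- vs
intra-branch comparison.

Changed sites are classified by branch exclusivity (changes confined to
inter-type branches vs confined to intra-type branches), annotated with the
signed distance from the segment midpoint to the nearest gene TSS, binned
into twelve upstream/downstream distance categories, and the two weighted
distance distributions are compared with a two-sample Kolmogorov-Smirnov
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .cell_type_tree import INTER, INTRA
from .parsimony import AncestralReconstruction

INTER_ONLY = "INTER_ONLY"
INTRA_ONLY = "INTRA_ONLY"
MIXED = "MIXED"
NO_CHANGE = "NO_CHANGE"

#: Distance-band edges in bp; each side of the TSS gets one bin per band.
BIN_EDGES_KB = (0, 1_000, 3_000, 5_000, 10_000, 100_000)
BIN_LABELS = ("0-1 kb", "1-3 kb", "3-5 kb", "5-10 kb", "10-100 kb", ">100 kb")

CATEGORIES = tuple(
    f"upstream {lab}" for lab in reversed(BIN_LABELS)
) + tuple(f"downstream {lab}" for lab in BIN_LABELS)


@dataclass(frozen=True)
class GeneModel:
    """A gene anchored at its TSS; body coordinates are 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"gene {self.gene_id}: empty body")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1


def read_gtf_genes(path) -> list[GeneModel]:
    """Load gene features from a GTF file (gene lines only)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9 or fields[2] != "gene":
                continue
            attrs = fields[8]
            gene_id = None
            for part in attrs.split(";"):
                part = part.strip()
                if part.startswith("gene_id"):
                    gene_id = part.split(None, 1)[1].strip('"')
                    break
            if gene_id is None:
                raise ValueError(f"GTF gene line without gene_id: {line!r}")
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chrom=fields[0],
                    strand=fields[6],
                    start=int(fields[3]) - 1,  # GTF is 1-based closed
                    end=int(fields[4]),
                )
            )
    return genes


def read_tss_bed(path) -> list[GeneModel]:
    """Load genes from a 6-column BED (name = gene_id, thick = body)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            chrom, start, end, name, _score, strand = line.split()[:6]
            genes.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=int(start),
                    end=int(end),
                )
            )
    return genes


def classify_exclusivity(recon: AncestralReconstruction) -> pd.Series:
    """Branch-exclusivity class per variable pattern id.

    INTER_ONLY when every changed edge is inter-type, INTRA_ONLY when every
    changed edge is intra-type, MIXED when both occur, NO_CHANGE otherwise.
    """
    tree = recon.tree
    idx = recon.index
    n_var = recon.node_states.shape[1]
    inter_hit = np.zeros(n_var, dtype=bool)
    intra_hit = np.zeros(n_var, dtype=bool)
    for i in range(idx.n_nodes - 1):
        node = idx.nodes[i]
        parent_states = recon.node_states[idx.parent[i]]
        changed = parent_states != recon.node_states[i]
        if tree.edge_class(node) == INTER:
            inter_hit |= changed
        else:
            intra_hit |= changed
    cls = np.where(
        inter_hit & intra_hit,
        MIXED,
        np.where(inter_hit, INTER_ONLY, np.where(intra_hit, INTRA_ONLY, NO_CHANGE)),
    )
    return pd.Series(cls, index=recon.pattern_ids, name="exclusivity")


class TssIndex:
    """Nearest-TSS lookup with the tie rule: smaller gene_id wins."""

    def __init__(self, genes: list[GeneModel]):
        self.by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        per_chrom: dict[str, list[GeneModel]] = {}
        for gene in genes:
            per_chrom.setdefault(gene.chrom, []).append(gene)
        for chrom, glist in per_chrom.items():
            glist.sort(key=lambda g: (g.tss, g.gene_id))
            self.by_chrom[chrom] = (np.array([g.tss for g in glist]), glist)

    def nearest(self, chrom: str, position: int) -> GeneModel | None:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return None
        tss, glist = entry
        j = int(np.searchsorted(tss, position))
        dist = []
        if j > 0:
            dist.append(position - int(tss[j - 1]))
        if j < len(tss):
            dist.append(int(tss[j]) - position)
        best_d = min(dist)
        candidates = []
        for coord in {position - best_d, position + best_d}:
            lo = int(np.searchsorted(tss, coord, side="left"))
            hi = int(np.searchsorted(tss, coord, side="right"))
            candidates.extend(glist[lo:hi])
        return min(candidates, key=lambda g: g.gene_id)


def tss_distance(
    chrom: str, start: int, end: int, index: TssIndex, anchor: str = "midpoint"
) -> tuple[float, GeneModel | None]:
    """Signed strand-aware distance from a segment to the nearest TSS.

    Negative = upstream of the gene, positive = downstream.  Returns NaN
    (category "unassigned") when the chromosome has no gene.
    """
    if anchor == "midpoint":
        point = (start + end) // 2
    elif anchor == "five_prime":
        point = start
    else:
        raise ValueError(f"unknown anchor {anchor!r}")
    gene = index.nearest(chrom, point)
    if gene is None:
        return float("nan"), None
    d = point - gene.tss
    if gene.strand == "-":
        d = -d
    return float(d), gene


def bin_distance(distance: float) -> str:
    """One of the 12 upstream/downstream distance categories.

    Bands are half-open, lower-inclusive on |distance|; distance 0 counts
    as downstream 0-1 kb.
    """
    if not np.isfinite(distance):
        raise ValueError("distance must be finite")
    side = "upstream" if distance < 0 else "downstream"
    mag = abs(distance)
    for edge, label in zip(BIN_EDGES_KB[1:], BIN_LABELS[:-1]):
        if mag < edge:
            return f"{side} {label}"
    return f"{side} {BIN_LABELS[-1]}"


def distance_distribution(distances: np.ndarray, weights: np.ndarray) -> pd.Series:
    """bp-weighted fraction of sites per category (sums to 1 over assigned)."""
    distances = np.asarray(distances, dtype=float)
    weights = np.asarray(weights, dtype=float)
    assigned = np.isfinite(distances)
    total = weights[assigned].sum()
    frac = pd.Series(0.0, index=list(CATEGORIES), name="fraction")
    for d, w in zip(distances[assigned], weights[assigned]):
        frac[bin_distance(d)] += w
    if total > 0:
        frac /= total
    return frac


def weighted_ecdf(values: np.ndarray, weights: np.ndarray):
    order = np.argsort(values, kind="stable")
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w) / w.sum()
    return v, cum


def ks_two_sample(
    values_a: np.ndarray,
    weights_a: np.ndarray,
    values_b: np.ndarray,
    weights_b: np.ndarray,
) -> tuple[float, float]:
    """Two-sided KS test on weighted ECDFs.

    D is the sup-difference of the two bp-weighted ECDFs.  The p-value uses
    segment counts (not bp) as effective sample sizes: with equal weights
    and small n the exact two-sample distribution is used, otherwise the
    asymptotic Kolmogorov distribution.
    """
    values_a, values_b = np.asarray(values_a, float), np.asarray(values_b, float)
    weights_a, weights_b = np.asarray(weights_a, float), np.asarray(weights_b, float)
    if values_a.size == 0 or values_b.size == 0:
        raise ValueError("both samples must be non-empty")
    va, ca = weighted_ecdf(values_a, weights_a)
    vb, cb = weighted_ecdf(values_b, weights_b)
    grid = np.union1d(va, vb)
    fa = np.concatenate([[0.0], ca])[np.searchsorted(va, grid, side="right")]
    fb = np.concatenate([[0.0], cb])[np.searchsorted(vb, grid, side="right")]
    d_stat = float(np.abs(fa - fb).max())
    n1, n2 = len(values_a), len(values_b)
    unweighted = np.allclose(weights_a, weights_a[0]) and np.allclose(
        weights_b, weights_b[0]
    )
    if unweighted and max(n1, n2) <= 25:
        p = float(stats.ks_2samp(values_a, values_b, method="exact").pvalue)
    else:
        en = np.sqrt(n1 * n2 / (n1 + n2))
        p = float(np.clip(special.kolmogorov(en * d_stat), 0.0, 1.0))
    return d_stat, p


def changed_segment_table(
    recon: AncestralReconstruction, matrix, genes: list[GeneModel], anchor="midpoint"
) -> pd.DataFrame:
    """One row per changed atomic segment: exclusivity class, TSS distance,
    category, weight.  The Fig-2-style input table."""
    exclusivity = classify_exclusivity(recon)
    changed_ids = exclusivity[exclusivity != NO_CHANGE]
    index = TssIndex(genes)
    wanted = set(int(i) for i in changed_ids.index)
    rows = []
    for chrom, (bounds, idx) in matrix.segments.items():
        for k in np.nonzero(np.isin(idx, list(wanted)))[0]:
            pid = int(idx[k])
            start, end = int(bounds[k]), int(bounds[k + 1])
            d, gene = tss_distance(chrom, start, end, index, anchor)
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "pattern_id": pid,
                    "exclusivity": changed_ids.loc[pid],
                    "weight_bp": end - start,
                    "tss_distance": d,
                    "nearest_gene": gene.gene_id if gene else None,
                    "category": bin_distance(d) if np.isfinite(d) else "unassigned",
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "pattern_id",
            "exclusivity",
            "weight_bp",
            "tss_distance",
            "nearest_gene",
            "category",
        ],
    )


def plot_tss_fractions(fractions_by_group: dict[str, pd.Series], ax=None):
    """Stacked horizontal bars of category fractions, one bar per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 0.6 * len(fractions_by_group) + 1))
    groups = list(fractions_by_group)
    left = np.zeros(len(groups))
    cmap = plt.get_cmap("RdBu", len(CATEGORIES))
    for ci, cat in enumerate(CATEGORIES):
        vals = np.array([fractions_by_group[g].get(cat, 0.0) for g in groups])
        ax.barh(groups, vals, left=left, color=cmap(ci), label=cat)
        left += vals
    ax.set_xlabel("fraction of changed sites")
    ax.set_xlim(0, 1)
    ax.legend(fontsize=7, bbox_to_anchor=(1.02, 1), loc="upper left")
    return ax


def compare_inter_intra(segment_table: pd.DataFrame) -> dict:
    """Category fractions for the two exclusive classes plus the KS test."""
    table = segment_table[np.isfinite(segment_table["tss_distance"])]
    inter = table[table["exclusivity"] == INTER_ONLY]
    intra = table[table["exclusivity"] == INTRA_ONLY]
    out = {
        "inter_fractions": distance_distribution(
            inter["tss_distance"].to_numpy(), inter["weight_bp"].to_numpy()
        ),
        "intra_fractions": distance_distribution(
            intra["tss_distance"].to_numpy(), intra["weight_bp"].to_numpy()
        ),
    }
    if len(inter) and len(intra):
        d_stat, p = ks_two_sample(
            inter["tss_distance"].to_numpy(),
            inter["weight_bp"].to_numpy(),
            intra["tss_distance"].to_numpy(),
            intra["weight_bp"].to_numpy(),
        )
        out["ks_D"], out["ks_p"] = d_stat, p
    return out
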