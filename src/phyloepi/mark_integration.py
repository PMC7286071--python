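"""Per-gene, per-node integration of the six reconstructed modifications.

For every internal node (progenitor state) and gene, the reconstructed ON
track of each modification is intersected with the gene body and with a 5'
upstream window, giving bp counts per region.  Combinatorial chromatin
marks are called on top: promoter H3K4me3 + H3K27ac = ACTIVE, promoter
H3K4me3 + H3K27me3 = BIVALENT (poised).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .change_annotation import GeneModel

FIVE_PRIME_UPSTREAM = "FIVE_PRIME_UPSTREAM"
GENE_BODY = "GENE_BODY"

ACTIVE = "ACTIVE"
BIVALENT = "BIVALENT"


def _overlap_bp(intervals: np.ndarray | None, start: int, end: int) -> int:
    if intervals is None or len(intervals) == 0 or start >= end:
        return 0
    lo = np.maximum(intervals[:, 0], start)
    hi = np.minimum(intervals[:, 1], end)
    return int(np.clip(hi - lo, 0, None).sum())


def gene_regions(gene: GeneModel, upstream_window: int) -> dict[str, tuple[int, int]]:
    """Gene body plus the strand-aware 5' upstream window."""
    if gene.strand == "+":
        upstream = (max(0, gene.start - upstream_window), gene.start)
    else:
        upstream = (gene.end, gene.end + upstream_window)
    return {FIVE_PRIME_UPSTREAM: upstream, GENE_BODY: (gene.start, gene.end)}


def node_gene_bp(
    node_tracks: dict[str, dict[str, dict[str, np.ndarray]]],
    genes: list[GeneModel],
    upstream_window: int = 5000,
    drop_all_zero: bool = True,
) -> pd.DataFrame:
    """The per-gene mark table.

    ``node_tracks[modification][node]`` is a per-chromosome dict of merged
    ON intervals (as decoded from a reconstruction).  Output rows are
    (gene_id, region, modification) with one bp column per node; rows where
    every node is 0 are omitted, mirroring the published table's rule.
    """
    rows = []
    node_names: list[str] = []
    for mod_tracks in node_tracks.values():
        for node in mod_tracks:
            if node not in node_names:
                node_names.append(node)
    for gene in genes:
        regions = gene_regions(gene, upstream_window)
        for region, (start, end) in regions.items():
            for modification, mod_tracks in node_tracks.items():
                bp = {
                    node: _overlap_bp(
                        mod_tracks.get(node, {}).get(gene.chrom), start, end
                    )
                    for node in node_names
                }
                if drop_all_zero and not any(bp.values()):
                    continue
                rows.append(
                    {"gene_id": gene.gene_id, "region": region,
                     "modification": modification, **bp}
                )
    return pd.DataFrame(rows, columns=["gene_id", "region", "modification", *node_names])


def call_marks(table: pd.DataFrame, threshold_bp: int = 200) -> pd.DataFrame:
    """ACTIVE / BIVALENT flags per (gene, node).

    Promoter-region H3K4me3 is combined with H3K27ac (ACTIVE) or H3K27me3
    (BIVALENT); a mark counts when its promoter bp is at least the
    threshold.  The promoter region here is the 5' upstream window united
    with the gene body (proximal signal in either suffices).  Flags are not
    mutually exclusive.
    """
    node_cols = [c for c in table.columns if c not in ("gene_id", "region", "modification")]
    rows = []
    for gene_id, sub in table.groupby("gene_id", sort=False):
        for node in node_cols:
            bp = {
                mod: int(sub.loc[sub["modification"] == mod, node].sum())
                for mod in ("H3K4me3", "H3K27ac", "H3K27me3")
            }
            active = bp["H3K4me3"] >= threshold_bp and bp["H3K27ac"] >= threshold_bp
            bivalent = bp["H3K4me3"] >= threshold_bp and bp["H3K27me3"] >= threshold_bp
            if active or bivalent:
                rows.append(
                    {
                        "gene_id": gene_id,
                        "node": node,
                        "flags": ",".join(
                            flag
                            for flag, on in ((ACTIVE, active), (BIVALENT, bivalent))
                            if on
                        ),
                    }
                )
    return pd.DataFrame(rows, columns=["gene_id", "node", "flags"])


def write_mark_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_mark_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
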