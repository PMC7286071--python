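"""Model/Results interface over the reconstruction pipeline.

:class:`CellTypeParsimonyModel` bundles the weighted site-pattern matrix
(one modification) with a cell-type tree; ``fit()`` runs the weighted
Fitch / ACCTRAN-DELTRAN machinery and returns a
:class:`CellTypeParsimonyResults` carrying the score, ancestral states,
per-branch change table and diagnostics, in the style of statsmodels
model objects.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import change_annotation as ca
from . import enrichment as en
from .cell_type_tree import CellTypeTree
from .character_encoding import SitePatternMatrix, build_matrix
from .genomic_io import GenomeLayout, IntervalTrack, qc_filter
from .parsimony import ACCTRAN, GAIN, aggregate_changes, reconstruct


class CellTypeParsimonyModel:
    """Ancestral ON/OFF reconstruction of one modification on a fixed tree."""

    def __init__(self, matrix: SitePatternMatrix, tree: CellTypeTree,
                 modification: str = ""):
        leaf_labels = {n.label for n in tree.root.leaves()}
        if leaf_labels != set(matrix.sample_ids):
            raise ValueError(
                "tree leaves and matrix samples differ: "
                f"{sorted(leaf_labels ^ set(matrix.sample_ids))}"
            )
        self.matrix = matrix
        self.tree = tree
        self.modification = modification

    @classmethod
    def from_tracks(
        cls,
        tracks: list[IntervalTrack],
        layout: GenomeLayout,
        tree: CellTypeTree,
        apply_qc: bool = True,
    ) -> "CellTypeParsimonyModel":
        """Build the site-pattern matrix from normalized peak tracks.

        Tracks failing the per-chromosome QC rule are rejected here; drop
        them (and their tree leaves) beforehand if that is intended.
        """
        if apply_qc:
            kept, excluded = qc_filter(tracks, layout)
            if excluded:
                names = [(t.sample_id, miss) for t, miss in excluded]
                raise ValueError(f"tracks failing QC: {names}")
            tracks = kept
        modification = tracks[0].modification if tracks else ""
        return cls(build_matrix(tracks, layout), tree, modification)

    def fit(self, method: str = ACCTRAN) -> "CellTypeParsimonyResults":
        recon = reconstruct(self.matrix, self.tree, algorithm=method.upper())
        return CellTypeParsimonyResults(self, recon)


class CellTypeParsimonyResults:
    """Fitted ancestral reconstruction with summaries and diagnostics."""

    def __init__(self, model: CellTypeParsimonyModel, recon):
        self.model = model
        self.reconstruction = recon

    # -- headline quantities -------------------------------------------------
    @property
    def parsimony_score(self) -> int:
        """Weighted score: sum over patterns of bp weight x Fitch length."""
        return self.reconstruction.parsimony_score

    @property
    def variable_bp(self) -> int:
        return self.model.matrix.count_variable_sites()

    @property
    def algorithm(self) -> str:
        return self.reconstruction.algorithm

    def change_table(self, classes: str | None = "INTER") -> pd.DataFrame:
        """Per-branch ON/OFF change bp table (inter-type branches by default)."""
        return aggregate_changes(
            self.reconstruction, self.model.modification, classes=classes
        )

    def node_track(self, node_label: str) -> dict[str, np.ndarray]:
        """Reconstructed ON intervals per chromosome at one internal node."""
        matrix = self.model.matrix
        return matrix.decode_states(
            self.reconstruction.states_for_node(node_label, matrix.n_patterns)
        )

    def exclusivity(self) -> pd.Series:
        return ca.classify_exclusivity(self.reconstruction)

    def changed_segments(self, genes) -> pd.DataFrame:
        return ca.changed_segment_table(self.reconstruction, self.model.matrix, genes)

    def compare_inter_intra(self, genes) -> dict:
        return ca.compare_inter_intra(self.changed_segments(genes))

    def enrichment(self, genes, db: en.GeneSetDB, direction: str = GAIN,
                   promoter_window: int = 3000, alpha: float = 0.05) -> pd.DataFrame:
        groups = en.branch_groups(self.reconstruction, self.model.matrix, direction)
        genes_by_group = en.assign_genes(groups, genes, promoter_window)
        return en.enrichment_table(genes_by_group, db, alpha)

    def summary(self) -> str:
        lines = [
            "Cell-type parsimony reconstruction",
            "==================================",
            f"modification:        {self.model.modification or '-'}",
            f"algorithm:           {self.algorithm}",
            f"samples (leaves):    {len(self.model.matrix.sample_ids)}",
            f"site patterns:       {self.model.matrix.n_patterns}"
            f" ({int(self.model.matrix.is_variable.sum())} variable)",
            f"genome size (bp):    {self.model.matrix.total_bp}",
            f"variable sites (bp): {self.variable_bp}",
            f"parsimony score:     {self.parsimony_score} (bp x changes)",
            "",
            "Inter-type branch changes (bp):",
        ]
        table = self.change_table(classes="INTER")
        lines.append(table.to_string(index=False))
        return "\n".join(lines)


def integrate_marks(
    results: dict[str, CellTypeParsimonyResults],
    genes,
    upstream_window: int = 5000,
    threshold_bp: int = 200,
):
    """Combine fitted modifications into the per-gene node mark table and
    the ACTIVE/BIVALENT calls (see :mod:`phyloepi.mark_integration`)."""
    from .mark_integration import call_marks, node_gene_bp

    node_tracks: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for modification, res in results.items():
        per_node = {}
        for node in res.model.tree.internal_nodes():
            per_node[node.label] = res.node_track(node.label)
        node_tracks[modification] = per_node
    table = node_gene_bp(node_tracks, genes, upstream_window)
    return table, call_marks(table, threshold_bp)
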