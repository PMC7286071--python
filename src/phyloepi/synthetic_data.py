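"""Synthetic multi-sample histone-modification data with known truth.

The generator emulates the statistical structure the reconstruction
assumes: heritable binary ON/OFF peak regions evolving along a fixed
cell-type tree, with branch-class-specific gain/loss rates, whole-region
leaf noise standing in for tissue/individual variation, genes whose
promoters anchor a fraction of the peak regions, and optional planted
functional enrichment (a gain-rate multiplier for one gene set's promoter
regions on one named branch).

Everything is deterministic given the seed, and the ground truth —
ancestral region states per internal node, per-branch events, the planted
manifest — is retained so every downstream stage can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_type_tree import (
    HEMATOPOIESIS_BACKBONE,
    CellTypeTree,
    ConstraintSet,
    build_tree,
)
from .genomic_io import (
    STANDARD_MODIFICATIONS,
    GenomeLayout,
    IntervalTrack,
    merge_intervals,
)
from .parsimony import GAIN, LOSS, AncestralReconstruction


@dataclass(frozen=True)
class PlantedEnrichment:
    """Multiply the gain rate for one gene set's promoter regions on one branch."""

    gene_set: str
    branch: str
    multiplier: float


@dataclass
class SimConfig:
    """Study conditions for the generator; defaults are the reference setup."""

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    backbone_newick: str = HEMATOPOIESIS_BACKBONE
    samples_per_type: int = 3
    modifications: tuple[str, ...] = STANDARD_MODIFICATIONS
    regions_per_modification: int = 300
    region_length: tuple[int, int] = (500, 2000)
    region_gap: int = 10
    root_on_prob: float = 0.3
    gain_prob_inter: float = 0.05
    loss_prob_inter: float = 0.05
    gain_prob_intra: float = 0.01
    loss_prob_intra: float = 0.01
    leaf_noise: float = 0.01
    n_genes: int = 150
    gene_body_length: int = 2000
    promoter_anchor_fraction: float = 0.5
    anchors_per_gene: int = 1
    promoter_window: int = 3000
    n_gene_sets: int = 10
    genes_per_set: int = 15
    planted: list[PlantedEnrichment] = field(default_factory=list)
    seed: int = 1

    def __post_init__(self):
        for p in (
            self.root_on_prob,
            self.gain_prob_inter,
            self.loss_prob_inter,
            self.gain_prob_intra,
            self.loss_prob_intra,
            self.leaf_noise,
            self.promoter_anchor_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_gene_sets * self.genes_per_set > self.n_genes:
            raise ValueError("gene sets require more genes than generated")


@dataclass
class SimTruth:
    """Ground truth: per-node region states, per-edge events, planting."""

    # node_states[modification][node_label] -> bool array over regions
    node_states: dict[str, dict[str, np.ndarray]]
    # set of (modification, edge_name, region_index, GAIN|LOSS)
    events: set[tuple[str, str, int, str]]
    # regions[modification] -> list of (chrom, start, end)
    regions: dict[str, list[tuple[str, int, int]]]
    planted: list[PlantedEnrichment]


@dataclass
class SimulatedDataset:
    config: SimConfig
    layout: GenomeLayout
    tree: CellTypeTree
    constraints: ConstraintSet
    tracks: dict[str, list[IntervalTrack]]  # modification -> tracks
    genes: list  # GeneModel
    gene_sets: dict[str, set[str]]
    truth: SimTruth
    sample_sheet: pd.DataFrame

    def write(self, outdir) -> None:
        """Emit exactly the formats the pipeline consumes, plus truth JSON."""
        from .genomic_io import write_bed

        outdir = Path(outdir)
        (outdir / "beds").mkdir(parents=True, exist_ok=True)
        self.layout.to_chrom_sizes(outdir / "chrom.sizes")
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(self.tree.newick() + "\n")
        with open(outdir / "backbone.nwk", "w") as fh:
            fh.write(self.config.backbone_newick + "\n")
        rows = []
        for modification, tracks in self.tracks.items():
            for track in tracks:
                bed = outdir / "beds" / f"{track.sample_id}.{modification}.bed"
                write_bed(track, bed, self.layout)
                rows.append(
                    {
                        "sample_id": track.sample_id,
                        "cell_type": track.cell_type,
                        "tissue": "synthetic",
                        "individual": track.sample_id.split("_")[-1],
                        "subtype": "NA",
                        "modification": modification,
                        "bed_path": str(bed),
                    }
                )
        pd.DataFrame(rows).to_csv(outdir / "samples.tsv", sep="\t", index=False)
        with open(outdir / "genes.gtf", "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.gene_id}";'
                fh.write(
                    f"{g.chrom}\tsynthetic\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
        with open(outdir / "gene_sets.gmt", "w") as fh:
            for name, members in self.gene_sets.items():
                fh.write("\t".join([name, "synthetic"] + sorted(members)) + "\n")
        truth = {
            "node_states": {
                mod: {node: states.astype(int).tolist() for node, states in per.items()}
                for mod, per in self.truth.node_states.items()
            },
            "events": sorted(list(e) for e in self.truth.events),
            "regions": self.truth.regions,
            "planted": [
                {"gene_set": p.gene_set, "branch": p.branch, "multiplier": p.multiplier}
                for p in self.truth.planted
            ],
        }
        with open(outdir / "truth.json", "w") as fh:
            json.dump(truth, fh)


def _place_genes(config: SimConfig, rng: np.random.Generator):
    """One gene per evenly sized slot (with jitter): spaced promoters."""
    from .change_annotation import GeneModel

    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    per_chrom = np.maximum(
        1, np.round(config.n_genes * lengths / lengths.sum()).astype(int)
    )
    while per_chrom.sum() > config.n_genes:
        per_chrom[np.argmax(per_chrom)] -= 1
    while per_chrom.sum() < config.n_genes:
        per_chrom[np.argmin(per_chrom)] += 1
    genes = []
    gid = 0
    body = config.gene_body_length
    margin = config.promoter_window + config.region_length[1] + body
    for chrom, count in zip(chroms, per_chrom):
        length = config.chrom_lengths[chrom]
        slot = length // count
        for k in range(count):
            lo = k * slot + margin
            hi = min((k + 1) * slot - margin, length - margin)
            if hi <= lo:
                lo, hi = margin, max(margin + 1, length - margin)
            tss = int(rng.integers(lo, hi))
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                start, end = tss, min(tss + body, length)
            else:
                start, end = max(0, tss + 1 - body), tss + 1
            gid += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gid:04d}", chrom=chrom, strand=strand, start=start, end=end
                )
            )
    return genes


def _place_regions(
    config: SimConfig, genes, rng: np.random.Generator
) -> list[tuple[str, int, int]]:
    """Non-overlapping regions for one modification; a fraction sits on
    gene promoters, the rest is placed uniformly with rejection."""
    lo_len, hi_len = config.region_length
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_lengths}

    def free(chrom, start, end):
        for s, e in occupied[chrom]:
            if start < e + config.region_gap and s < end + config.region_gap:
                return False
        return True

    regions: list[tuple[str, int, int]] = []
    n_anchor = int(round(config.promoter_anchor_fraction * config.regions_per_modification))
    if config.anchors_per_gene == 1:
        n_anchor = min(n_anchor, len(genes))
        picked = rng.choice(len(genes), size=n_anchor, replace=False)
        for gi in picked:
            gene = genes[gi]
            length = int(rng.integers(lo_len, hi_len + 1))
            jitter = int(rng.integers(-200, 201))
            start = max(0, gene.tss + jitter - length // 2)
            end = min(config.chrom_lengths[gene.chrom], start + length)
            if end > start and free(gene.chrom, start, end):
                occupied[gene.chrom].append((start, end))
                regions.append((gene.chrom, start, end))
    else:
        # a promoter-proximal peak cluster: one region per slot across the
        # promoter window (flanking/bimodal promoter peaks), collision-free
        n_genes_anchor = min(len(genes), max(1, n_anchor // config.anchors_per_gene))
        picked = rng.choice(len(genes), size=n_genes_anchor, replace=False)
        slot_span = 2 * config.promoter_window // config.anchors_per_gene
        for gi in picked:
            gene = genes[gi]
            for k in range(config.anchors_per_gene):
                length = min(
                    int(rng.integers(lo_len, hi_len + 1)),
                    slot_span - config.region_gap,
                )
                center = gene.tss - config.promoter_window + k * slot_span + slot_span // 2
                jitter = int(rng.integers(-config.region_gap, config.region_gap + 1))
                start = max(0, center + jitter - length // 2)
                end = min(config.chrom_lengths[gene.chrom], start + length)
                if end > start and free(gene.chrom, start, end):
                    occupied[gene.chrom].append((start, end))
                    regions.append((gene.chrom, start, end))
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lengths / lengths.sum()
    attempts = 0
    while len(regions) < config.regions_per_modification:
        attempts += 1
        if attempts > 200 * config.regions_per_modification:
            raise ValueError("region model infeasible: genome too crowded")
        chrom = chroms[int(rng.choice(len(chroms), p=probs))]
        length = int(rng.integers(lo_len, hi_len + 1))
        start = int(rng.integers(0, config.chrom_lengths[chrom] - length))
        if free(chrom, start, start + length):
            occupied[chrom].append((start, start + length))
            regions.append((chrom, start, start + length))
    regions.sort()
    return regions


def _promoter_overlap_mask(
    regions: list[tuple[str, int, int]], genes, members: set[str], window: int
) -> np.ndarray:
    """True for regions overlapping a promoter (TSS +/- window) of a member gene."""
    promoters: dict[str, list[tuple[int, int]]] = {}
    for gene in genes:
        if gene.gene_id in members:
            promoters.setdefault(gene.chrom, []).append(
                (max(0, gene.tss - window), gene.tss + window + 1)
            )
    mask = np.zeros(len(regions), dtype=bool)
    for i, (chrom, start, end) in enumerate(regions):
        for s, e in promoters.get(chrom, []):
            if start < e and s < end:
                mask[i] = True
                break
    return mask


def simulate(config: SimConfig) -> SimulatedDataset:
    """Run the generator; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    layout = GenomeLayout(
        chrom_names=tuple(config.chrom_lengths),
        chrom_lengths=dict(config.chrom_lengths),
        excluded_chroms=frozenset(),
    )
    backbone_types = sorted(
        {leaf for leaf in _backbone_types(config.backbone_newick)}
    )
    samples_by_type = {
        t: [f"{t}_{i + 1}" for i in range(config.samples_per_type)]
        for t in backbone_types
    }
    constraints = ConstraintSet(config.backbone_newick, samples_by_type)
    tree = build_tree(constraints, seed=int(rng.integers(1, 2**31 - 1)))
    genes = _place_genes(config, rng)
    gene_order = rng.permutation(len(genes))
    gene_sets: dict[str, set[str]] = {}
    cursor = 0
    for k in range(config.n_gene_sets):
        members = {genes[i].gene_id for i in gene_order[cursor : cursor + config.genes_per_set]}
        gene_sets[f"SET{k + 1:02d}"] = members
        cursor += config.genes_per_set

    planted_masks: dict[str, np.ndarray] = {}
    node_states_all: dict[str, dict[str, np.ndarray]] = {}
    regions_all: dict[str, list[tuple[str, int, int]]] = {}
    events: set[tuple[str, str, int, str]] = set()
    tracks: dict[str, list[IntervalTrack]] = {}

    nodes = list(tree.root.preorder())
    for modification in config.modifications:
        regions = _place_regions(config, genes, rng)
        regions_all[modification] = regions
        n_regions = len(regions)
        for p in config.planted:
            key = (modification, p.branch)
            planted_masks[key] = _promoter_overlap_mask(
                regions, genes, gene_sets[p.gene_set], config.promoter_window
            ) * (p.multiplier - 1.0) + 1.0

        states: dict[int, np.ndarray] = {}
        node_states: dict[str, np.ndarray] = {}
        for node in nodes:
            if node.parent is None:
                states[id(node)] = rng.random(n_regions) < config.root_on_prob
            else:
                parent_state = states[id(node.parent)]
                edge_class = tree.edge_class(node)
                if edge_class == "INTER":
                    q_gain, q_loss = config.gain_prob_inter, config.loss_prob_inter
                else:
                    q_gain, q_loss = config.gain_prob_intra, config.loss_prob_intra
                edge_name = tree.edge_name(node)
                gain_prob = np.full(n_regions, q_gain)
                key = (modification, edge_name)
                if key in planted_masks:
                    gain_prob = np.minimum(1.0, gain_prob * planted_masks[key])
                draw = rng.random(n_regions)
                gained = (~parent_state) & (draw < gain_prob)
                lost = parent_state & (draw < q_loss)
                state = parent_state.copy()
                state[gained] = True
                state[lost] = False
                states[id(node)] = state
                for r in np.nonzero(gained)[0]:
                    events.add((modification, edge_name, int(r), GAIN))
                for r in np.nonzero(lost)[0]:
                    events.add((modification, edge_name, int(r), LOSS))
            if not node.is_leaf:
                node_states[node.label] = states[id(node)].copy()
        node_states_all[modification] = node_states

        mod_tracks = []
        for leaf in tree.root.leaves():
            state = states[id(leaf)].copy()
            flips = rng.random(n_regions) < config.leaf_noise
            state[flips] = ~state[flips]
            intervals: dict[str, list[tuple[int, int]]] = {}
            for r in np.nonzero(state)[0]:
                chrom, start, end = regions[r]
                intervals.setdefault(chrom, []).append((start, end))
            mod_tracks.append(
                IntervalTrack(
                    sample_id=leaf.label,
                    cell_type=tree.sample_to_type[leaf.label],
                    modification=modification,
                    intervals={
                        c: merge_intervals(np.array(v, dtype=np.int64))
                        for c, v in intervals.items()
                    },
                )
            )
        tracks[modification] = mod_tracks

    sheet_rows = []
    for modification, mod_tracks in tracks.items():
        for track in mod_tracks:
            sheet_rows.append(
                {
                    "sample_id": track.sample_id,
                    "cell_type": track.cell_type,
                    "tissue": "synthetic",
                    "individual": track.sample_id.split("_")[-1],
                    "subtype": "NA",
                    "modification": modification,
                    "bed_path": "",
                }
            )
    truth = SimTruth(
        node_states=node_states_all,
        events=events,
        regions=regions_all,
        planted=list(config.planted),
    )
    return SimulatedDataset(
        config=config,
        layout=layout,
        tree=tree,
        constraints=constraints,
        tracks=tracks,
        genes=genes,
        gene_sets=gene_sets,
        truth=truth,
        sample_sheet=pd.DataFrame(sheet_rows),
    )


def _backbone_types(newick: str) -> list[str]:
    from .cell_type_tree import parse_newick

    return [leaf.label for leaf in parse_newick(newick).leaves()]


@dataclass
class RecoveryMetrics:
    """How well a reconstruction recovers the simulated truth."""

    state_accuracy: float       # matching bp / total bp over internal nodes
    event_precision: float
    event_recall: float
    n_truth_events: int
    n_recon_events: int


def score_recovery(
    matrices: dict[str, "object"],
    recons: dict[str, AncestralReconstruction],
    dataset: SimulatedDataset,
    min_overlap: float = 0.5,
) -> RecoveryMetrics:
    """Score internal-node states (bp over the modifiable regions) and
    per-edge event triples (edge, region, direction) against the truth.

    A reconstructed change counts as recovering a truth event when the
    same-direction changed segments on that edge cover more than
    ``min_overlap`` of the region.  On the merged root branch the change
    direction of an undirected character is not identifiable (it depends
    only on the root-state tie-break), so events there are matched by
    (edge, region) alone.
    """
    truth = dataset.truth
    match_bp = 0
    total_bp = 0
    recon_events: set[tuple[str, str, int, str]] = set()
    for modification, recon in recons.items():
        matrix = matrices[modification]
        if set(recon.index.labels) - {None} != {
            n.label for n in dataset.tree.root.postorder()
        } - {None}:
            raise ValueError("reconstruction tree does not match the simulated tree")
        regions = truth.regions[modification]
        node_states = truth.node_states[modification]
        for node_label, true_state in node_states.items():
            decoded = matrix.decode_states(
                recon.states_for_node(node_label, matrix.n_patterns)
            )
            for r, (chrom, start, end) in enumerate(regions):
                length = end - start
                on_bp = _interval_overlap(decoded.get(chrom), start, end)
                matching = on_bp if true_state[r] else (length - on_bp)
                match_bp += matching
                total_bp += length
        for edge, (gain, loss) in recon.edge_changes().items():
            for kind, mask in ((GAIN, gain), (LOSS, loss)):
                if not mask.any():
                    continue
                full = np.zeros(matrix.n_patterns, dtype=np.uint8)
                full[recon.pattern_ids[mask]] = 1
                changed = matrix.decode_states(full)
                for r, (chrom, start, end) in enumerate(regions):
                    cov = _interval_overlap(changed.get(chrom), start, end)
                    if cov > min_overlap * (end - start):
                        recon_events.add((modification, edge, r, kind))
    truth_events = {
        (m, e, r, k)
        for (m, e, r, k) in truth.events
        if m in recons
    }
    root = dataset.tree.root
    root_edge = (
        dataset.tree.edge_name(root.children[0]) if len(root.children) == 2 else None
    )

    def _key(event):
        m, e, r, k = event
        return (m, e, r) if e == root_edge else (m, e, r, k)

    recon_keys = {_key(ev) for ev in recon_events}
    truth_keys = {_key(ev) for ev in truth_events}
    tp = len(recon_keys & truth_keys)
    precision = tp / len(recon_keys) if recon_keys else 1.0
    recall = tp / len(truth_keys) if truth_keys else 1.0
    return RecoveryMetrics(
        state_accuracy=match_bp / total_bp if total_bp else 1.0,
        event_precision=precision,
        event_recall=recall,
        n_truth_events=len(truth_events),
        n_recon_events=len(recon_events),
    )


def _interval_overlap(intervals, start: int, end: int) -> int:
    if intervals is None or len(intervals) == 0:
        return 0
    lo = np.maximum(intervals[:, 0], start)
    hi = np.minimum(intervals[:, 1], end)
    return int(np.clip(hi - lo, 0, None).sum())
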