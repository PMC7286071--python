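"""Per-nucleotide binary ON/OFF characters, losslessly compressed.

Every nucleotide of the genome carries a binary site pattern: the vector of
ON/OFF states across all samples for one modification.  Maximal runs of
constant pattern form *atomic segments*; distinct patterns with summed bp
weights form the :class:`SitePatternMatrix`.  Parsimony on weighted unique
patterns is provably identical to parsimony on the raw per-nucleotide
matrix, because tree length is additive over characters and identical
characters have identical length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic_io import GenomeLayout, IntervalTrack


@dataclass(frozen=True)
class AtomicSegment:
    """A maximal run of nucleotides sharing one site pattern."""

    chrom: str
    start: int
    end: int

    @property
    def weight(self) -> int:
        return self.end - self.start


@dataclass
class ChromPartition:
    """Partition of one chromosome into pattern-constant segments."""

    chrom: str
    bounds: np.ndarray  # length S+1, bounds[0] == 0, bounds[-1] == chrom length
    states: np.ndarray  # S x n_samples uint8

    @property
    def starts(self) -> np.ndarray:
        return self.bounds[:-1]

    @property
    def ends(self) -> np.ndarray:
        return self.bounds[1:]

    @property
    def widths(self) -> np.ndarray:
        return self.bounds[1:] - self.bounds[:-1]


def partition(
    tracks: list[IntervalTrack], layout: GenomeLayout, chroms: list[str] | None = None
):
    """Yield a :class:`ChromPartition` per chromosome.

    Segment boundaries are exactly the union of all interval endpoints plus
    the chromosome bounds; each segment's per-sample state vector is
    constant across its nucleotides.  Streaming one chromosome at a time
    keeps memory bounded for genome-scale inputs.
    """
    known = set(layout.chrom_names)
    for track in tracks:
        bad = set(track.intervals) - known
        if bad:
            raise ValueError(
                f"track {track.sample_id}: chromosomes absent from layout: {sorted(bad)}"
            )
    for chrom in chroms if chroms is not None else layout.chrom_names:
        length = layout.chrom_lengths[chrom]
        endpoints = [np.array([0, length], dtype=np.int64)]
        for track in tracks:
            iv = track.intervals.get(chrom)
            if iv is not None and len(iv):
                endpoints.append(iv.ravel())
        bounds = np.unique(np.concatenate(endpoints))
        bounds = bounds[(bounds >= 0) & (bounds <= length)]
        n_seg = len(bounds) - 1
        states = np.zeros((n_seg, len(tracks)), dtype=np.uint8)
        for j, track in enumerate(tracks):
            iv = track.intervals.get(chrom)
            if iv is None or not len(iv):
                continue
            si = np.searchsorted(bounds, iv[:, 0])
            ei = np.searchsorted(bounds, iv[:, 1])
            delta = np.zeros(n_seg + 1, dtype=np.int64)
            np.add.at(delta, si, 1)
            np.add.at(delta, ei, -1)
            states[:, j] = (np.cumsum(delta[:-1]) > 0).astype(np.uint8)
        yield ChromPartition(chrom=chrom, bounds=bounds, states=states)


@dataclass
class SitePatternMatrix:
    """Unique site patterns with bp weights, plus the segment map for decoding.

    ``patterns`` is P x N (uint8, one row per unique pattern), ``weights``
    holds total bp per pattern, and ``segments`` maps each chromosome to
    (bounds, pattern_index) so any per-pattern result can be decoded back
    to BED intervals.
    """

    sample_ids: list[str]
    patterns: np.ndarray
    weights: np.ndarray
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return self.patterns.shape[0]

    @property
    def is_variable(self) -> np.ndarray:
        if self.n_patterns == 0:
            return np.zeros(0, dtype=bool)
        return self.patterns.min(axis=1) != self.patterns.max(axis=1)

    @property
    def total_bp(self) -> int:
        return int(self.weights.sum())

    def count_variable_sites(self) -> int:
        """Total bp whose pattern contains both ON and OFF samples."""
        return int(self.weights[self.is_variable].sum())

    def pattern_segments(self, pattern_id: int):
        """All atomic segments carrying one pattern, as AtomicSegment list."""
        out = []
        for chrom, (bounds, idx) in self.segments.items():
            for k in np.nonzero(idx == pattern_id)[0]:
                out.append(AtomicSegment(chrom, int(bounds[k]), int(bounds[k + 1])))
        return out

    def decode_states(self, pattern_states: np.ndarray) -> dict[str, np.ndarray]:
        """Turn a per-pattern 0/1 vector into merged ON intervals per chromosome."""
        from .genomic_io import merge_intervals

        tracks: dict[str, np.ndarray] = {}
        for chrom, (bounds, idx) in self.segments.items():
            on = pattern_states[idx].astype(bool)
            if not on.any():
                continue
            iv = np.column_stack([bounds[:-1][on], bounds[1:][on]])
            tracks[chrom] = merge_intervals(iv)
        return tracks

    def to_tsv(self, pattern_path, segment_path) -> None:
        """Serialize to a pattern TSV and a BED-like segment map TSV."""
        pat = pd.DataFrame(
            {
                "pattern_id": np.arange(self.n_patterns),
                "weight": self.weights,
                "states": ["".join(map(str, row)) for row in self.patterns],
            }
        )
        with open(pattern_path, "w") as fh:
            fh.write("#samples=" + ",".join(self.sample_ids) + "\n")
            pat.to_csv(fh, sep="\t", index=False)
        rows = []
        for chrom, (bounds, idx) in self.segments.items():
            rows.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "start": bounds[:-1],
                        "end": bounds[1:],
                        "pattern_id": idx,
                    }
                )
            )
        pd.concat(rows, ignore_index=True).to_csv(segment_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, pattern_path, segment_path) -> "SitePatternMatrix":
        with open(pattern_path) as fh:
            header = fh.readline().strip()
            if not header.startswith("#samples="):
                raise ValueError("pattern TSV missing #samples= header")
            sample_ids = header[len("#samples=") :].split(",")
            pat = pd.read_csv(fh, sep="\t", dtype={"states": str})
        patterns = np.array(
            [[int(ch) for ch in s] for s in pat["states"]], dtype=np.uint8
        ).reshape(len(pat), len(sample_ids))
        seg = pd.read_csv(segment_path, sep="\t", dtype={"chrom": str})
        segments = {}
        for chrom, grp in seg.groupby("chrom", sort=False):
            grp = grp.sort_values("start")
            bounds = np.append(grp["start"].to_numpy(np.int64), grp["end"].iloc[-1])
            segments[chrom] = (bounds, grp["pattern_id"].to_numpy(np.int64))
        return cls(
            sample_ids=sample_ids,
            patterns=patterns,
            weights=pat["weight"].to_numpy(np.int64),
            segments=segments,
        )


def collapse(partitions, sample_ids: list[str]) -> SitePatternMatrix:
    """Collapse chromosome partitions into unique weighted site patterns.

    Accepts any iterable of :class:`ChromPartition` (one chromosome at a
    time), so memory stays proportional to the number of unique patterns.
    """
    index: dict[bytes, int] = {}
    pattern_rows: list[np.ndarray] = []
    weights: list[int] = []
    segments: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for part in partitions:
        widths = part.widths
        uniq, inverse = np.unique(part.states, axis=0, return_inverse=True)
        inverse = inverse.ravel()
        local_to_global = np.empty(len(uniq), dtype=np.int64)
        for u, row in enumerate(uniq):
            key = row.tobytes()
            pid = index.get(key)
            if pid is None:
                pid = len(pattern_rows)
                index[key] = pid
                pattern_rows.append(row.copy())
                weights.append(0)
            local_to_global[u] = pid
        local_weights = np.bincount(inverse, weights=widths, minlength=len(uniq))
        for u in range(len(uniq)):
            weights[local_to_global[u]] += int(local_weights[u])
        segments[part.chrom] = (part.bounds.copy(), local_to_global[inverse])
    patterns = (
        np.vstack(pattern_rows)
        if pattern_rows
        else np.zeros((0, len(sample_ids)), dtype=np.uint8)
    )
    return SitePatternMatrix(
        sample_ids=list(sample_ids),
        patterns=patterns,
        weights=np.array(weights, dtype=np.int64),
        segments=segments,
    )


def build_matrix(tracks: list[IntervalTrack], layout: GenomeLayout) -> SitePatternMatrix:
    """Partition the genome and collapse to the weighted pattern matrix."""
    sample_ids = [t.sample_id for t in tracks]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_ids among tracks")
    mods = {t.modification for t in tracks}
    if len(mods) > 1:
        raise ValueError(f"tracks mix modifications: {sorted(mods)}")
    return collapse(partition(tracks, layout), sample_ids)


def count_variable_sites(matrix: SitePatternMatrix) -> int:
    return matrix.count_variable_sites()


def per_nucleotide_partitions(tracks: list[IntervalTrack], layout: GenomeLayout):
    """Yield partitions with one 1-bp segment per nucleotide (no compression).

    Only sensible for small genomes; used to check that the weighted-pattern
    path is equivalent to running one character per nucleotide.
    """
    for part in partition(tracks, layout):
        length = int(part.bounds[-1])
        bounds = np.arange(length + 1, dtype=np.int64)
        states = np.repeat(part.states, part.widths, axis=0)
        yield ChromPartition(chrom=part.chrom, bounds=bounds, states=states)


def build_matrix_per_nucleotide(
    tracks: list[IntervalTrack], layout: GenomeLayout
) -> SitePatternMatrix:
    """Per-nucleotide (uncompressed characters) variant of :func:`build_matrix`."""
    sample_ids = [t.sample_id for t in tracks]
    return collapse_uncompressed(per_nucleotide_partitions(tracks, layout), sample_ids)


def collapse_uncompressed(partitions, sample_ids: list[str]) -> SitePatternMatrix:
    """Keep one pattern per segment (no dedup): every character enters separately."""
    pattern_rows = []
    weights = []
    segments = {}
    offset = 0
    for part in partitions:
        n = part.states.shape[0]
        idx = np.arange(offset, offset + n, dtype=np.int64)
        pattern_rows.append(part.states)
        weights.append(part.widths)
        segments[part.chrom] = (part.bounds.copy(), idx)
        offset += n
    patterns = (
        np.vstack(pattern_rows)
        if pattern_rows
        else np.zeros((0, len(sample_ids)), dtype=np.uint8)
    )
    return SitePatternMatrix(
        sample_ids=list(sample_ids),
        patterns=patterns,
        weights=np.concatenate(weights) if weights else np.zeros(0, dtype=np.int64),
        segments=segments,
    )
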