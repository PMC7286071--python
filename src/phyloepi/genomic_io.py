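"""Reading, writing and QC of per-sample histone-modification peak tracks.

A ChIP-seq peak track for one sample and one modification is treated as a
set of genomic intervals in which the modification is "ON"; every other
nucleotide is "OFF".  All coordinates are BED-native: 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STANDARD_MODIFICATIONS = (
    "H3K4me1",
    "H3K4me3",
    "H3K27ac",
    "H3K36me3",
    "H3K27me3",
    "H3K9me3",
)

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "cell_type",
    "tissue",
    "individual",
    "subtype",
    "modification",
    "bed_path",
)


class BedParseError(ValueError):
    """Raised for malformed BED records; carries the offending line number."""


@dataclass(frozen=True)
class GenomeLayout:
    """The chromosome universe of an analysis.

    ``excluded_chroms`` lists chromosomes that the per-chromosome sample
    QC ignores (the Y chromosome by default, since many donors lack it).
    """

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]
    excluded_chroms: frozenset[str] = frozenset({"Y", "chrY"})

    def __post_init__(self):
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names in layout")
        for name in self.chrom_names:
            length = self.chrom_lengths.get(name)
            if length is None or length <= 0:
                raise ValueError(f"chromosome {name!r} needs a positive length")

    @classmethod
    def from_chrom_sizes(cls, path, excluded_chroms=("Y", "chrY")) -> "GenomeLayout":
        """Read a 2-column TSV of (chromosome name, length in bp)."""
        sizes = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "length"], dtype={"chrom": str}
        )
        return cls(
            chrom_names=tuple(sizes["chrom"]),
            chrom_lengths=dict(zip(sizes["chrom"], sizes["length"].astype(int))),
            excluded_chroms=frozenset(excluded_chroms),
        )

    def to_chrom_sizes(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.chrom_names:
                fh.write(f"{name}\t{self.chrom_lengths[name]}\n")

    @property
    def qc_chroms(self) -> tuple[str, ...]:
        """Chromosomes a sample must cover to pass QC."""
        return tuple(c for c in self.chrom_names if c not in self.excluded_chroms)

    @property
    def total_bp(self) -> int:
        return int(sum(self.chrom_lengths[c] for c in self.chrom_names))


def merge_intervals(intervals: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping or book-ended half-open intervals."""
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.shape[0] == 0:
        return arr
    arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
    # adjacent intervals merge too: ON/OFF per nucleotide is the only semantics
    running_end = np.maximum.accumulate(arr[:, 1])
    keep_start = np.concatenate(([True], arr[1:, 0] > running_end[:-1]))
    starts = arr[keep_start, 0]
    group_last = np.append(np.nonzero(keep_start)[0][1:] - 1, len(arr) - 1)
    ends = running_end[group_last]
    return np.column_stack([starts, ends])


@dataclass
class IntervalTrack:
    """One sample x modification ON-region set: disjoint sorted intervals per chromosome."""

    sample_id: str
    cell_type: str
    modification: str
    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    def normalize(self) -> "IntervalTrack":
        self.intervals = {
            c: merge_intervals(iv) for c, iv in self.intervals.items() if len(iv)
        }
        return self

    def validate(self, layout: GenomeLayout) -> None:
        for chrom, iv in self.intervals.items():
            if chrom not in self.chrom_ok_set(layout):
                raise ValueError(f"track {self.sample_id}: unknown chromosome {chrom!r}")
            if len(iv) and (iv[:, 0].min() < 0 or iv[:, 1].max() > layout.chrom_lengths[chrom]):
                raise ValueError(f"track {self.sample_id}: interval outside {chrom}")

    @staticmethod
    def chrom_ok_set(layout: GenomeLayout) -> set[str]:
        return set(layout.chrom_names)

    def bp_on(self, chrom: str | None = None) -> int:
        if chrom is not None:
            iv = self.intervals.get(chrom)
            return int((iv[:, 1] - iv[:, 0]).sum()) if iv is not None and len(iv) else 0
        return int(sum(self.bp_on(c) for c in self.intervals))

    def chroms_with_data(self) -> set[str]:
        return {c for c, iv in self.intervals.items() if len(iv)}

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalTrack):
            return NotImplemented
        if (self.sample_id, self.cell_type, self.modification) != (
            other.sample_id,
            other.cell_type,
            other.modification,
        ):
            return False
        mine = {c: iv for c, iv in self.intervals.items() if len(iv)}
        theirs = {c: iv for c, iv in other.intervals.items() if len(iv)}
        if mine.keys() != theirs.keys():
            return False
        return all(np.array_equal(mine[c], theirs[c]) for c in mine)


def read_bed(
    path,
    layout: GenomeLayout,
    sample_id: str = "",
    cell_type: str = "",
    modification: str = "",
    strict: bool = False,
) -> IntervalTrack:
    """Read a BED3+ file into a normalized :class:`IntervalTrack`.

    Columns past the third are ignored.  Records on chromosomes absent from
    ``layout`` are skipped with a warning, or rejected when ``strict``.
    """
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    known = set(layout.chrom_names)
    unknown_seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            if chrom not in known:
                if strict:
                    raise BedParseError(
                        f"{path}: line {lineno}: unknown chromosome {chrom!r}"
                    )
                unknown_seen.add(chrom)
                continue
            if end > layout.chrom_lengths[chrom]:
                raise BedParseError(
                    f"{path}: line {lineno}: interval end {end} beyond {chrom} length"
                )
            per_chrom.setdefault(chrom, []).append((start, end))
    if unknown_seen:
        warnings.warn(
            f"{path}: skipped records on chromosomes not in layout: "
            f"{sorted(unknown_seen)}",
            stacklevel=2,
        )
    track = IntervalTrack(
        sample_id=sample_id,
        cell_type=cell_type,
        modification=modification,
        intervals={c: np.array(v, dtype=np.int64) for c, v in per_chrom.items()},
    )
    return track.normalize()


def write_bed(track: IntervalTrack, path, layout: GenomeLayout | None = None) -> None:
    """Write a normalized track as 3-column BED, in layout chromosome order."""
    chroms = (
        [c for c in layout.chrom_names if c in track.intervals]
        if layout is not None
        else sorted(track.intervals)
    )
    with open(path, "w") as fh:
        for chrom in chroms:
            for start, end in track.intervals[chrom]:
                fh.write(f"{chrom}\t{start}\t{end}\n")


def qc_filter(
    tracks: list[IntervalTrack], layout: GenomeLayout
) -> tuple[list[IntervalTrack], list[tuple[IntervalTrack, list[str]]]]:
    """Exclude samples with no data on any required (non-excluded) chromosome.

    Returns ``(kept, excluded)`` where each excluded entry carries the list
    of chromosomes with zero peak intervals.
    """
    required = layout.qc_chroms
    kept: list[IntervalTrack] = []
    excluded: list[tuple[IntervalTrack, list[str]]] = []
    for track in tracks:
        present = track.chroms_with_data()
        missing = [c for c in required if c not in present]
        if missing:
            excluded.append((track, missing))
        else:
            kept.append(track)
    return kept, excluded


def read_sample_sheet(path) -> pd.DataFrame:
    """Read the TSV sample sheet and validate its columns and uniqueness."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    dup = sheet.duplicated(subset=["sample_id", "modification"])
    if dup.any():
        raise ValueError("sample sheet: duplicate (sample_id, modification) rows")
    return sheet


def load_tracks(
    sheet: pd.DataFrame,
    layout: GenomeLayout,
    modification: str,
    strict: bool = False,
) -> list[IntervalTrack]:
    """Load every track of one modification listed in the sample sheet."""
    rows = sheet[sheet["modification"] == modification]
    return [
        read_bed(
            row.bed_path,
            layout,
            sample_id=row.sample_id,
            cell_type=row.cell_type,
            modification=modification,
            strict=strict,
        )
        for row in rows.itertuples()
    ]
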