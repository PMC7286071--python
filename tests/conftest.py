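import numpy as np
import pytest

from phyloepi.cell_type_tree import Node
from phyloepi.genomic_io import GenomeLayout, IntervalTrack


@pytest.fixture
def small_layout():
    return GenomeLayout(
        chrom_names=("chr1", "chr2"),
        chrom_lengths={"chr1": 10_000, "chr2": 5_000},
        excluded_chroms=frozenset(),
    )


@pytest.fixture
def layout_with_y():
    return GenomeLayout(
        chrom_names=("chr1", "chr2", "chrY"),
        chrom_lengths={"chr1": 10_000, "chr2": 5_000, "chrY": 2_000},
    )


def make_track(sample_id, intervals, modification="H3K4me3", cell_type="T"):
    return IntervalTrack(
        sample_id=sample_id,
        cell_type=cell_type,
        modification=modification,
        intervals={c: np.array(v, dtype=np.int64) for c, v in intervals.items()},
    ).normalize()


@pytest.fixture
def track_factory():
    return make_track


def random_multifurcating_tree(labels, rng):
    """Random rooted tree with 2-3 children per internal node."""
    nodes = [Node(label) for label in labels]
    while len(nodes) > 1:
        k = 2 if len(nodes) < 3 else int(rng.integers(2, min(3, len(nodes)) + 1))
        picks = [nodes.pop(int(rng.integers(len(nodes)))) for _ in range(k)]
        nodes.append(Node(None, picks))
    return nodes[0]


@pytest.fixture
def tree_factory():
    return random_multifurcating_tree


def random_tracks(rng, layout, n_samples, modification="H3K4me3"):
    """Random normalized tracks over a layout (for property tests)."""
    tracks = []
    for j in range(n_samples):
        intervals = {}
        for chrom in layout.chrom_names:
            length = layout.chrom_lengths[chrom]
            n = int(rng.integers(0, 8))
            if n:
                points = np.sort(rng.integers(0, length + 1, size=2 * n))
                iv = points.reshape(-1, 2)
                iv = iv[iv[:, 0] < iv[:, 1]]
                if len(iv):
                    intervals[chrom] = iv
        tracks.append(
            make_track(f"s{j}", intervals, modification=modification)
        )
    return tracks


@pytest.fixture
def random_track_factory():
    return random_tracks
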