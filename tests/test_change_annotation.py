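import numpy as np
import pytest
from scipy import stats

from phyloepi.cell_type_tree import CellTypeTree, parse_newick
from phyloepi.change_annotation import (
    CATEGORIES,
    INTER_ONLY,
    INTRA_ONLY,
    MIXED,
    GeneModel,
    TssIndex,
    bin_distance,
    changed_segment_table,
    classify_exclusivity,
    compare_inter_intra,
    distance_distribution,
    ks_two_sample,
    read_gtf_genes,
    tss_distance,
)
from phyloepi.character_encoding import SitePatternMatrix
from phyloepi.parsimony import reconstruct


def six_leaf_tree():
    # two types with two samples each plus two singleton types
    root = parse_newick("(((T_1,T_2)T,(B_1,B_2)B)L,(M_1,M_2)M)root;")
    return CellTypeTree(
        root=root,
        sample_to_type={
            "T_1": "T", "T_2": "T", "B_1": "B", "B_2": "B", "M_1": "M", "M_2": "M",
        },
    )


def matrix_for(patterns, weights, segments=None):
    return SitePatternMatrix(
        sample_ids=["T_1", "T_2", "B_1", "B_2", "M_1", "M_2"],
        patterns=np.array(patterns, dtype=np.uint8),
        weights=np.array(weights, dtype=np.int64),
        segments=segments or {},
    )


class TestExclusivity:
    def test_classes(self):
        patterns = [
            [1, 1, 0, 0, 0, 0],  # single change on type stem (INTER only)
            [1, 0, 0, 0, 0, 0],  # change inside the T clade (INTRA only)
            [1, 1, 1, 0, 0, 0],  # stem change plus change inside B (MIXED)
            [1, 1, 1, 1, 1, 1],  # constant
        ]
        matrix = matrix_for(patterns, [10, 10, 10, 10])
        recon = reconstruct(matrix, six_leaf_tree())
        classes = classify_exclusivity(recon)
        assert classes.loc[0] == INTER_ONLY
        assert classes.loc[1] == INTRA_ONLY
        assert classes.loc[2] == MIXED
        assert 3 not in classes.index  # constant patterns carry no class

    def test_partition_of_changed_bp(self):
        rng = np.random.default_rng(21)
        patterns = rng.integers(0, 2, size=(50, 6)).astype(np.uint8)
        weights = rng.integers(1, 9, size=50)
        matrix = matrix_for(patterns, weights)
        recon = reconstruct(matrix, six_leaf_tree())
        classes = classify_exclusivity(recon)
        variable = matrix.is_variable
        assert set(classes.index) == set(np.nonzero(variable)[0])
        changed = classes[classes != "NO_CHANGE"]
        total = matrix.weights[changed.index].sum()
        parts = sum(
            matrix.weights[classes[classes == c].index].sum()
            for c in (INTER_ONLY, INTRA_ONLY, MIXED)
        )
        assert parts == total


GENES = [
    GeneModel("gA", "chr1", "+", 10_000, 12_000),
    GeneModel("gB", "chr1", "-", 30_000, 31_000),  # TSS at 30_999
]


class TestTssDistance:
    def test_upstream_of_plus_strand_gene(self):
        d, gene = tss_distance("chr1", 9_400, 9_600, TssIndex(GENES))
        assert d == -500 and gene.gene_id == "gA"

    def test_minus_strand_flips_sign(self):
        # genomically left of a minus-strand TSS is downstream of that gene
        d, gene = tss_distance("chr1", 30_399, 30_599, TssIndex(GENES))
        assert d == 500 and gene.gene_id == "gB"

    def test_equidistant_tie_smaller_gene_id(self):
        genes = [
            GeneModel("gZ", "chr1", "+", 1_000, 2_000),
            GeneModel("gA2", "chr1", "+", 3_000, 4_000),
        ]
        d, gene = tss_distance("chr1", 1_999, 2_001, TssIndex(genes))
        assert abs(d) == 1_000 and gene.gene_id == "gA2"

    def test_no_gene_on_chromosome_unassigned(self):
        d, gene = tss_distance("chr2", 0, 100, TssIndex(GENES))
        assert np.isnan(d) and gene is None


class TestBinning:
    @pytest.mark.parametrize(
        "distance,category",
        [
            (-500, "upstream 0-1 kb"),
            (150_000, "downstream >100 kb"),
            (0, "downstream 0-1 kb"),
            (-1_000, "upstream 1-3 kb"),   # half-open lower-inclusive bands
            (999, "downstream 0-1 kb"),
            (-99_999, "upstream 10-100 kb"),
            (100_000, "downstream >100 kb"),
        ],
    )
    def test_category_boundaries(self, distance, category):
        assert bin_distance(distance) == category

    def test_twelve_categories_total(self):
        sweep = np.concatenate([-np.geomspace(1, 5e5, 400), np.geomspace(1, 5e5, 400)])
        assert {bin_distance(d) for d in sweep} == set(CATEGORIES)
        assert len(CATEGORIES) == 12

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(7)
        d = rng.normal(scale=2e4, size=200)
        w = rng.integers(1, 100, size=200)
        frac = distance_distribution(d, w)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)
        assert list(frac.index) == list(CATEGORIES)


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample(np.r_[1.0, 2, 3], np.ones(3), np.r_[1.0, 2, 3], np.ones(3))
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample(np.r_[1.0, 2], np.ones(2), np.r_[5.0, 6], np.ones(2))
        assert d == 1.0

    def test_small_sample_exact_p_matches_permutation(self):
        d, p = ks_two_sample(np.r_[1.0, 2, 3], np.ones(3), np.r_[4.0, 5, 6], np.ones(3))
        assert d == 1.0
        # exhaustive: of C(6,3)=20 splits, only 2 reach D=1
        assert p == pytest.approx(2 / 20)

    def test_equal_weights_match_textbook_statistic(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            a = rng.normal(size=int(rng.integers(3, 30)))
            b = rng.normal(size=int(rng.integers(3, 30)))
            d, _ = ks_two_sample(a, np.ones_like(a), b, np.ones_like(b))
            assert d == pytest.approx(stats.ks_2samp(a, b).statistic, abs=1e-12)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError, match="non-empty"):
            ks_two_sample(np.array([]), np.array([]), np.r_[1.0], np.r_[1.0])

    def test_weights_shift_the_ecdf(self):
        # heavy weight on a large value drags the weighted ECDF down
        d_unw, _ = ks_two_sample(np.r_[1.0, 9], np.r_[1.0, 1], np.r_[1.0], np.r_[1.0])
        d_wt, _ = ks_two_sample(np.r_[1.0, 9], np.r_[1.0, 99], np.r_[1.0], np.r_[1.0])
        assert d_wt > d_unw


class TestSegmentTable:
    def test_changed_segments_annotated_and_compared(self):
        bounds = np.array([0, 9_000, 9_500, 20_000, 29_000, 30_000, 40_000])
        seg_idx = np.array([3, 0, 3, 1, 3, 2])
        segments = {"chr1": (bounds, seg_idx)}
        patterns = [
            [1, 1, 0, 0, 0, 0],   # INTER_ONLY, midpoint 9250 -> -750 of gA
            [1, 0, 0, 0, 0, 0],   # INTRA_ONLY, midpoint 24500 -> gB side
            [1, 1, 1, 0, 0, 0],   # MIXED
            [0, 0, 0, 0, 0, 0],   # constant filler
        ]
        weights = [500, 9_000, 10_000, 9_000 + 10_500 + 1_000]
        matrix = matrix_for(patterns, weights, segments)
        recon = reconstruct(matrix, six_leaf_tree())
        table = changed_segment_table(recon, matrix, GENES)
        assert set(table["exclusivity"]) == {INTER_ONLY, INTRA_ONLY, MIXED}
        inter_rows = table[table["exclusivity"] == INTER_ONLY]
        assert bin_distance(inter_rows.iloc[0]["tss_distance"]) == "upstream 0-1 kb"
        out = compare_inter_intra(table)
        assert out["inter_fractions"].sum() == pytest.approx(1.0)
        assert 0 <= out["ks_D"] <= 1


class TestGtfReader:
    def test_reads_gene_features_with_one_based_conversion(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tsrc\tgene\t101\t200\t.\t+\t.\tgene_id "g1"; gene_name "G1";\n'
            'chr1\tsrc\texon\t101\t150\t.\t+\t.\tgene_id "g1";\n'
            'chr2\tsrc\tgene\t51\t80\t.\t-\t.\tgene_id "g2";\n'
        )
        genes = read_gtf_genes(gtf)
        assert [g.gene_id for g in genes] == ["g1", "g2"]
        assert genes[0].start == 100 and genes[0].end == 200
        assert genes[0].tss == 100
        assert genes[1].tss == 79
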