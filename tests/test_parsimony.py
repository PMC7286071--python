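import numpy as np
import pytest

from phyloepi.cell_type_tree import CellTypeTree, Node, parse_newick
from phyloepi.character_encoding import SitePatternMatrix
from phyloepi.parsimony import (
    ACCTRAN,
    DELTRAN,
    TreeIndex,
    aggregate_changes,
    brute_force_oracle,
    fitch_score,
    map_changes,
    mpr_state_sets,
    reconstruct,
    resolve,
    weighted_score,
)

QUARTET = "((A,B)ab,(C,D)cd)root;"
SAMPLES = ["A", "B", "C", "D"]


def quartet_tree():
    return parse_newick(QUARTET)


def as_index(root, samples):
    return TreeIndex.build(root, samples)


class TestFitchScore:
    @pytest.mark.parametrize(
        "pattern,expected",
        [
            ([1, 1, 0, 0], 1),  # one synapomorphy
            ([1, 0, 1, 0], 2),  # homoplasy: verified by exhaustive enumeration
            ([0, 0, 0, 0], 0),
            ([1, 1, 1, 1], 0),
        ],
    )
    def test_quartet_lengths(self, pattern, expected):
        assert fitch_score(quartet_tree(), SAMPLES, np.array(pattern)) == expected

    def test_missing_leaf_state_errors(self):
        with pytest.raises(ValueError, match="no state column"):
            TreeIndex.build(quartet_tree(), ["A", "B", "C"])

    def test_matches_brute_force_on_random_trees(self, tree_factory):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(4, 11))
            labels = [f"s{i}" for i in range(n)]
            root = tree_factory(labels, rng)
            pattern = rng.integers(0, 2, n).astype(np.uint8)
            best, _ = brute_force_oracle(root, labels, pattern)
            assert fitch_score(root, labels, pattern) == best


class TestMprStateSets:
    def test_quartet_synapomorphy_root_ambiguous(self):
        idx = as_index(quartet_tree(), SAMPLES)
        sets = mpr_state_sets(idx, np.array([[1, 1, 0, 0]], dtype=np.uint8))
        root_set = sets[-1, 0]
        assert root_set.tolist() == [True, True]

    def test_constant_pattern_every_node_singleton(self):
        idx = as_index(quartet_tree(), SAMPLES)
        sets = mpr_state_sets(idx, np.array([[1, 1, 1, 1]], dtype=np.uint8))
        assert (sets[:, 0, 1] == True).all()  # noqa: E712
        assert (sets[:, 0, 0] == False).all()  # noqa: E712

    def test_triplet_forced_ancestor(self):
        root = parse_newick("((A,B)ab,C)root;")
        idx = as_index(root, ["A", "B", "C"])
        sets = mpr_state_sets(idx, np.array([[1, 0, 0]], dtype=np.uint8))
        ab = idx.labels.index("ab")
        assert sets[ab, 0].tolist() == [True, False]

    def test_equals_union_of_enumerated_mprs(self, tree_factory):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 10))
            labels = [f"s{i}" for i in range(n)]
            root = tree_factory(labels, rng)
            pattern = rng.integers(0, 2, n).astype(np.uint8)
            _, labelings = brute_force_oracle(root, labels, pattern)
            idx = TreeIndex.build(root, labels)
            sets = mpr_state_sets(idx, pattern.reshape(1, -1))[:, 0, :]
            union = np.zeros_like(sets)
            for lab in labelings:
                for i, s in enumerate(lab):
                    union[i, s] = True
            assert (sets == union.astype(bool)).all()


class TestResolve:
    def test_unique_mpr_algorithms_agree(self):
        root = parse_newick("((A,B)ab,C)root;")
        idx = as_index(root, ["A", "B", "C"])
        states = np.array([[1, 1, 0]], dtype=np.uint8)
        acc = resolve(idx, states, ACCTRAN)
        dlt = resolve(idx, states, DELTRAN)
        assert np.array_equal(acc, dlt)

    def test_outputs_are_enumerated_mprs(self, tree_factory):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = int(rng.integers(4, 10))
            labels = [f"s{i}" for i in range(n)]
            root = tree_factory(labels, rng)
            pattern = rng.integers(0, 2, n).astype(np.uint8)
            best, labelings = brute_force_oracle(root, labels, pattern)
            enum = set(labelings)
            idx = TreeIndex.build(root, labels)
            for alg in (ACCTRAN, DELTRAN):
                lab = tuple(
                    int(x) for x in resolve(idx, pattern.reshape(1, -1), alg)[:, 0]
                )
                assert lab in enum

    def test_root_tie_resolves_off(self):
        idx = as_index(quartet_tree(), SAMPLES)
        lab = resolve(idx, np.array([[1, 1, 0, 0]], dtype=np.uint8), ACCTRAN)
        assert lab[-1, 0] == 0  # root is OFF by the documented tie-break

    def test_acctran_places_change_rootward_deltran_tipward(self):
        # two of three leaves ON under one internal node, rest OFF:
        # ACCTRAN turns the internal node ON (gain on the deep edge, loss
        # at the OFF tip), DELTRAN keeps it OFF (two parallel tip gains).
        root = parse_newick("((A,B,C)abc,(D,E)de)root;")
        labels = ["A", "B", "C", "D", "E"]
        idx = as_index(root, labels)
        states = np.array([[1, 1, 0, 0, 0]], dtype=np.uint8)
        best, labelings = brute_force_oracle(root, labels, states[0])
        enum = set(labelings)
        acc = tuple(int(x) for x in resolve(idx, states, ACCTRAN)[:, 0])
        dlt = tuple(int(x) for x in resolve(idx, states, DELTRAN)[:, 0])
        assert acc in enum and dlt in enum
        abc = idx.labels.index("abc")
        assert acc[abc] == 1  # accelerated: ancestral gain, then loss at C
        assert dlt[abc] == 0  # delayed: two parallel tip gains

    def test_unknown_algorithm_rejected(self):
        idx = as_index(quartet_tree(), SAMPLES)
        with pytest.raises(ValueError, match="unknown algorithm"):
            resolve(idx, np.zeros((1, 4), dtype=np.uint8), "MIDTRAN")


def quartet_cell_tree():
    root = parse_newick(QUARTET)
    return CellTypeTree(
        root=root,
        sample_to_type={"A": "ab", "B": "ab", "C": "cd", "D": "cd"},
    )


def quartet_matrix(patterns, weights):
    return SitePatternMatrix(
        sample_ids=SAMPLES,
        patterns=np.array(patterns, dtype=np.uint8),
        weights=np.array(weights, dtype=np.int64),
    )


class TestChanges:
    def test_single_synapomorphy_gain_on_ab_side(self):
        matrix = quartet_matrix([[1, 1, 0, 0]], [100])
        recon = reconstruct(matrix, quartet_cell_tree(), ACCTRAN)
        table = map_changes(recon)
        assert len(table) == 1
        row = table.iloc[0]
        # OFF root => the merged root branch carries a 100 bp GAIN
        assert row["change"] == "GAIN" and row["weight_bp"] == 100
        assert row["edge"] == "ab-cd"

    def test_constant_patterns_zero_change_table(self):
        matrix = quartet_matrix([[1, 1, 1, 1], [0, 0, 0, 0]], [60, 40])
        recon = reconstruct(matrix, quartet_cell_tree(), ACCTRAN)
        table = aggregate_changes(recon, classes=None)
        values = table.drop(columns=["modification", "change"]).to_numpy()
        assert (values == 0).all()

    def test_changes_sum_to_weighted_score(self):
        rng = np.random.default_rng(9)
        patterns = rng.integers(0, 2, size=(40, 4)).astype(np.uint8)
        weights = rng.integers(1, 50, size=40)
        matrix = quartet_matrix(patterns, weights)
        for alg in (ACCTRAN, DELTRAN):
            recon = reconstruct(matrix, quartet_cell_tree(), alg)
            table = aggregate_changes(recon, classes=None)
            total = table.drop(columns=["modification", "change"]).to_numpy().sum()
            assert total == recon.parsimony_score
            assert recon.parsimony_score == weighted_score(
                quartet_cell_tree().root, matrix
            )

    def test_score_additivity_over_patterns(self):
        matrix = quartet_matrix([[1, 1, 0, 0], [1, 0, 1, 0]], [10, 7])
        recon = reconstruct(matrix, quartet_cell_tree(), ACCTRAN)
        assert recon.parsimony_score == 10 * 1 + 7 * 2

    def test_both_algorithms_are_mprs_for_every_pattern(self):
        rng = np.random.default_rng(10)
        patterns = rng.integers(0, 2, size=(30, 4)).astype(np.uint8)
        matrix = quartet_matrix(patterns, np.ones(30, dtype=np.int64))
        idx = TreeIndex.build(quartet_cell_tree().root, SAMPLES)
        from phyloepi.parsimony import fitch_lengths

        lengths = fitch_lengths(idx, patterns)
        for alg in (ACCTRAN, DELTRAN):
            recon = reconstruct(matrix, quartet_cell_tree(), alg)
            variable = matrix.is_variable
            parent = idx.parent
            changes = (
                recon.node_states[:-1] != recon.node_states[parent[:-1]]
            ).sum(axis=0)
            assert np.array_equal(changes, lengths[variable])
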