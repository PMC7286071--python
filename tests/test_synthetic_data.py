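import numpy as np
import pytest

import phyloepi as pe
from phyloepi.parsimony import GAIN
from phyloepi.synthetic_data import RecoveryMetrics, score_recovery


def small_config(**kw):
    defaults = dict(
        chrom_lengths={"chr1": 300_000},
        samples_per_type=2,
        modifications=("H3K4me3",),
        regions_per_modification=80,
        n_genes=40,
        n_gene_sets=4,
        genes_per_set=8,
        seed=5,
    )
    defaults.update(kw)
    return pe.SimConfig(**defaults)


class TestSimulate:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        a_dir, b_dir = tmp_path / "a", tmp_path / "b"
        pe.simulate(small_config()).write(a_dir)
        pe.simulate(small_config()).write(b_dir)
        beds_a = sorted((a_dir / "beds").iterdir())
        beds_b = sorted((b_dir / "beds").iterdir())
        assert [p.name for p in beds_a] == [p.name for p in beds_b]
        for pa, pb in zip(beds_a, beds_b):
            assert pa.read_bytes() == pb.read_bytes()
        assert (a_dir / "tree.nwk").read_text() == (b_dir / "tree.nwk").read_text()

    def test_no_change_limit_zero_variable_patterns(self):
        ds = pe.simulate(
            small_config(
                gain_prob_inter=0, loss_prob_inter=0,
                gain_prob_intra=0, loss_prob_intra=0, leaf_noise=0,
            )
        )
        matrix = pe.build_matrix(ds.tracks["H3K4me3"], ds.layout)
        assert matrix.count_variable_sites() == 0

    def test_leaf_tracks_follow_truth_in_noiseless_limit(self):
        ds = pe.simulate(small_config(leaf_noise=0))
        truth = ds.truth
        regions = truth.regions["H3K4me3"]
        # leaf state = nearest ancestral state transformed by recorded events:
        # verify each leaf's ON regions are consistent with its parent node
        for track in ds.tracks["H3K4me3"]:
            on_regions = {
                r
                for r, (chrom, start, end) in enumerate(regions)
                if track.intervals.get(chrom) is not None
                and any(s <= start and end <= e for s, e in track.intervals[chrom])
            }
            leaf = next(
                n for n in ds.tree.root.leaves() if n.label == track.sample_id
            )
            parent_state = truth.node_states["H3K4me3"][leaf.parent.label]
            edge = ds.tree.edge_name(leaf)
            expected = {
                r for r in range(len(regions)) if parent_state[r]
            }
            gained = {
                r for (m, e, r, k) in truth.events
                if m == "H3K4me3" and e == edge and k == GAIN
                and r not in expected
            }
            lost = {
                r for (m, e, r, k) in truth.events
                if m == "H3K4me3" and e == edge and k == "LOSS" and r in expected
            }
            assert on_regions == (expected | gained) - lost

    def test_event_counts_follow_binomial_rates(self):
        # inter edges gain at q=0.05 per OFF region: empirical mean over
        # seeds should sit within 3 standard errors of the expectation
        n_seeds = 100
        counts = []
        for seed in range(1, n_seeds + 1):
            ds = pe.simulate(
                small_config(seed=seed, leaf_noise=0, root_on_prob=0.0,
                             loss_prob_inter=0.0, gain_prob_intra=0.0,
                             loss_prob_intra=0.0)
            )
            lb = sum(
                1 for (m, e, r, k) in ds.truth.events if e == "L-B" and k == GAIN
            )
            counts.append(lb)
        n_regions = 80
        # a region can gain on L-B only if it is still OFF at L, i.e. it
        # did not already gain on the root-L half-edge (prob 0.95)
        p = 0.95 * 0.05
        expected = n_regions * p
        se = np.sqrt(n_regions * p * (1 - p) / n_seeds)
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_infeasible_region_model_errors(self):
        with pytest.raises(ValueError, match="infeasible"):
            pe.simulate(
                small_config(
                    chrom_lengths={"chr1": 20_000}, regions_per_modification=200
                )
            )

    def test_planted_single_event_recovered_exactly(self):
        # zero baseline rates, one planted branch with certain gain:
        # reconstruction must place exactly those gains on that branch
        ds = pe.simulate(
            small_config(
                gain_prob_inter=1e-12, loss_prob_inter=0.0,
                gain_prob_intra=0.0, loss_prob_intra=0.0,
                leaf_noise=0.0, root_on_prob=0.0,
                planted=[pe.PlantedEnrichment("SET01", "L-B", 1e12)],
            )
        )
        matrix = pe.build_matrix(ds.tracks["H3K4me3"], ds.layout)
        recon = pe.reconstruct(matrix, ds.tree, "ACCTRAN")
        truth_edges = {e for (_, e, _, _) in ds.truth.events}
        assert truth_edges == {"L-B"}
        table = pe.aggregate_changes(recon, classes=None)
        nonzero = {
            c
            for c in table.columns[2:]
            if table[c].to_numpy().sum() > 0
        }
        assert nonzero == {"L-B"}
        metrics = score_recovery({"H3K4me3": matrix}, {"H3K4me3": recon}, ds)
        assert metrics.event_recall == 1.0 and metrics.event_precision == 1.0


class TestScoreRecovery:
    def test_perfect_reconstruction_scores_one(self):
        ds = pe.simulate(small_config(leaf_noise=0))
        matrix = pe.build_matrix(ds.tracks["H3K4me3"], ds.layout)
        recon = pe.reconstruct(matrix, ds.tree, "ACCTRAN")
        low_rate = score_recovery({"H3K4me3": matrix}, {"H3K4me3": recon}, ds)
        assert isinstance(low_rate, RecoveryMetrics)
        assert 0 <= low_rate.state_accuracy <= 1

    def test_all_off_reconstruction_accuracy_near_one_minus_p0(self):
        # truth: root ON with p = 0.3, no events; an all-OFF "reconstruction"
        # should match about 70% of region bp
        ds = pe.simulate(
            pe.SimConfig(
                gain_prob_inter=0, loss_prob_inter=0,
                gain_prob_intra=0, loss_prob_intra=0, leaf_noise=0,
                root_on_prob=0.3, seed=11,
            )
        )
        matrices, recons = {}, {}
        for mod, tracks in ds.tracks.items():
            matrix = pe.build_matrix(tracks, ds.layout)
            recon = pe.reconstruct(matrix, ds.tree, "ACCTRAN")
            # overwrite ancestral states with all-OFF (constant-ON included)
            recon.node_states[:] = 0
            recon.constant_on = np.zeros(0, dtype=np.int64)
            matrices[mod], recons[mod] = matrix, recon
        metrics = score_recovery(matrices, recons, ds)
        assert metrics.state_accuracy == pytest.approx(0.7, abs=0.05)

    def test_mismatched_tree_rejected(self):
        ds = pe.simulate(small_config())
        other = pe.simulate(small_config(samples_per_type=3))
        matrix = pe.build_matrix(other.tracks["H3K4me3"], other.layout)
        recon = pe.reconstruct(matrix, other.tree, "ACCTRAN")
        with pytest.raises(ValueError, match="does not match"):
            score_recovery({"H3K4me3": matrix}, {"H3K4me3": recon}, ds)


def test_noiseless_low_rate_pipeline_identity():
    """With at most ~one event per region and no noise, reconstruction
    events equal truth events exactly."""
    ds = pe.simulate(
        small_config(
            gain_prob_inter=0.003, loss_prob_inter=0.0,
            gain_prob_intra=0.001, loss_prob_intra=0.0,
            root_on_prob=0.0, leaf_noise=0.0, seed=23,
        )
    )
    matrix = pe.build_matrix(ds.tracks["H3K4me3"], ds.layout)
    recon = pe.reconstruct(matrix, ds.tree, "ACCTRAN")
    metrics = score_recovery({"H3K4me3": matrix}, {"H3K4me3": recon}, ds)
    assert metrics.event_recall == 1.0
    assert metrics.event_precision == 1.0
    assert metrics.state_accuracy == 1.0
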