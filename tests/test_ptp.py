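import numpy as np
import pytest

from stagematch.core import ClusterPartition, DataError, read_gene_tree
from stagematch.ptp import (PTP, count_antichain_covers, fit_ptp_exact,
                            fit_ptp_heuristic, ptp_loglik)
from stagematch.simulate import SimConfig, simulate_dataset

from .oracles import enumerate_tip_partitions


def two_class_tree():
    # within-branches ~0.01, between ~0.5: clusters {A,B,C} and {D,E}
    return read_gene_tree(
        "(((A:0.01,B:0.012):0.011,C:0.013):0.5,(D:0.014,E:0.009):0.52);", "g")


def exp_fit(lengths):
    n, s = len(lengths), sum(lengths)
    return n * (np.log(n / s) - 1.0)


class TestLoglik:
    def test_single_cluster_equals_null(self):
        gt = two_class_tree()
        part = ClusterPartition("g", "PTP", [set("ABCDE")])
        logL, _rw, rb = ptp_loglik(gt, part)
        lengths = [e.length for e in gt.tree.preorder_edge_iter()
                   if e.head_node.parent_node is not None]
        assert logL == pytest.approx(exp_fit(lengths))
        assert np.isnan(rb)

    def test_all_singletons_equals_null(self):
        gt = two_class_tree()
        part = ClusterPartition("g", "PTP", [{t} for t in "ABCDE"])
        logL, rw, _rb = ptp_loglik(gt, part)
        lengths = [e.length for e in gt.tree.preorder_edge_iter()
                   if e.head_node.parent_node is not None]
        assert logL == pytest.approx(exp_fit(lengths))
        assert np.isnan(rw)

    def test_true_two_cluster_partition_beats_degenerates(self):
        gt = two_class_tree()
        true = ClusterPartition("g", "PTP", [set("ABC"), set("DE")])
        logL_true, rw, rb = ptp_loglik(gt, true)
        # independent evaluation from the branch-length classes
        within = [0.01, 0.012, 0.011, 0.013, 0.014, 0.009]
        between = [0.5, 0.52]
        assert logL_true == pytest.approx(exp_fit(within) + exp_fit(between))
        null = ptp_loglik(gt, ClusterPartition("g", "PTP", [set("ABCDE")]))[0]
        assert logL_true > null
        assert rb < rw  # between-branches are longer -> smaller rate

    def test_non_clade_cluster_rejected(self):
        gt = two_class_tree()
        with pytest.raises(DataError, match="clade"):
            ptp_loglik(gt, ClusterPartition("g", "PTP", [set("AD"), set("BCE")]))


class TestExact:
    def test_two_tip_enumeration(self):
        gt = read_gene_tree("(A:0.01,B:0.6);", "g")
        res = fit_ptp_exact(gt)
        assert res.n_clusters in (1, 2)
        assert res.loglik >= res.null_loglik

    def test_candidate_count_matches_independent_enumeration(self, caterpillar4,
                                                             balanced4):
        for gt in (caterpillar4, balanced4):
            parts = enumerate_tip_partitions(gt)
            assert count_antichain_covers(gt) == len(parts)
            assert len(set(parts)) == len(parts)
        assert count_antichain_covers(caterpillar4) == 4

    def test_exact_is_argmax_over_all_partitions(self):
        gt = two_class_tree()
        res = fit_ptp_exact(gt)
        best = -np.inf
        for part in enumerate_tip_partitions(gt):
            cp = ClusterPartition("g", "PTP", [set(c) for c in part])
            best = max(best, ptp_loglik(gt, cp)[0])
        assert res.loglik == pytest.approx(best, abs=1e-10)
        assert sorted(map(sorted, res.cluster_tip_sets)) == [list("ABC"), list("DE")]

    def test_refuses_large_trees(self):
        cfg = SimConfig(n_species=5, samples_per_species=4,
                        missing_gene_prob={"CAD": 0.0, "COI": 0.0},
                        seq_length={"CAD": 10, "COI": 10}, seed=0)
        gt = simulate_dataset(cfg).genes["CAD"].subst_tree
        with pytest.raises(DataError, match="heuristic"):
            fit_ptp_exact(gt)


class TestHeuristic:
    def test_never_beats_and_usually_matches_exact(self):
        eq = 0
        for seed in range(25):
            cfg = SimConfig(n_species=3, samples_per_species=3, depth_ratio=8,
                            missing_gene_prob={"CAD": 0.0, "COI": 0.0},
                            seq_length={"CAD": 10, "COI": 10}, seed=seed)
            st = simulate_dataset(cfg).genes["COI"].subst_tree
            ex, he = fit_ptp_exact(st), fit_ptp_heuristic(st, seed=seed)
            assert he.loglik <= ex.loglik + 1e-9
            eq += abs(he.loglik - ex.loglik) < 1e-9
        assert eq >= 23

    def test_recovers_three_species_with_strong_contrast(self):
        cfg = SimConfig(n_species=3, samples_per_species=3, depth_ratio=200,
                        missing_gene_prob={"CAD": 0.0, "COI": 0.0},
                        seq_length={"CAD": 10, "COI": 10}, seed=7)
        ds = simulate_dataset(cfg)
        res = fit_ptp_exact(ds.genes["COI"].subst_tree)
        truth = {}
        for sid, sp in ds.species_truth.items():
            truth.setdefault(sp, set()).add(sid)
        assert sorted(map(sorted, res.partition.clusters)) == \
            sorted(sorted(v) for v in truth.values())

    def test_determinism_given_seed(self):
        cfg = SimConfig(n_species=4, samples_per_species=5,
                        missing_gene_prob={"CAD": 0.0, "COI": 0.0},
                        seq_length={"CAD": 10, "COI": 10}, seed=3)
        st = simulate_dataset(cfg).genes["COI"].subst_tree
        a = fit_ptp_heuristic(st, seed=11)
        b = fit_ptp_heuristic(st, seed=11)
        assert a.loglik == b.loglik
        assert a.partition.clusters == b.partition.clusters

    def test_null_generated_tree_rarely_rejects(self):
        """Trees whose branches are one iid exponential class (the PTP null)
        should not produce systematic LRT rejections."""
        from stagematch.core import GeneTree

        rej = 0
        n = 40
        for seed in range(n):
            cfg = SimConfig(n_species=1, samples_per_species=12,
                            coal_ne={"g": 0.5}, missing_gene_prob={"g": 0.0},
                            subst_rate={"g": 1.0}, seq_length={"g": 10},
                            seed=4000 + seed)
            st = simulate_dataset(cfg).genes["g"].subst_tree
            rng = np.random.default_rng(seed)
            tree = st.tree.clone(depth=1)
            for e in tree.preorder_edge_iter():
                if e.head_node.parent_node is not None:
                    e.length = float(rng.exponential(0.1))
            gt = GeneTree(gene="g", tree=tree)
            rej += fit_ptp_heuristic(gt, seed=seed).lrt_pvalue < 0.05
        assert rej / n < 0.25
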