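import numpy as np
import pytest

from stagematch.core import UNKNOWN
from stagematch.monophyly import test_monophyly as monophyly_verdict
from stagematch.simulate import (ConfigError, SimConfig, inject_paraphyly,
                                 simulate_dataset)


def small_cfg(**kw):
    base = dict(n_species=5, samples_per_species=4, seed=0,
                missing_gene_prob={"CAD": 0.0, "COI": 0.0},
                seq_length={"CAD": 40, "COI": 40})
    base.update(kw)
    return SimConfig(**base)


class TestSimulate:
    def test_determinism_byte_identical(self, tmp_path):
        for sub in ("a", "b"):
            simulate_dataset(small_cfg(seed=9)).write(tmp_path / sub)
        for name in ("specimens.tsv", "CAD_time.nwk", "COI_subst.nwk",
                     "CAD.fasta", "species_truth.tsv"):
            assert (tmp_path / "a" / name).read_bytes() == \
                   (tmp_path / "b" / name).read_bytes()

    def test_single_species_is_pure_coalescent(self):
        ds = simulate_dataset(small_cfg(n_species=1, samples_per_species=6))
        gt = ds.genes["CAD"].time_tree
        assert gt.n_tips == 6
        for node in gt.tree.preorder_internal_node_iter():
            species = {ds.species_truth[l.taxon.label] for l in node.leaf_iter()}
            assert len(species) == 1  # zero between-species nodes

    def test_tip_counts_and_truth_partition(self):
        ds = simulate_dataset(small_cfg())
        for gd in ds.genes.values():
            assert gd.time_tree.n_tips == 20
        by_species = {}
        for sid, sp in ds.species_truth.items():
            by_species.setdefault(sp, set()).add(sid)
        assert len(by_species) == 5
        assert all(len(v) == 4 for v in by_species.values())

    def test_trees_are_ultrametric(self):
        ds = simulate_dataset(small_cfg(seed=3))
        assert ds.genes["CAD"].time_tree.is_ultrametric()
        assert ds.genes["COI"].time_tree.is_ultrametric()

    def test_supports_reflect_true_species_boundaries(self):
        ds = simulate_dataset(small_cfg(seed=1))
        gt = ds.genes["COI"].time_tree
        for node in gt.tree.preorder_internal_node_iter():
            species = {ds.species_truth[l.taxon.label] for l in node.leaf_iter()}
            if len(species) >= 2:
                assert node.support == 1.0
            elif node.parent_node is not None:
                assert 0.5 <= node.support <= 1.0

    def test_larvae_are_unlabelled_and_recorded_in_truth(self):
        ds = simulate_dataset(small_cfg(seed=2))
        for s in ds.specimens:
            if s.is_immature:
                assert s.species == UNKNOWN
            assert s.id in ds.species_truth

    def test_missingness_drops_genes_but_never_all(self):
        cfg = small_cfg(n_species=10, samples_per_species=10,
                        missing_gene_prob={"CAD": 0.5, "COI": 0.1}, seed=5)
        ds = simulate_dataset(cfg)
        frac_cad = np.mean([not s.has_gene["CAD"] for s in ds.specimens])
        assert 0.35 < frac_cad < 0.65
        assert all(any(s.has_gene.values()) for s in ds.specimens)
        assert ds.genes["CAD"].time_tree.n_tips == \
            sum(s.has_gene["CAD"] for s in ds.specimens)

    def test_subst_tree_is_rate_scaled_time_tree(self):
        ds = simulate_dataset(small_cfg(seed=6))
        t_len = sum(e.length or 0 for e in ds.genes["COI"].time_tree.tree.preorder_edge_iter())
        s_len = sum(e.length or 0 for e in ds.genes["COI"].subst_tree.tree.preorder_edge_iter())
        assert s_len / t_len == pytest.approx(ds.config.subst_rate["COI"])

    def test_within_species_divergence_scales_with_ne(self):
        """Mean within-species pairwise time distance is linear in Ne."""

        def mean_within(ne, seeds):
            vals = []
            for seed in seeds:
                cfg = small_cfg(n_species=6, samples_per_species=5,
                                coal_ne={"g": ne}, subst_rate={"g": 1.0},
                                missing_gene_prob={"g": 0.0},
                                seq_length={"g": 10}, seed=seed)
                ds = simulate_dataset(cfg)
                gt = ds.genes["g"].time_tree
                ages = gt.node_ages()
                for node in gt.tree.preorder_internal_node_iter():
                    spp = {ds.species_truth[l.taxon.label] for l in node.leaf_iter()}
                    if len(spp) == 1:
                        vals.append(ages[node])
                del ds
            return np.mean(vals)

        lo = mean_within(0.01, range(6))
        hi = mean_within(0.04, range(6))
        assert 2.8 < hi / lo < 5.7  # expected factor 4, stochastic tolerance

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            SimConfig(n_species=0).validate()
        with pytest.raises(ConfigError):
            SimConfig(larva_fraction=1.4).validate()
        with pytest.raises(ConfigError):
            SimConfig(coal_ne={"CAD": -1, "COI": 0.01}).validate()


class TestInjectParaphyly:
    def test_zero_fraction_is_identity(self):
        ds = simulate_dataset(small_cfg(seed=5))
        out = inject_paraphyly(ds, ("sp01", "sp02"), 0.0, seed=1)
        assert out.genes["COI"].time_tree.as_string() == \
            ds.genes["COI"].time_tree.as_string()

    def test_same_seed_same_surgery(self):
        ds = simulate_dataset(small_cfg(seed=5))
        a = inject_paraphyly(ds, ("sp01", "sp02"), 0.5, seed=7)
        b = inject_paraphyly(ds, ("sp01", "sp02"), 0.5, seed=7)
        assert a.genes["COI"].time_tree.as_string() == \
            b.genes["COI"].time_tree.as_string()

    def test_full_swap_breaks_monophyly_on_target_gene_only(self):
        ds = simulate_dataset(small_cfg(seed=5, depth_ratio=80))
        out = inject_paraphyly(ds, ("sp01", "sp02"), 1.0, seed=3, gene="COI")
        for gene, expected in (("CAD", "yes"), ("COI", "no")):
            target = {s for s, v in ds.species_truth.items() if v == "sp01"}
            res = monophyly_verdict(out.genes[gene].time_tree, target,
                                    support_threshold=0.0)
            assert res.is_monophyletic == expected
        assert out.genes["COI"].time_tree.is_ultrametric()

    def test_unknown_species_rejected(self):
        ds = simulate_dataset(small_cfg())
        with pytest.raises(ConfigError, match="unknown species"):
            inject_paraphyly(ds, ("sp01", "nope"), 0.5, seed=0)
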