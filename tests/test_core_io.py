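import io

import pytest

from stagematch.core import (ClusterPartition, DataError, FormatError, GeneTree,
                             Specimen, UNKNOWN, read_gene_tree,
                             read_specimen_table, read_tip_map,
                             write_specimen_table, write_tip_map)
from stagematch.simulate import SimConfig, simulate_dataset


class TestReadGeneTree:
    def test_four_tip_ultrametric(self, balanced4):
        assert balanced4.n_tips == 4
        assert balanced4.is_ultrametric()
        ages = balanced4.node_ages()
        assert max(ages.values()) == pytest.approx(2.0)

    def test_supports_from_labels(self, balanced4):
        sups = {frozenset(l.taxon.label for l in n.leaf_iter()): n.support
                for n in balanced4.tree.preorder_internal_node_iter()}
        assert sups[frozenset("AB")] == pytest.approx(0.99)
        assert sups[frozenset("CD")] == pytest.approx(0.8)
        assert sups[frozenset("ABCD")] == 1.0  # root convention

    def test_supports_from_beast_comments(self):
        nwk = "((A:1,B:1)[&posterior=0.97]:1,(C:1,D:1)[&posterior=0.55]:1);"
        gt = read_gene_tree(nwk, "g", support_source="comment")
        sups = {frozenset(l.taxon.label for l in n.leaf_iter()): n.support
                for n in gt.tree.preorder_internal_node_iter()}
        assert sups[frozenset("AB")] == pytest.approx(0.97)
        assert sups[frozenset("CD")] == pytest.approx(0.55)

    def test_outgroup_rooting_and_pruning(self):
        nwk = "((A:1,B:1):1,(C:1,D:1):1,R_polonica:3);"
        gt = read_gene_tree(nwk, "g", outgroup="R_polonica")
        assert sorted(gt.tip_labels()) == ["A", "B", "C", "D"]
        assert len(gt.tree.seed_node.child_nodes()) == 2

    def test_unrooted_without_outgroup_rejected(self):
        with pytest.raises(FormatError, match="multifurcation"):
            read_gene_tree("(A:1,B:1,C:1);", "g")

    def test_missing_branch_lengths_rejected(self):
        with pytest.raises(FormatError, match="branch length"):
            read_gene_tree("((A,B),(C,D));", "g")

    def test_duplicate_tips_rejected(self):
        with pytest.raises(DataError, match="duplicate"):
            read_gene_tree("((A:1,A:1):1,C:2);", "g")

    def test_non_ultrametric_flagged(self):
        gt = read_gene_tree("((A:1,B:2):1,C:2);", "g")
        assert not gt.is_ultrametric()

    def test_roundtrip_preserves_lengths_and_supports(self, tmp_path):
        cfg = SimConfig(n_species=3, samples_per_species=3, seed=4,
                        missing_gene_prob={"CAD": 0.0, "COI": 0.0},
                        seq_length={"CAD": 20, "COI": 20})
        gt = simulate_dataset(cfg).genes["CAD"].time_tree
        path = tmp_path / "t.nwk"
        gt.write(path)
        back = read_gene_tree(path, "CAD")
        assert back.as_string() == gt.as_string()
        a0 = sorted(a for n, a in gt.node_ages().items() if not n.is_leaf())
        a1 = sorted(a for n, a in back.node_ages().items() if not n.is_leaf())
        assert a1 == pytest.approx(a0, abs=1e-9)


class TestSpecimenTable:
    def test_basic_row_parsing(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("id\tstage\tspecies\tsex\tCOI\tCAD\n"
                     "L0123\tlarva\t\t\t1\t0\n"
                     "A001\tadult\tH. acharai\tM\t1\t1\n"
                     "F001\tadult\t\tF\t0\t1\n")
        specs = read_specimen_table(p)
        by_id = {s.id: s for s in specs}
        assert by_id["L0123"].species == UNKNOWN
        assert by_id["L0123"].has_gene == {"COI": True, "CAD": False}
        assert by_id["A001"].species == "H. acharai"
        assert by_id["F001"].species == UNKNOWN and by_id["F001"].is_adult

    def test_unknown_stage_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("id\tstage\nX1\timago\n")
        with pytest.raises(DataError, match="stage"):
            read_specimen_table(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("id\tstage\nX1\tadult\nX1\tlarva\n")
        with pytest.raises(DataError, match="duplicate"):
            read_specimen_table(p)

    def test_identified_larva_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("id\tstage\tspecies\nX1\tlarva\tH. acharai\n")
        with pytest.raises(DataError):
            read_specimen_table(p)

    def test_roundtrip_of_full_roster(self, tmp_path):
        cfg = SimConfig(n_species=38, samples_per_species=14, seed=0,
                        seq_length={"CAD": 10, "COI": 10})
        ds = simulate_dataset(cfg)
        assert len(ds.specimens) == 38 * 14
        p = tmp_path / "s.tsv"
        write_specimen_table(ds.specimens, p)
        back = read_specimen_table(p)
        assert len(back) == len(ds.specimens)
        stages = {}
        for s in back:
            stages[s.stage] = stages.get(s.stage, 0) + 1
        assert stages == {s: sum(1 for x in ds.specimens if x.stage == s)
                          for s in stages}


class TestTipMapAndPartition:
    def test_tip_map_roundtrip(self, tmp_path):
        tm = {"h1": frozenset({"a", "b"}), "h2": frozenset({"c"})}
        p = tmp_path / "m.tsv"
        write_tip_map(tm, p)
        assert read_tip_map(p) == tm

    def test_gene_tree_rejects_specimen_under_two_tips(self):
        with pytest.raises(DataError, match="mapped to tips"):
            GeneTree(gene="g",
                     tree=read_gene_tree("((A:1,B:1):1,C:2);", "g").tree,
                     tip_map={"A": frozenset({"x"}), "B": frozenset({"x"}),
                              "C": frozenset({"y"})})

    def test_partition_invariants(self):
        with pytest.raises(DataError, match="overlap"):
            ClusterPartition("g", "PTP", [{"a", "b"}, {"b", "c"}])
        with pytest.raises(DataError, match="empty"):
            ClusterPartition("g", "PTP", [set()])

    def test_specimen_vocabulary(self):
        with pytest.raises(DataError):
            Specimen(id="x", stage="egg")
        assert Specimen(id="x", stage="pupa").is_immature
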