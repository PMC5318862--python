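import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phyloflora as pf
from phyloflora.exceptions import GraftError
from phyloflora.treebuild import CalibrationTable, set_node_ages

from conftest import make_table


def patristic_among(tree, labels):
    dm = pf.patristic_matrix(tree)
    idx = [dm.labels.index(l) for l in sorted(labels)]
    return dm.values[np.ix_(idx, idx)]


class TestGraftS1:
    def test_species_joins_genus_crown_as_polytomy(self, t4):
        table = make_table(
            t4, genus_of={"A": "G1", "B": "G1", "C": "G2", "D": "G2", "E": "G1"},
            family_of=dict.fromkeys("ABCDE", "Fam1") | {"C": "Fam2", "D": "Fam2"})
        tree, report = pf.graft_taxa(t4, table, "S1")
        assert report.polytomy == ("E",)
        assert pf.is_ultrametric(tree, rel_tol=1e-6)
        dm = pf.patristic_matrix(tree)
        # E is equidistant from A and B at the G1 crown (age 1)
        i = {l: k for k, l in enumerate(dm.labels)}
        assert dm.values[i["E"], i["A"]] == pytest.approx(2.0)
        assert dm.values[i["E"], i["B"]] == pytest.approx(2.0)

    def test_monotypic_genus_gets_half_pendant_insertion(self, t4):
        table = make_table(
            t4, genus_of={"A": "G1", "B": "G1", "C": "Gc", "D": "G2", "F": "Gc"},
            family_of=dict.fromkeys("ABCDF", "Fam1"))
        tree, _ = pf.graft_taxa(t4, table, "S1")
        dm = pf.patristic_matrix(tree)
        i = {l: k for k, l in enumerate(dm.labels)}
        assert dm.values[i["C"], i["F"]] == pytest.approx(1.0)  # 0.5 + 0.5
        assert pf.is_ultrametric(tree, rel_tol=1e-6)

    def test_family_absent_reports_unplaced(self, t4, t4_table):
        df = t4_table.data.copy()
        df = pd.concat([df, pd.DataFrame([{
            "species": "Z", "genus": "Gz", "family": "FamZ",
            "element": "PT", "r1": 1, "r2": 0, "r3": 0}])], ignore_index=True)
        table = pf.TaxonTable(data=df, regions=t4_table.regions)
        tree, report = pf.graft_taxa(t4, table, "S1")
        assert report.unplaced == ("Z",)
        assert sorted(lv.taxon.label for lv in tree.leaf_node_iter()) == list("ABCD")

    def test_grafting_preserves_distances_among_existing_tips(self):
        tree = pf.simulate_tree(40, seed=0)
        tax = pf.simulate_taxonomy(tree, 4, 2)
        extra = pd.DataFrame([
            {"species": f"new{i:02d}", "genus": g, "family": f, "element": "UNKNOWN"}
            for i, (g, f) in enumerate(
                tax[["genus", "family"]].drop_duplicates().itertuples(index=False))])
        full = pd.concat([tax, extra], ignore_index=True)
        full["r1"] = 1
        table = pf.TaxonTable(data=full, regions=("r1",))
        before = patristic_among(tree, tax.species)
        grafted, report = pf.graft_taxa(tree, table, "S1")
        assert set(report.polytomy) == set(extra.species)
        after = patristic_among(grafted, tax.species)
        assert np.allclose(before, after, atol=1e-9)
        assert pf.is_ultrametric(grafted, rel_tol=1e-6)

    def test_prune_then_regraft_round_trip_restores_distances(self):
        tree = pf.simulate_tree(30, seed=9)
        tax = pf.simulate_taxonomy(tree, 3, 2)
        tax["r1"] = 1
        table = pf.TaxonTable(data=tax, regions=("r1",))
        # remove one species whose genus keeps >= 2 members, regraft as polytomy
        sizes = tax.groupby("genus").size()
        genus = sizes[sizes >= 3].index[0]
        victim = sorted(tax[tax.genus == genus].species)[0]
        keep = [s for s in tax.species if s != victim]
        pruned = pf.prune_to_taxa(tree, keep)
        regrafted, _ = pf.graft_taxa(pruned, table, "S1")
        # distances among the never-removed tips are untouched
        assert np.allclose(patristic_among(tree, keep),
                           patristic_among(regrafted, keep), atol=1e-9)

    def test_non_ultrametric_backbone_fatal(self, t4_table):
        tree = pf.read_newick_string("((A:1,B:2):1,(C:1,D:1):1);")
        with pytest.raises(GraftError, match="ultrametric"):
            pf.graft_taxa(tree, t4_table, "S1")


class TestGraftS2S3:
    def _table_with_extra(self, t4_table, species="E", genus="G1", family="Fam1"):
        df = pd.concat([t4_table.data, pd.DataFrame([{
            "species": species, "genus": genus, "family": family,
            "element": "PT", "r1": 1, "r2": 0, "r3": 0}])], ignore_index=True)
        return pf.TaxonTable(data=df, regions=t4_table.regions)

    def test_seed_required(self, t4, t4_table):
        table = self._table_with_extra(t4_table)
        for scenario in ("S2", "S3"):
            with pytest.raises(GraftError, match="seed"):
                pf.graft_taxa(t4, table, scenario)

    def test_s2_is_seeded_and_deterministic(self, t4, t4_table):
        table = self._table_with_extra(t4_table)
        t_a, rep = pf.graft_taxa(t4, table, "S2", seed=3)
        t_b, _ = pf.graft_taxa(t4, table, "S2", seed=3)
        assert pf.write_newick(t_a) == pf.write_newick(t_b)
        assert rep.random == ("E",)
        assert pf.is_ultrametric(t_a, rel_tol=1e-6)

    def test_s2_attachment_varies_with_seed(self, t4, t4_table):
        table = self._table_with_extra(t4_table)
        trees = {pf.write_newick(pf.graft_taxa(t4, table, "S2", seed=s)[0])
                 for s in range(12)}
        assert len(trees) > 1

    def test_s3_redates_and_stays_ultrametric(self, t4, t4_table):
        table = self._table_with_extra(t4_table, genus="Gc", family="Fam2",
                                       species="F")
        df = table.data
        df.loc[df.species == "C", "genus"] = "Gc"
        tree, rep = pf.graft_taxa(t4, table, "S3", seed=1)
        assert rep.bladj == ("F",)
        assert pf.is_ultrametric(tree, rel_tol=1e-6)

    def test_report_partitions_added_taxa(self, t4, t4_table):
        table = self._table_with_extra(t4_table)
        df = pd.concat([table.data, pd.DataFrame([{
            "species": "Z", "genus": "Gz", "family": "FamZ",
            "element": "PT", "r1": 1, "r2": 0, "r3": 0}])], ignore_index=True)
        table = pf.TaxonTable(data=df, regions=table.regions)
        _, rep = pf.graft_taxa(t4, table, "S1")
        added = {"E", "Z"}
        pieces = [set(rep.polytomy), set(rep.random), set(rep.bladj),
                  set(rep.unplaced)]
        assert set().union(*pieces) == added
        assert sum(len(p) for p in pieces) == len(added)


class TestBladj:
    def test_single_undated_node_gets_midpoint(self):
        tree = pf.read_newick_string("((tip)x)root;")
        out = pf.bladj_smooth(tree, CalibrationTable.from_pairs([("root", 10.0)]))
        ages = {nd.label: nd.age for nd in out.preorder_node_iter() if nd.label}
        assert ages["x"] == pytest.approx(5.0)

    def test_two_undated_nodes_split_interval_evenly(self):
        tree = pf.read_newick_string("(((tip)y)x)root;")
        out = pf.bladj_smooth(tree, CalibrationTable.from_pairs([("root", 9.0)]))
        ages = {nd.label: nd.age for nd in out.preorder_node_iter() if nd.label}
        assert ages["x"] == pytest.approx(6.0)
        assert ages["y"] == pytest.approx(3.0)

    def test_fully_dated_tree_is_unchanged(self, t4):
        set_node_ages(t4)
        out = pf.bladj_smooth(t4)
        assert pf.write_newick(out) == pf.write_newick(t4)

    def test_conflicting_calibration_fatal(self):
        tree = pf.read_newick_string("(((tip)y)x)root;")
        cal = CalibrationTable.from_pairs([("root", 5.0), ("x", 8.0)])
        with pytest.raises(GraftError, match="conflict"):
            pf.bladj_smooth(tree, cal)

    @settings(deadline=None, max_examples=15)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_path_sums_equal_root_age_and_ages_monotone(self, seed):
        tree = pf.simulate_tree(20, seed=seed)
        set_node_ages(tree)
        root_age = tree.seed_node.age
        # forget every other internal age, then re-interpolate
        rng = np.random.default_rng(seed)
        for nd in tree.preorder_node_iter():
            if nd.parent_node is not None and not nd.is_leaf() and rng.random() < 0.5:
                nd.age = None
        out = pf.bladj_smooth(tree)
        for lv in out.leaf_node_iter():
            depth = sum(nd.edge.length for nd in lv.ancestor_iter(inclusive=True)
                        if nd.parent_node is not None)
            assert depth == pytest.approx(root_age, abs=1e-9)
        for nd in out.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.age <= nd.parent_node.age + 1e-12


class TestCollapseToRank:
    def test_genus_collapse_of_t4(self, t4, t4_table):
        out = pf.collapse_to_rank(t4, t4_table, "genus")
        assert pf.write_newick(out).strip() == "(G1:2,G2:2);"

    def test_species_rank_is_identity(self, t4, t4_table):
        out = pf.collapse_to_rank(t4, t4_table, "species")
        assert pf.write_newick(out) == pf.write_newick(t4)

    def test_single_species_family_is_relabelled_only(self, t4):
        table = make_table(
            t4, genus_of={"A": "G1", "B": "G1", "C": "G2", "D": "G2"},
            family_of={"A": "FamA", "B": "FamB", "C": "FamB", "D": "FamB"})
        out = pf.collapse_to_rank(t4, table, "family")
        labels = sorted(lv.taxon.label for lv in out.leaf_node_iter())
        assert labels == ["FamA", "FamB"]
        dm = pf.patristic_matrix(out)
        assert dm.values.max() == pytest.approx(2.0)  # A-B distance preserved

    def test_exemplar_is_lexicographically_first(self):
        tree = pf.simulate_tree(20, seed=2)
        tax = pf.simulate_taxonomy(tree, 2, 2)
        tax["r1"] = 1
        table = pf.TaxonTable(data=tax, regions=("r1",))
        out = pf.collapse_to_rank(tree, table, "genus")
        dm_full = pf.patristic_matrix(tree)
        dm_gen = pf.patristic_matrix(out)
        exemplars = tax.groupby("genus")["species"].min()
        for ga in exemplars.index:
            for gb in exemplars.index:
                full = dm_full.values[dm_full.labels.index(exemplars[ga]),
                                      dm_full.labels.index(exemplars[gb])]
                coll = dm_gen.values[dm_gen.labels.index(ga),
                                     dm_gen.labels.index(gb)]
                assert coll == pytest.approx(full, abs=1e-9)
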