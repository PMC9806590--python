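"""Support-annotated Newick parsing and shared-clade detection."""

import pytest

from tirscape import synthetic_data as sd
from tirscape.clade_analysis import (
    SupportParseError,
    find_shared_clades,
    lineage_presence_from_clades,
    parse_newick_with_support,
    select_representatives,
)

TAX4 = {
    "A": ("spA", "Rosids"),
    "B": ("spB", "Asterids"),
    "C": ("spC", "Rosids"),
    "D": ("spD", "monocots"),
}


def write_tree(tmp_path, newick):
    path = tmp_path / "t.nwk"
    path.write_text(newick + "\n")
    return path


def brute_force_shared_clades(atree, min_ufboot=90.0, min_sh_alrt=80.0,
                              min_lineages=2):
    """Independent per-node evaluation plus subset-based maximality."""
    qualifying = []
    for node in atree.tree.preorder_node_iter():
        if node.is_leaf():
            continue
        uf, sh = getattr(node, "ufboot", None), getattr(node, "sh_alrt", None)
        if uf is None or uf <= min_ufboot:
            continue
        if min_sh_alrt is not None and (sh is None or sh <= min_sh_alrt):
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len({atree.lineage_of(l) for l in leaves}) >= min_lineages:
            qualifying.append(leaves)
    return {
        s for s in qualifying
        if not any(s < t for t in qualifying)
    }


class TestParseNewick:
    def test_single_dialect(self, tmp_path):
        path = write_tree(tmp_path, "((A,B)95,C);")
        atree = parse_newick_with_support(path, "single",
                                          {k: TAX4[k] for k in "ABC"})
        supports = [
            (n.sh_alrt, n.ufboot)
            for n in atree.tree.preorder_node_iter()
            if not n.is_leaf()
        ]
        assert (None, 95.0) in supports

    def test_dual_dialect(self, tmp_path):
        path = write_tree(tmp_path, "((A,B)80/95,C);")
        atree = parse_newick_with_support(path, "dual",
                                          {k: TAX4[k] for k in "ABC"})
        supports = [
            (n.sh_alrt, n.ufboot)
            for n in atree.tree.preorder_node_iter()
            if not n.is_leaf()
        ]
        assert (80.0, 95.0) in supports

    def test_unlabeled_nodes_have_no_support(self, tmp_path):
        path = write_tree(tmp_path, "((A,B),C);")
        atree = parse_newick_with_support(path, "dual",
                                          {k: TAX4[k] for k in "ABC"})
        assert all(
            n.sh_alrt is None and n.ufboot is None
            for n in atree.tree.preorder_node_iter()
        )

    def test_unparseable_label_raises(self, tmp_path):
        path = write_tree(tmp_path, "((A,B)high,C);")
        with pytest.raises(SupportParseError, match="high"):
            parse_newick_with_support(path, "dual", {k: TAX4[k] for k in "ABC"})

    def test_leaf_missing_from_taxonomy_raises(self, tmp_path):
        path = write_tree(tmp_path, "((A,B)80/95,Z);")
        with pytest.raises(ValueError, match="Z"):
            parse_newick_with_support(path, "dual", TAX4)

    def test_leaf_count_matches_generated_taxonomy(self, tmp_path):
        """Synthetic round-trip: parsed leaves equal the emitted taxonomy rows."""
        sim = sd.simulate_tree(sd.TreeSpec(n_leaves=80, n_decoys=2), seed=5)
        paths = sim.write(tmp_path)
        from tirscape.clade_analysis import read_taxonomy

        tax = read_taxonomy(paths["taxonomy"])
        atree = parse_newick_with_support(paths["tree"], "dual", tax)
        assert sorted(atree.leaf_ids) == sorted(tax.keys())
        assert len(atree.leaf_ids) == 80


class TestFindSharedClades:
    def test_single_lineage_tree_yields_nothing(self, tmp_path):
        path = write_tree(tmp_path, "((A,C)90/95,(A2,C2)90/95);")
        tax = {"A": ("spA", "Rosids"), "C": ("spC", "Rosids"),
               "A2": ("spA", "Rosids"), "C2": ("spC", "Rosids")}
        atree = parse_newick_with_support(path, "dual", tax)
        assert find_shared_clades(atree) == []

    def test_support_threshold_is_strict(self, tmp_path):
        # 95 qualifies (> 90), 85 and exactly 90 do not
        path = write_tree(tmp_path, "(((A,B)85/95,(C,D)85/85)10/20,(E,F)85/90);")
        tax = {**{k: TAX4[k] for k in "ABCD"},
               "E": ("spE", "Rosids"), "F": ("spF", "Asterids")}
        atree = parse_newick_with_support(path, "dual", tax)
        groups = find_shared_clades(atree, min_ufboot=90, min_sh_alrt=80)
        assert [sorted(g.member_leaves) for g in groups] == [["A", "B"]]

    def test_missing_support_fails_rather_than_errors(self, tmp_path):
        path = write_tree(tmp_path, "((A,B),(C,D)85/95);")
        atree = parse_newick_with_support(path, "dual", TAX4)
        groups = find_shared_clades(atree)
        assert [sorted(g.member_leaves) for g in groups] == [["C", "D"]]

    def test_sh_alrt_requirement_optional(self, tmp_path):
        path = write_tree(tmp_path, "((A,B)95,(C,D)91);")
        atree = parse_newick_with_support(path, "single", TAX4)
        assert find_shared_clades(atree, min_sh_alrt=80) == []
        got = find_shared_clades(atree, min_sh_alrt=None)
        assert len(got) == 2

    def test_maximality_and_nested_flag(self, tmp_path):
        path = write_tree(tmp_path, "(((A,B)90/95,C)90/96,(D,D2)10/10);")
        tax = {**TAX4, "D2": ("spD2", "magnoliids")}
        atree = parse_newick_with_support(path, "dual", tax)
        maximal = find_shared_clades(atree)
        assert [sorted(g.member_leaves) for g in maximal] == [["A", "B", "C"]]
        nested = find_shared_clades(atree, include_nested=True)
        assert sorted(sorted(g.member_leaves) for g in nested) == [
            ["A", "B"], ["A", "B", "C"],
        ]

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_brute_force_on_small_trees(self, seed, tmp_path):
        sim = sd.simulate_tree(
            sd.TreeSpec(n_leaves=60, n_decoys=3, decoy_size=5,
                        clades=(sd.PlantedClade(8, ("Rosids", "Asterids")),
                                sd.PlantedClade(6, ("monocots", "magnoliids")))),
            seed=seed,
        )
        paths = sim.write(tmp_path / str(seed))
        from tirscape.clade_analysis import read_taxonomy

        atree = parse_newick_with_support(paths["tree"], "dual",
                                          read_taxonomy(paths["taxonomy"]))
        got = {g.member_leaves for g in find_shared_clades(atree)}
        assert got == brute_force_shared_clades(atree)

    @pytest.mark.parametrize("seed", range(5))
    def test_raising_threshold_never_adds_groups(self, seed, tmp_path):
        sim = sd.simulate_tree(sd.TreeSpec(n_leaves=100, n_decoys=4), seed=seed)
        paths = sim.write(tmp_path / str(seed))
        from tirscape.clade_analysis import read_taxonomy

        atree = parse_newick_with_support(paths["tree"], "dual",
                                          read_taxonomy(paths["taxonomy"]))
        # monotonicity holds for the qualifying-clade sets themselves: a
        # higher threshold admits a subset of the clades (maximal-group
        # counts are not monotone, since a newly qualifying ancestor can
        # absorb several previously maximal groups)
        sets = [
            {g.member_leaves
             for g in find_shared_clades(atree, min_ufboot=t, min_sh_alrt=None,
                                         include_nested=True)}
            for t in (50, 70, 90, 96)
        ]
        for wider, tighter in zip(sets, sets[1:]):
            assert tighter <= wider

    def test_returned_groups_pairwise_non_nested(self, tmp_path):
        sim = sd.simulate_tree(sd.TreeSpec(), seed=11)
        paths = sim.write(tmp_path)
        from tirscape.clade_analysis import read_taxonomy

        atree = parse_newick_with_support(paths["tree"], "dual",
                                          read_taxonomy(paths["taxonomy"]))
        groups = find_shared_clades(atree)
        sets = [g.member_leaves for g in groups]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                assert not (a <= b or b <= a)

    def test_rerooting_preserves_clades_off_the_root_path(self, tmp_path):
        newick = "(((A,B)85/95,(C,D)10/20)30/40,((E,F)20/30,G)40/50);"
        tax = {**TAX4, "E": ("spE", "Rosids"), "F": ("spF", "Rosids"),
               "G": ("spG", "monocots")}
        path = write_tree(tmp_path, newick)
        atree = parse_newick_with_support(path, "dual", tax)
        before = {g.member_leaves for g in find_shared_clades(atree)}
        # reroot on the edge above leaf G; the planted (A,B) clade avoids
        # the old-root-to-new-root path
        g_leaf = [l for l in atree.tree.leaf_node_iter() if l.taxon.label == "G"][0]
        atree.tree.reroot_at_edge(g_leaf.edge, update_bipartitions=False)
        after = {g.member_leaves for g in find_shared_clades(atree)}
        assert frozenset({"A", "B"}) in before
        assert frozenset({"A", "B"}) in after


class TestSelectRepresentatives:
    def make(self, tmp_path):
        sim = sd.simulate_tree(sd.TreeSpec(n_leaves=100, n_decoys=4), seed=3)
        paths = sim.write(tmp_path)
        from tirscape.clade_analysis import read_taxonomy

        atree = parse_newick_with_support(paths["tree"], "dual",
                                          read_taxonomy(paths["taxonomy"]))
        return atree, find_shared_clades(atree)

    def test_large_per_group_returns_all_members(self, tmp_path):
        atree, groups = self.make(tmp_path)
        chosen = select_representatives(atree, groups, per_group=10_000, seed=0)
        assert sorted(chosen) == sorted(
            l for g in groups for l in g.member_leaves
        )

    def test_deterministic_under_seed(self, tmp_path):
        atree, groups = self.make(tmp_path)
        a = select_representatives(atree, groups, per_group=5, seed=42)
        b = select_representatives(atree, groups, per_group=5, seed=42)
        assert a == b

    def test_stratified_by_lineage(self, tmp_path):
        atree, groups = self.make(tmp_path)
        for g in groups:
            chosen = select_representatives(atree, [g], per_group=3, seed=1)
            lineages_chosen = {atree.lineage_of(l) for l in chosen}
            expect = min(3, len(g.lineages))
            assert len(lineages_chosen) >= expect

    def test_empty_group_list(self, tmp_path):
        atree, _ = self.make(tmp_path)
        assert select_representatives(atree, [], per_group=3, seed=1) == []


def test_lineage_presence_matrix(tmp_path):
    sim = sd.simulate_tree(sd.TreeSpec(n_leaves=80, n_decoys=2), seed=7)
    paths = sim.write(tmp_path)
    from tirscape.clade_analysis import read_taxonomy

    tax = read_taxonomy(paths["taxonomy"])
    atree = parse_newick_with_support(paths["tree"], "dual", tax)
    groups = find_shared_clades(atree)
    leaf_species = {l: atree.species_of(l) for l in atree.leaf_ids}
    pm = lineage_presence_from_clades(groups, leaf_species)
    for g in groups:
        present = {leaf_species[l] for l in g.member_leaves}
        for sp in pm.species_ids:
            assert pm.df.loc[g.group_label, sp] == (sp in present)
    assert lineage_presence_from_clades([], leaf_species, ["s"]).df.empty
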