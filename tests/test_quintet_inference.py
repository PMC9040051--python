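import numpy as np
import pytest

from conftest import random_multispecies_tree
from cytorate.codon_ml import QUINTET_BRANCHES, BranchRate, BranchRates
from cytorate.io_formats import GeneTree, resolve_roles
from cytorate.quintet_inference import (
    CONCORDANT,
    DISCORDANT,
    UNRESOLVED,
    Quintet,
    check_topology_concordance,
    collapse_low_support,
    extract_species_complete_subtrees,
    filter_by_tree_ds,
    infer_phylogenetic_quintets,
    merge_quintet_sets,
    quintets_from_table,
    quintets_to_table,
    trim_lineage_duplicates,
)
from cytorate.synthetic_data import DEFAULT_SPECIES_MAP, simulate_gene_tree_set, tip_ids


def brute_force_species_complete(tree: GeneTree, species_map) -> set[frozenset]:
    """Independent clade-by-clade check of the two defining conditions."""
    roles = resolve_roles(tree, species_map)
    all_roles = {"outgroup", "diploid_maternal", "diploid_paternal", "polyploid"}

    nodes = list(tree.tree.preorder_node_iter())

    def tipset(node):
        return frozenset(l.taxon.label for l in node.leaf_iter())

    def complete(node):
        return {roles[t].role for t in tipset(node)} >= all_roles

    selected = set()
    for node in nodes:
        if not complete(node):
            continue
        tips = tipset(node)
        has_complete_descendant = any(
            complete(child) and tipset(child) < tips
            for other in node.child_nodes()
            for child in [other, *other.preorder_iter()]
        )
        if not has_complete_descendant:
            selected.add(tips)
    return selected


class TestCollapseLowSupport:
    def test_boundary_support_collapsed(self):
        t = GeneTree.from_newick("((A,B)50,(C,D)80,E);")
        out = collapse_low_support(t, threshold=50)
        assert frozenset({"A", "B"}) not in out.bipartitions()
        assert frozenset({"C", "D"}) in out.bipartitions()

    def test_high_support_unchanged(self):
        t = GeneTree.from_newick("((A,B)100,(C,D)100,E);")
        out = collapse_low_support(t, 50)
        assert out.bipartitions() == t.bipartitions()

    def test_idempotent_on_star_tree(self):
        t = GeneTree.from_newick("((A,B)10,(C,D)20,E);")
        once = collapse_low_support(t, 50)
        twice = collapse_low_support(once, 50)
        assert once.bipartitions() == set()
        assert twice.bipartitions() == set()
        assert sorted(twice.tip_labels()) == ["A", "B", "C", "D", "E"]

    def test_missing_support_never_collapsed(self):
        t = GeneTree.from_newick("((A,B),(C,D)30,E);")
        out = collapse_low_support(t, 50)
        assert frozenset({"A", "B"}) in out.bipartitions()
        assert frozenset({"C", "D"}) not in out.bipartitions()


class TestExtractSpeciesComplete:
    def test_five_tip_quintet_returns_whole_tree(self, species_map):
        ids = tip_ids("g1")
        t = GeneTree.from_newick(
            "((({pp},{dp}),({pm},{dm})),{o});".format(
                pp=ids["polyploid_paternal"], dp=ids["diploid_paternal"],
                pm=ids["polyploid_maternal"], dm=ids["diploid_maternal"],
                o=ids["outgroup"],
            )
        )
        subs = extract_species_complete_subtrees(t, species_map)
        assert len(subs) == 1
        assert sorted(subs[0].tip_labels()) == sorted(t.tip_labels())

    def test_two_sibling_complete_clades_both_returned(self, species_map):
        # two sister species-complete clades: both minimal, union is not
        clade1 = "(((Poly_P1,Dpat_1),(Poly_M1,Dmat_1)),Outg_1)"
        clade2 = "(((Poly_P2,Dpat_2),(Poly_M2,Dmat_2)),Outg_2)"
        t = GeneTree.from_newick(f"({clade1},{clade2});")
        subs = extract_species_complete_subtrees(t, species_map)
        assert len(subs) == 2
        tipsets = {frozenset(s.tip_labels()) for s in subs}
        assert frozenset({"Poly_P1", "Dpat_1", "Poly_M1", "Dmat_1", "Outg_1"}) in tipsets

    def test_no_outgroup_gives_empty_result(self, species_map):
        t = GeneTree.from_newick("((Poly_P1,Dpat_1),(Poly_M1,Dmat_1));")
        assert extract_species_complete_subtrees(t, species_map) == []

    def test_matches_brute_force_on_random_trees(self, species_map):
        rng = np.random.default_rng(17)
        for _ in range(300):
            t = GeneTree.from_newick(random_multispecies_tree(rng))
            got = {
                frozenset(s.tip_labels())
                for s in extract_species_complete_subtrees(t, species_map)
            }
            expected = brute_force_species_complete(t, species_map)
            assert got == expected


class TestTrimDuplicates:
    def test_longest_paralog_kept(self, species_map):
        t = GeneTree.from_newick(
            "((((Dpat_1a,Dpat_1b),Poly_P1),(Poly_M1,Dmat_1)),Outg_1);"
        )
        lengths = {"Dpat_1a": 300, "Dpat_1b": 450}
        out = trim_lineage_duplicates(t, lengths, seed=0, species_map=species_map)
        labels = out.tip_labels()
        assert "Dpat_1b" in labels and "Dpat_1a" not in labels
        assert len(labels) == 5

    def test_equal_length_tie_is_seeded_and_reproducible(self, species_map):
        t = GeneTree.from_newick(
            "((((Dpat_1a,Dpat_1b),Poly_P1),(Poly_M1,Dmat_1)),Outg_1);"
        )
        lengths = {"Dpat_1a": 300, "Dpat_1b": 300}
        picks = {
            tuple(sorted(
                trim_lineage_duplicates(t, lengths, seed=42,
                                        species_map=species_map).tip_labels()
            ))
            for _ in range(3)
        }
        assert len(picks) == 1  # same choice on every rerun

    def test_no_duplicates_unchanged(self, species_map):
        t = GeneTree.from_newick(
            "(((Poly_P1,Dpat_1),(Poly_M1,Dmat_1)),Outg_1);"
        )
        out = trim_lineage_duplicates(t, {}, seed=0, species_map=species_map)
        assert sorted(out.tip_labels()) == sorted(t.tip_labels())

    def test_polyploid_subgenomes_are_separate_lineages(self, species_map):
        # Poly_M and Poly_P are different units: both kept
        t = GeneTree.from_newick(
            "((((Poly_P1,Poly_P2),Dpat_1),(Poly_M1,Dmat_1)),Outg_1);"
        )
        out = trim_lineage_duplicates(
            t, {"Poly_P1": 10, "Poly_P2": 5}, seed=0, species_map=species_map
        )
        labels = out.tip_labels()
        assert "Poly_P1" in labels and "Poly_M1" in labels
        assert "Poly_P2" not in labels


def _quintet(gid, ids, source="phylogenetic"):
    roles = ("outgroup", "diploid_maternal", "diploid_paternal",
             "polyploid_maternal", "polyploid_paternal")
    return Quintet(gene_id=gid, members=dict(zip(roles, ids)), source=source)


class TestMergeQuintets:
    def test_identical_quintet_in_intersection_and_union_once(self):
        p = [_quintet("p1", ["o1", "m1", "f1", "pm1", "pp1"])]
        s = [_quintet("s1", ["o1", "m1", "f1", "pm1", "pp1"], "syntenic")]
        merged = merge_quintet_sets(p, s)
        assert len(merged.intersection) == 1
        assert len(merged.union) == 1
        assert merged.union[0].source == "both"
        assert merged.conflicts == []

    def test_disjoint_quintet_union_only(self):
        p = [_quintet("p1", ["o1", "m1", "f1", "pm1", "pp1"])]
        s = [_quintet("s1", ["o2", "m2", "f2", "pm2", "pp2"], "syntenic")]
        merged = merge_quintet_sets(p, s)
        assert len(merged.union) == 2
        assert merged.intersection == []

    def test_partial_overlap_is_conflict(self):
        p = [_quintet("p1", ["o1", "m1", "f1", "pm1", "pp1"])]
        s = [_quintet("s1", ["o1", "m1", "f1", "pm1", "ppX"], "syntenic")]
        merged = merge_quintet_sets(p, s)
        assert len(merged.conflicts) == 2
        assert merged.union == [] and merged.intersection == []

    def test_duplicate_gene_id_rejected(self):
        p = [_quintet("p1", ["o1", "m1", "f1", "pm1", "pp1"]),
             _quintet("p1", ["o2", "m2", "f2", "pm2", "pp2"])]
        with pytest.raises(ValueError, match="duplicate"):
            merge_quintet_sets(p, [])

    def test_partition_invariants_on_random_sets(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            def rand_quintets(prefix, n):
                out = []
                for i in range(n):
                    pool = rng.integers(0, 6, size=5)
                    ids = [f"{r}{pool[k]}" for k, r in
                           enumerate(["o", "m", "f", "pm", "pp"])]
                    out.append(_quintet(f"{prefix}{i}", ids))
                return out

            p = rand_quintets("p", int(rng.integers(1, 6)))
            s = rand_quintets("s", int(rng.integers(1, 6)))
            merged = merge_quintet_sets(p, s)
            union_sets = {q.member_set for q in merged.union}
            inter_sets = {q.member_set for q in merged.intersection}
            conflict_ids = {q.gene_id for q in merged.conflicts}
            assert inter_sets <= union_sets
            assert conflict_ids.isdisjoint(q.gene_id for q in merged.union)

    def test_table_round_trip(self):
        p = [_quintet("p1", ["o1", "m1", "f1", "pm1", "pp1"])]
        table = quintets_to_table(p)
        again = quintets_from_table(table)
        assert again[0].member_set == p[0].member_set


class TestTopologyConcordance:
    def newick(self, pp, dp, pm, dm):
        ids = tip_ids("g1")
        return "((({a},{b})90,({c},{d})90)90,{o});".format(
            a=ids[pp], b=ids[dp], c=ids[pm], d=ids[dm], o=ids["outgroup"]
        )

    def test_species_topology_concordant(self, species_map):
        t = GeneTree.from_newick(self.newick(
            "polyploid_paternal", "diploid_paternal",
            "polyploid_maternal", "diploid_maternal"))
        assert check_topology_concordance(t, species_map) == CONCORDANT

    def test_swapped_diploids_discordant(self, species_map):
        t = GeneTree.from_newick(self.newick(
            "polyploid_paternal", "diploid_maternal",
            "polyploid_maternal", "diploid_paternal"))
        assert check_topology_concordance(t, species_map) == DISCORDANT

    def test_star_ingroup_unresolved(self, species_map):
        ids = tip_ids("g1")
        t = GeneTree.from_newick(
            "({pp},{dp},{pm},{dm},{o});".format(
                pp=ids["polyploid_paternal"], dp=ids["diploid_paternal"],
                pm=ids["polyploid_maternal"], dm=ids["diploid_maternal"],
                o=ids["outgroup"])
        )
        assert check_topology_concordance(t, species_map) == UNRESOLVED

    def test_one_cherry_resolved_is_unresolved(self, species_map):
        ids = tip_ids("g1")
        t = GeneTree.from_newick(
            "(({pp},{dp})90,{pm},{dm},{o});".format(
                pp=ids["polyploid_paternal"], dp=ids["diploid_paternal"],
                pm=ids["polyploid_maternal"], dm=ids["diploid_maternal"],
                o=ids["outgroup"])
        )
        assert check_topology_concordance(t, species_map) == UNRESOLVED

    def test_wrong_tip_count_rejected(self, species_map):
        t = GeneTree.from_newick("((Poly_P1,Dpat_1),(Poly_M1,Dmat_1));")
        with pytest.raises(ValueError):
            check_topology_concordance(t, species_map)


class TestDsFilter:
    def make_rates(self, tree_ds):
        per_branch = tree_ds / 7
        branches = {
            b: BranchRate(t=0.1, dn=0.01, ds=per_branch, omega=0.2)
            for b in QUINTET_BRANCHES
        }
        return BranchRates(branches=branches, kappa=2.0, lnl=-1.0)

    def test_above_cutoff_dropped(self):
        assert filter_by_tree_ds(self.make_rates(5.0), cutoff=2.0) is False

    def test_at_cutoff_kept(self):
        assert filter_by_tree_ds(self.make_rates(2.0), cutoff=2.0) is True

    def test_below_cutoff_kept(self):
        assert filter_by_tree_ds(self.make_rates(0.5), cutoff=2.0) is True


class TestPipelineOnSimulatedTrees:
    def test_concordant_fraction_tracks_discordance_rate(self, species_map):
        d = 0.3
        n = 400
        trees, _ = simulate_gene_tree_set(
            n, discordance_rate=d, duplication_rate=0.2,
            low_support_rate=0.0, seed=31,
        )
        quintets = infer_phylogenetic_quintets(
            trees, species_map, lengths={}, support_threshold=50, seed=1
        )
        assert len(quintets) == n  # every tree yields a quintet after trimming
        trees_by_gene = dict(zip([f"g{i + 1:04d}" for i in range(n)], trees))
        # verdict on the original (untrimmed) topology mirrors the truth
        from scipy import stats
        verdicts = [
            check_topology_concordance(
                trim_lineage_duplicates(
                    t, {}, seed=0, species_map=species_map
                ), species_map,
            )
            for t in trees
        ]
        frac = np.mean([v == CONCORDANT for v in verdicts])
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 1 - d) / n
        assert lo <= frac <= hi
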