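"""Tree algebra: bipartitions, pruning, distances, RF, and neighbor joining.

Independent oracles: dendropy's bipartition encoding and treecompare for
splits/RF, scikit-bio's nj for topology cross-checks, and brute-force pairwise
loops for distances.
"""

import itertools

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from phylomosaic import seqio, synthetic_data as sd, treekit
from phylomosaic.errors import (
    DegenerateInputError,
    LengthMismatchError,
    MissingTaxonError,
    PhylomosaicError,
    SaturationError,
)
from phylomosaic.supermatrix import Alignment

from conftest import random_resolved_tree


def dendropy_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Oracle: non-trivial splits via dendropy's own bipartition encoding."""
    tree = tree.clone(depth=1)
    tree.encode_bipartitions()
    universe = treekit.leaf_labels(tree)
    out = set()
    for bip in tree.bipartition_encoding:
        side = frozenset(
            t.label
            for t in tree.taxon_namespace.bitmask_taxa_list(bip.leafset_bitmask)
        )
        if 2 <= len(side) <= len(universe) - 2:
            if min(universe) not in side:
                side = frozenset(universe - side)
            out.add(side)
    return out


class TestBipartitions:
    def test_quartet_has_single_split(self, quartet_tree):
        bips = treekit.bipartitions(quartet_tree)
        assert {frozenset(b.side) for b in bips} == {frozenset("AB")}

    def test_resolved_six_leaf_has_three(self, six_leaf_tree):
        assert len(treekit.bipartitions(six_leaf_tree)) == 3

    def test_fewer_than_four_leaves_empty(self):
        tree = seqio.read_newick("((A:1,B:1):1,C:1);")
        assert treekit.bipartitions(tree) == set()

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_encoding_on_random_trees(self, seed):
        tree = random_resolved_tree(12, seed)
        mine = {frozenset(b.side) for b in treekit.bipartitions(tree)}
        assert mine == dendropy_splits(tree)

    @pytest.mark.parametrize("n", [5, 8, 12, 20])
    def test_resolved_tree_has_n_minus_3_splits(self, n):
        tree = random_resolved_tree(n, seed=n)
        assert len(treekit.bipartitions(tree)) == n - 3

    def test_canonicalization_idempotent(self):
        b = treekit.Bipartition.from_side({"C", "D"}, {"A", "B", "C", "D"})
        again = treekit.Bipartition.from_side(b.side, b.universe)
        assert b == again
        assert "A" in b.side  # canonical side holds the smallest taxon


class TestPrune:
    def test_degree_two_suppression_sums_lengths(self, quartet_tree):
        pruned = treekit.prune_to_taxa(quartet_tree, {"A", "C", "D"})
        assert treekit.leaf_labels(pruned) == {"A", "C", "D"}
        # A's cherry partner was removed: its pendant edge absorbs the
        # internal edge (1 + 1)
        assert treekit.patristic_distance(pruned, "A", "C") == pytest.approx(4.0)

    def test_keep_all_is_identity(self, six_leaf_tree):
        pruned = treekit.prune_to_taxa(six_leaf_tree, treekit.leaf_labels(six_leaf_tree))
        rf, _ = treekit.robinson_foulds(six_leaf_tree, pruned)
        assert rf == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_patristic_distances_preserved(self, seed):
        tree = random_resolved_tree(12, seed)
        taxa = sorted(treekit.leaf_labels(tree))
        rng = np.random.default_rng(seed)
        keep = sorted(rng.choice(taxa, size=6, replace=False))
        pruned = treekit.prune_to_taxa(tree, keep)
        for a, b in itertools.combinations(keep, 2):
            assert treekit.patristic_distance(pruned, a, b) == pytest.approx(
                treekit.patristic_distance(tree, a, b), abs=1e-9
            )

    def test_too_few_kept_rejected(self, quartet_tree):
        with pytest.raises(DegenerateInputError):
            treekit.prune_to_taxa(quartet_tree, {"A"})

    def test_unknown_taxon_rejected(self, quartet_tree):
        with pytest.raises(MissingTaxonError):
            treekit.prune_to_taxa(quartet_tree, {"A", "Z"})


class TestPatristic:
    def test_simple_path_sum(self):
        tree = seqio.read_newick("((A:0.1,B:0.2):0.3,C:0.4);")
        assert treekit.patristic_distance(tree, "A", "C") == pytest.approx(0.8)

    def test_self_distance_zero(self, quartet_tree):
        assert treekit.patristic_distance(quartet_tree, "A", "A") == 0.0

    def test_missing_length_on_path_rejected(self):
        tree = seqio.read_newick("((A:1,B),C:1,D:1);")
        with pytest.raises(PhylomosaicError):
            treekit.patristic_distance(tree, "B", "C")

    @pytest.mark.parametrize("seed", range(5))
    def test_matrix_matches_pairwise_walks(self, seed):
        tree = random_resolved_tree(15, seed)
        pm = treekit.patristic_matrix(tree)
        for a, b in itertools.combinations(pm.taxa, 2):
            assert pm.get(a, b) == pytest.approx(
                treekit.patristic_distance(tree, a, b), abs=1e-9
            )


class TestRobinsonFoulds:
    def test_identical_trees_zero(self, six_leaf_tree):
        assert treekit.robinson_foulds(six_leaf_tree, six_leaf_tree) == (0, 0.0)

    def test_one_nni_gives_two(self):
        # exchange B with the CD clade across the AB|CDEF edge: one split swapped
        t1 = seqio.read_newick("(((A:1,B:1):1,(C:1,D:1):1):1,(E:1,F:1):1);")
        t2 = seqio.read_newick("((A:1,(C:1,D:1):1):1,B:1,(E:1,F:1):1);")
        rf, norm = treekit.robinson_foulds(t1, t2)
        assert rf == 2
        assert norm == pytest.approx(2 / (2 * 3))

    def test_leaf_set_mismatch_rejected(self, quartet_tree, six_leaf_tree):
        with pytest.raises(MissingTaxonError):
            treekit.robinson_foulds(quartet_tree, six_leaf_tree)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_on_random_pairs(self, seed):
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(
            data=seqio.write_newick(random_resolved_tree(10, seed)),
            schema="newick",
            taxon_namespace=tns,
        )
        t2 = dendropy.Tree.get(
            data=seqio.write_newick(random_resolved_tree(10, seed + 100)),
            schema="newick",
            taxon_namespace=tns,
        )
        expected = treecompare.symmetric_difference(t1, t2)
        rf, _ = treekit.robinson_foulds(t1, t2)
        assert rf == expected

    def test_metric_axioms_on_random_triples(self):
        trees = [random_resolved_tree(8, s) for s in (0, 1, 2)]
        d = lambda a, b: treekit.robinson_foulds(a, b)[0]
        for a, b in itertools.combinations(trees, 2):
            assert d(a, b) == d(b, a) >= 0
        assert d(trees[0], trees[2]) <= d(trees[0], trees[1]) + d(trees[1], trees[2])


class TestPDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0.0),
            ("ACGT", "AGGT", 0.25),
            ("AC-T", "ACGT", 0.0),  # 3 shared sites, all matching
        ],
    )
    def test_reference_values(self, a, b, expected):
        assert treekit.p_distance(a, b, min_overlap=1) == pytest.approx(expected)

    def test_overlap_floor_returns_absent(self):
        assert treekit.p_distance("ACGT", "ACGT", min_overlap=5) is None

    def test_ambiguity_codes_excluded(self):
        assert treekit.p_distance("ANGT", "ACGT", min_overlap=1) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(LengthMismatchError):
            treekit.p_distance("ACGT", "ACG")


class TestJukesCantor:
    def test_zero_maps_to_zero(self):
        assert treekit.jc_correct(0.0) == 0.0

    def test_closed_form_value(self):
        assert treekit.jc_correct(0.1) == pytest.approx(
            -0.75 * np.log(1 - 0.4 / 3), rel=1e-12
        )

    def test_saturated_rejected(self):
        with pytest.raises(SaturationError):
            treekit.jc_correct(0.75)

    def test_recovers_simulated_jc_branch_length(self):
        # two leaves at total path 0.3 under an equal-rates model
        tree = seqio.read_newick("(A:0.15,B:0.15);")
        aln = sd.simulate_alignment_gtr(
            tree,
            20000,
            exchangeabilities=(1.0,) * 6,
            base_frequencies=(0.25,) * 4,
            seed=11,
        )
        p = treekit.p_distance(aln.rows["A"], aln.rows["B"])
        d = treekit.jc_correct(p)
        se = np.sqrt(p * (1 - p) / 20000) / (1 - 4 * p / 3)
        assert abs(d - 0.3) < 3 * se


class TestDistanceMatrix:
    def test_identical_rows_all_zero(self):
        aln = Alignment("m", {t: "ACGT" * 10 for t in "abc"})
        dm = treekit.distance_matrix(aln, min_overlap=1)
        assert np.allclose(dm.values, 0.0)

    def test_matches_direct_pairwise_loop(self):
        rng = np.random.default_rng(7)
        rows = {
            f"t{i}": "".join(rng.choice(list("ACGT-"), size=100)) for i in range(4)
        }
        aln = Alignment("m", rows)
        dm = treekit.distance_matrix(aln, min_overlap=1)
        for a, b in itertools.combinations(aln.taxa, 2):
            assert dm.get(a, b) == pytest.approx(
                treekit.p_distance(rows[a], rows[b], min_overlap=1)
            )

    def test_symmetric_and_round_trips_tsv(self, tmp_path):
        aln = Alignment("m", {t: "ACGT" * 10 for t in "abcd"})
        dm = treekit.distance_matrix(aln)
        assert np.allclose(dm.values, dm.values.T)
        path = tmp_path / "dm.tsv"
        dm.write_tsv(path)
        back = treekit.DistanceMatrix.read_tsv(path)
        assert back.taxa == dm.taxa
        assert np.allclose(back.values, dm.values, equal_nan=True)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = treekit.DistanceMatrix(
            ["a", "b", "c"],
            np.array([[0.0, 0.2, 0.3], [0.2, 0.0, 0.4], [0.3, 0.4, 0.0]]),
        )
        tree = treekit.neighbor_joining(dm)
        lengths = {
            leaf.taxon.label: leaf.edge.length for leaf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 0.05, "b": 0.15, "c": 0.25})

    @pytest.mark.parametrize("seed", range(5))
    def test_additive_matrix_recovered_exactly(self, seed):
        source = random_resolved_tree(8, seed)
        dm = treekit.patristic_matrix(source)
        tree = treekit.neighbor_joining(dm)
        rf, _ = treekit.robinson_foulds(tree, source)
        assert rf == 0
        back = treekit.patristic_matrix(tree).subset(dm.taxa)
        assert np.allclose(back.values, dm.values, atol=1e-9)

    def test_tie_breaks_to_lowest_index_pair_deterministically(self):
        # fully symmetric distances: every Q entry ties
        n = 4
        values = np.full((n, n), 1.0) - np.eye(n)
        dm = treekit.DistanceMatrix(list("abcd"), values)
        t1 = treekit.neighbor_joining(dm)
        t2 = treekit.neighbor_joining(dm)
        assert seqio.write_newick(t1) == seqio.write_newick(t2)
        sides = {frozenset(b.side) for b in treekit.bipartitions(t1)}
        assert sides == {frozenset("ab")}  # lowest (row, col) pair joined first

    def test_absent_entries_rejected_with_guidance(self):
        values = np.array(
            [[0.0, np.nan, 0.3], [np.nan, 0.0, 0.4], [0.3, 0.4, 0.0]]
        )
        dm = treekit.DistanceMatrix(["a", "b", "c"], values)
        with pytest.raises(PhylomosaicError, match="impute|drop"):
            treekit.neighbor_joining(dm)

    @pytest.mark.parametrize("seed", range(3))
    def test_topology_agrees_with_skbio(self, seed):
        skbio = pytest.importorskip("skbio")
        source = random_resolved_tree(10, seed)
        dm = treekit.patristic_matrix(source)
        sk_dm = skbio.DistanceMatrix(dm.values, ids=dm.taxa)
        sk_tree = skbio.tree.nj(sk_dm)
        mine = treekit.neighbor_joining(dm)
        theirs = seqio.read_newick(str(sk_tree))
        rf, _ = treekit.robinson_foulds(mine, theirs)
        assert rf == 0

    def test_recovery_rate_from_simulated_alignments(self):
        """NJ on JC-corrected distances recovers the generating topology on
        resolvable trees (shortest internal edge >= 0.01 subst/site)."""
        recovered = total = 0
        seed = 0
        while total < 10:
            cfg = sd.SimulationConfig(
                n_taxa=10,
                n_groups=2,
                markers=[(f"g{i}", 2000, 0.5) for i in range(3)],
                dropout=0.0,
                seed=seed,
                gtr_exchangeabilities=(1.0,) * 6,
                base_frequencies=(0.25,) * 4,
            )
            seed += 1
            species, alns, _, _ = sd.make_dataset(cfg)
            internal = [
                nd.edge.length
                for nd in species.preorder_node_iter()
                if nd.parent_node is not None and not nd.is_leaf()
            ]
            if min(internal) < 0.01:
                continue
            total += 1
            from phylomosaic.supermatrix import concatenate
            from phylomosaic.sensitivity import default_engine

            tree = default_engine(concatenate(alns))
            rf, _ = treekit.robinson_foulds(species, tree)
            recovered += rf == 0
        assert recovered >= round(0.95 * total)
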