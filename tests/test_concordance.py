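"""Concordance bookkeeping: per-marker counts, gCF, sCF, and summaries.

The brute-force oracle for restricted-split concordance enumerates, for every
reference bipartition, whether any gene-tree edge induces the same split after
restriction to the gene tree's taxon set.
"""

import numpy as np
import pytest

from phylomosaic import concordance as cc, seqio, synthetic_data as sd, treekit
from phylomosaic.errors import DegenerateInputError, PhylomosaicError
from phylomosaic.supermatrix import Alignment, concatenate

from conftest import random_resolved_tree


def oracle_marker_counts(gene_tree, reference):
    """Independent recomputation of (concordant, discordant, missing)."""
    gene_taxa = treekit.leaf_labels(gene_tree)
    gene_sides = set()
    for b in treekit.bipartitions(gene_tree):
        gene_sides.add(frozenset(b.side))
        gene_sides.add(frozenset(b.other_side))
    conc = disc = miss = 0
    for bip in treekit.bipartitions(reference):
        a = bip.side & gene_taxa
        b = bip.other_side & gene_taxa
        if len(a) < 2 or len(b) < 2:
            miss += 1
        elif a in gene_sides or b in gene_sides:
            conc += 1
        else:
            disc += 1
    return conc, disc, miss


class TestConcordancePercentage:
    @pytest.mark.parametrize(
        "concordant,total,missing,expected",
        [
            (25, 80, 44, 69.4),  # 25 / 36 assessable
            (40, 80, 36, 90.9),  # 40 / 44 assessable
        ],
    )
    def test_assessable_node_arithmetic(self, concordant, total, missing, expected):
        pct = cc.concordance_percentage(concordant, total, missing)
        assert round(pct, 1) == expected

    def test_nothing_assessable_is_undefined(self):
        assert cc.concordance_percentage(0, 10, 10) is None


class TestMarkerConcordance:
    def test_identical_tree_full_overlap(self):
        ref = random_resolved_tree(10, seed=1)
        mc = cc.marker_concordance(ref, ref, marker="self")
        assert mc.n_total == 7  # n - 3
        assert mc.n_concordant == 7
        assert mc.n_missing == 0
        assert mc.percentage == pytest.approx(100.0)

    def test_tiny_gene_tree_all_missing(self):
        ref = random_resolved_tree(8, seed=2)
        keep = sorted(treekit.leaf_labels(ref))[:3]
        gene = treekit.prune_to_taxa(ref, keep)
        mc = cc.marker_concordance(gene, ref)
        assert mc.n_missing == mc.n_total
        assert mc.percentage is None

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_restricted_split_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_resolved_tree(12, seed=seed)
        taxa = sorted(treekit.leaf_labels(ref))
        keep = sorted(rng.choice(taxa, size=rng.integers(4, 11), replace=False))
        gene = treekit.prune_to_taxa(ref, keep)
        if rng.random() < 0.5:  # sometimes perturb so discordance appears
            gene = sd.nni_perturb(gene, 2, seed=seed)
        mc = cc.marker_concordance(gene, ref)
        conc, disc, miss = oracle_marker_counts(gene, ref)
        assert (mc.n_concordant, mc.n_discordant, mc.n_missing) == (conc, disc, miss)

    def test_counts_always_sum_to_total(self):
        for seed in range(5):
            ref = random_resolved_tree(10, seed=seed)
            keep = sorted(treekit.leaf_labels(ref))[:6]
            gene = treekit.prune_to_taxa(ref, keep)
            mc = cc.marker_concordance(gene, ref)
            assert mc.n_concordant + mc.n_discordant + mc.n_missing == mc.n_total

    def test_invariant_under_rerooting(self):
        ref = random_resolved_tree(10, seed=9)
        gene = treekit.prune_to_taxa(ref, sorted(treekit.leaf_labels(ref))[:7])
        mc1 = cc.marker_concordance(gene, ref)
        rerooted = gene.clone(depth=1)
        leaf = next(rerooted.leaf_node_iter())
        rerooted.reroot_at_edge(leaf.edge, update_bipartitions=False)
        mc2 = cc.marker_concordance(rerooted, ref)
        assert (mc1.n_concordant, mc1.n_missing) == (mc2.n_concordant, mc2.n_missing)

    def test_dropout_only_gene_trees_stay_fully_concordant(self):
        """Gene trees that are the species tree with taxa dropped are 100%
        concordant; missing nodes grow with the dropout rate."""
        ref = random_resolved_tree(14, seed=11)
        taxa = sorted(treekit.leaf_labels(ref))
        rng = np.random.default_rng(0)
        missing_by_rate = []
        for rate in (0.2, 0.5):
            n_keep = max(4, int(len(taxa) * (1 - rate)))
            keep = sorted(rng.choice(taxa, size=n_keep, replace=False))
            mc = cc.marker_concordance(treekit.prune_to_taxa(ref, keep), ref)
            assert mc.percentage == pytest.approx(100.0)
            missing_by_rate.append(mc.n_missing)
        assert missing_by_rate[0] < missing_by_rate[1]


class TestGeneConcordanceFactors:
    def test_all_identical_gene_trees_give_100(self):
        ref = random_resolved_tree(8, seed=3)
        out = cc.node_concordance_factors(ref, [ref] * 4)
        assert len(out) == 5
        assert all(nc.gcf == pytest.approx(100.0) for nc in out)
        assert all(nc.n_decisive == 4 for nc in out)

    def test_half_of_gene_trees_containing_split_give_50(self):
        ref = seqio.read_newick("(((A,B),(C,D)),(E,F));")
        alt = seqio.read_newick("((A,(C,D)),B,(E,F));")  # AB split broken
        out = cc.node_concordance_factors(ref, [ref, ref, alt, alt])
        by_side = {frozenset(nc.bipartition.side): nc for nc in out}
        ab = by_side[
            treekit.Bipartition.from_side({"A", "B"}, treekit.leaf_labels(ref)).side
        ]
        assert ab.gcf == pytest.approx(50.0)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_per_node_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        ref = random_resolved_tree(10, seed=20 + seed)
        taxa = sorted(treekit.leaf_labels(ref))
        genes = []
        for g in range(5):
            keep = sorted(rng.choice(taxa, size=rng.integers(4, 9), replace=False))
            gene = treekit.prune_to_taxa(ref, keep)
            if g % 2:
                gene = sd.nni_perturb(gene, 1, seed=seed * 10 + g)
            genes.append(gene)
        out = cc.node_concordance_factors(ref, genes)
        for nc in out:
            assessable = concordant = 0
            for gene in genes:
                gene_taxa = treekit.leaf_labels(gene)
                a = nc.bipartition.side & gene_taxa
                b = nc.bipartition.other_side & gene_taxa
                if len(a) < 2 or len(b) < 2:
                    continue
                assessable += 1
                gene_sides = set()
                for gb in treekit.bipartitions(gene):
                    gene_sides.add(frozenset(gb.side))
                    gene_sides.add(frozenset(gb.other_side))
                concordant += a in gene_sides or b in gene_sides
            if assessable == 0:
                assert nc.gcf is None
            else:
                assert nc.gcf == pytest.approx(100.0 * concordant / assessable)


class TestSiteConcordanceFactors:
    @staticmethod
    def quartet_matrix(pattern_counts):
        """4-taxon supermatrix whose columns follow given quartet patterns.

        pattern_counts: dict like {"AABB": 30} meaning state(A)=state(B),
        state(C)=state(D) for 30 sites, etc.
        """
        cols = {t: [] for t in "ABCD"}
        for pattern, count in pattern_counts.items():
            for _ in range(count):
                for taxon, sym in zip("ABCD", pattern):
                    cols[taxon].append({"A": "A", "B": "C"}[sym])
        rows = {t: "".join(v) for t, v in cols.items()}
        return concatenate([Alignment("m", rows)])

    def test_uniform_supporting_pattern_gives_100(self):
        ref = seqio.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        matrix = self.quartet_matrix({"AABB": 40})
        (nc,) = cc.site_concordance_factors(ref, matrix, n_quartets=10, seed=1)
        assert nc.scf == pytest.approx(100.0)

    def test_balanced_patterns_give_one_third(self):
        ref = seqio.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        matrix = self.quartet_matrix({"AABB": 50, "ABAB": 50, "ABBA": 50})
        (nc,) = cc.site_concordance_factors(ref, matrix, n_quartets=10, seed=2)
        assert nc.scf == pytest.approx(100 / 3, abs=1e-9)

    def test_same_seed_is_deterministic(self):
        cfg = sd.SimulationConfig(
            n_taxa=12, n_groups=2, markers=[("m1", 400, 1.0)], dropout=0.0, seed=5
        )
        species, alns, _, _ = sd.make_dataset(cfg)
        matrix = concatenate(alns)
        a = cc.site_concordance_factors(species, matrix, n_quartets=25, seed=9)
        b = cc.site_concordance_factors(species, matrix, n_quartets=25, seed=9)
        assert [nc.scf for nc in a] == [nc.scf for nc in b]

    def test_ambiguous_residues_never_decisive(self):
        ref = seqio.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        rows = {"A": "AAN-", "B": "AA??", "C": "CCGT", "D": "CCGT"}
        matrix = concatenate([Alignment("m", rows)])
        (nc,) = cc.site_concordance_factors(ref, matrix, n_quartets=5, seed=3)
        assert nc.scf == pytest.approx(100.0)  # only the two clean sites count


class TestConcordanceSummary:
    def test_single_row_collapses_to_value(self):
        rows = [cc.MarkerConcordance("m", 5, 2, 3, 10, 71.4)]
        assert cc.concordance_summary(rows) == (71.4, 71.4, 71.4)

    def test_empty_subset_rejected(self):
        with pytest.raises((DegenerateInputError, PhylomosaicError)):
            cc.concordance_summary([], subset=[])

    def test_mean_min_max_over_subset(self):
        rows = [
            cc.MarkerConcordance(f"m{i}", 1, 0, 0, 1, pct)
            for i, pct in enumerate([50.0, 70.0, 90.0])
        ]
        mean, lo, hi = cc.concordance_summary(rows, subset=["m0", "m2"])
        assert (mean, lo, hi) == (70.0, 50.0, 90.0)
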