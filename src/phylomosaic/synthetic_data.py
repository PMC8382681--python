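"""Synthetic multi-marker datasets with the structure the analysis assumes.

The generator emulates a sparse multilocus design: a pure-birth (Yule)
species tree; 10-20 markers of 300-2,000 sites evolved under a GTR model with
heterogeneous per-marker rate multipliers; per-(taxon, marker) dropout giving
30-80% occupancy; and a taxonomy of labelled monophyletic groups carved from
the species tree's clades. Gene trees are either the species tree itself with
branch lengths scaled by the marker's rate multiplier (congruent mode) or
NNI-perturbed variants of it (discordant mode) — discordance is modelled
topologically, not by coalescent simulation, which is sufficient to exercise
the concordance bookkeeping.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .errors import DegenerateInputError, PhylomosaicError
from .seqio import UNGROUPED, TaxonomyMap
from .supermatrix import Alignment
from .treekit import leaf_labels

#: Transition/transversion-biased exchangeabilities (AC, AG, AT, CG, CT, GT)
#: and mildly AT-rich base frequencies — generic insect-like nuclear values.
DEFAULT_GTR_EXCHANGEABILITIES = (1.0, 4.0, 1.0, 1.0, 4.0, 1.0)
DEFAULT_BASE_FREQUENCIES = (0.3, 0.2, 0.2, 0.3)

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study-shaped defaults: 40 taxa in 8 groups, 12 markers spanning
    300-2,000 sites with rate multipliers spread over ~0.25-4x, and 35%
    per-marker taxon dropout (~65% occupancy)."""

    n_taxa: int = 40
    birth_rate: float = 1.0
    markers: list[tuple[str, int, float]] = field(
        default_factory=lambda: [
            (f"m{i + 1:02d}", length, mult)
            for i, (length, mult) in enumerate(
                zip(
                    [300, 450, 600, 750, 900, 1050, 1200, 1350, 1500, 1650, 1800, 2000],
                    [0.25, 0.4, 0.6, 0.8, 1.0, 1.2, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0],
                )
            )
        ]
    )
    gtr_exchangeabilities: tuple = DEFAULT_GTR_EXCHANGEABILITIES
    base_frequencies: tuple = DEFAULT_BASE_FREQUENCIES
    dropout: float = 0.35
    n_groups: int = 8
    nni_perturbations: int = 0  # 0 = congruent mode
    tree_height: float = 0.5  # root-to-tip substitutions/site at multiplier 1
    group_size_range: tuple[int, int] = (2, 8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise DegenerateInputError("need at least 4 taxa")
        if any(length < 1 for _, length, _ in self.markers):
            raise PhylomosaicError("marker lengths must be >= 1")
        if abs(sum(self.base_frequencies) - 1.0) > 1e-9:
            raise PhylomosaicError("base frequencies must sum to 1")
        if not 0.0 <= self.dropout < 1.0:
            raise PhylomosaicError("dropout must be in [0, 1)")


def simulate_yule_tree(
    n_taxa: int, birth_rate: float = 1.0, seed: int = 0
) -> dendropy.Tree:
    """Pure-birth tree with exponential waiting times, leaves t01..tNN.

    The tree is ultrametric: after the n-th leaf appears, all pending branches
    are extended by one further Exp(n * birth_rate) waiting time.
    """
    if n_taxa < 2:
        raise DegenerateInputError("a Yule tree needs >= 2 leaves")
    rng = np.random.default_rng(seed)
    width = len(str(n_taxa))
    labels = [f"t{i + 1:0{width}d}" for i in range(n_taxa)]
    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node

    # active lineages: (pending node, birth time of its branch)
    active = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    now = 0.0
    while len(active) < n_taxa:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        k = int(rng.integers(len(active)))
        node, born = active.pop(k)
        node.edge.length = now - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, now))
    now += rng.exponential(1.0 / (birth_rate * len(active)))
    order = rng.permutation(len(labels))
    for (node, born), lab in zip(active, (labels[i] for i in order)):
        node.edge.length = now - born
        node.taxon = tns.get_taxon(lab)
    tree.is_rooted = True
    return tree


def build_gtr_rate_matrix(
    exchangeabilities: Sequence[float], base_frequencies: Sequence[float]
) -> np.ndarray:
    """GTR rate matrix Q (rows A,C,G,T), scaled to one expected substitution
    per unit branch length at stationarity."""
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(base_frequencies, dtype=float)
    if s.shape != (6,) or (s < 0).any():
        raise PhylomosaicError("need 6 nonnegative exchangeabilities")
    if pi.shape != (4,) or (pi <= 0).any() or abs(pi.sum() - 1.0) > 1e-9:
        raise PhylomosaicError("need 4 positive base frequencies summing to 1")
    Q = np.zeros((4, 4))
    pairs = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for rate, (i, j) in zip(s, pairs):
        Q[i, j] = rate * pi[j]
        Q[j, i] = rate * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    if mu <= 0:
        raise PhylomosaicError("degenerate rate matrix")
    return Q / mu


def simulate_alignment_gtr(
    tree: dendropy.Tree,
    length: int,
    exchangeabilities: Sequence[float] = DEFAULT_GTR_EXCHANGEABILITIES,
    base_frequencies: Sequence[float] = DEFAULT_BASE_FREQUENCIES,
    rate_multiplier: float = 1.0,
    seed: int = 0,
    marker: str = "sim",
) -> Alignment:
    """Evolve independent sites down a tree under GTR.

    Root states are drawn from the stationary base frequencies; each branch
    applies P(t) = expm(Q * t * rate_multiplier). A multiplier of 0 copies the
    root draw to every leaf.
    """
    pi = np.asarray(base_frequencies, dtype=float)
    Q = build_gtr_rate_matrix(exchangeabilities, pi)
    rng = np.random.default_rng(seed)
    pmat_cache: dict[float, np.ndarray] = {}

    def pmat(t: float) -> np.ndarray:
        if t not in pmat_cache:
            P = expm(Q * t * rate_multiplier)
            P = np.clip(P, 0.0, None)
            pmat_cache[t] = P / P.sum(axis=1, keepdims=True)
        return pmat_cache[t]

    states: dict[dendropy.Node, np.ndarray] = {}
    rows: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = rng.choice(4, size=length, p=pi)
        else:
            t = node.edge.length
            if t is None:
                raise PhylomosaicError("tree has absent branch lengths")
            parent_states = states[node.parent_node]
            P = pmat(float(t))
            child = np.empty(length, dtype=np.int64)
            for s in range(4):
                mask = parent_states == s
                n = int(mask.sum())
                if n:
                    child[mask] = rng.choice(4, size=n, p=P[s])
            states[node] = child
        if node.is_leaf():
            rows[node.taxon.label] = "".join(_BASES[states[node]])
    return Alignment(marker, rows)


def apply_missing_mask(
    alignments: Sequence[Alignment], dropout: float, seed: int = 0
) -> list[Alignment]:
    """Remove each (taxon, marker) row independently with probability
    *dropout*; a taxon's mask is resampled if it would lose every marker."""
    if not 0.0 <= dropout < 1.0:
        raise PhylomosaicError("dropout must be in [0, 1)")
    if dropout == 0.0:
        return list(alignments)
    rng = np.random.default_rng(seed)
    taxa = sorted({t for aln in alignments for t in aln.rows})
    k = len(alignments)
    mask = np.zeros((len(taxa), k), dtype=bool)
    for i, _ in enumerate(taxa):
        while True:
            row = rng.random(k) < dropout
            if not row.all():
                mask[i] = row
                break
    drop = {
        (taxa[i], alignments[j].marker)
        for i in range(len(taxa))
        for j in range(k)
        if mask[i, j]
    }
    out = []
    for aln in alignments:
        rows = {
            t: s for t, s in aln.rows.items() if (t, aln.marker) not in drop
        }
        if rows:
            out.append(Alignment(aln.marker, rows))
    return out


def nni_perturb(tree: dendropy.Tree, n_moves: int, seed: int = 0) -> dendropy.Tree:
    """Apply random nearest-neighbor-interchange moves to a clone of *tree*.

    Each move picks a random internal (non-seed, non-leaf-parented-only) edge
    and swaps one child of its lower node with one sibling subtree.
    """
    out = tree.clone(depth=1)
    rng = np.random.default_rng(seed)
    for _ in range(n_moves):
        internal = [
            nd
            for nd in out.preorder_node_iter()
            if nd.parent_node is not None
            and not nd.is_leaf()
            and nd.parent_node.parent_node is not None
        ]
        if not internal:
            break
        node = internal[int(rng.integers(len(internal)))]
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        sib = siblings[int(rng.integers(len(siblings)))]
        child = node.child_nodes()[int(rng.integers(len(node.child_nodes())))]
        parent.remove_child(sib)
        node.remove_child(child)
        parent.add_child(child)
        node.add_child(sib)
    return out


def scale_to_height(tree: dendropy.Tree, height: float) -> dendropy.Tree:
    """Clone with branch lengths rescaled so the maximum root-to-tip path
    equals *height* (expected substitutions per site at rate multiplier 1)."""
    depths = tree.calc_node_root_distances(return_leaf_distances_only=True)
    current = max(depths)
    if current <= 0:
        raise PhylomosaicError("tree has zero height")
    return _scaled_clone(tree, height / current)


def _scaled_clone(tree: dendropy.Tree, factor: float) -> dendropy.Tree:
    out = tree.clone(depth=1)
    for edge in out.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length * factor
    return out


def _carve_groups(
    tree: dendropy.Tree, n_groups: int, size_range: tuple[int, int] = (2, 8)
) -> dict[str, set[str]]:
    """Pick n_groups disjoint clades of the tree as composite groups.

    Smallest admissible clades are taken first, which maximizes how many
    disjoint groups fit on a given topology.
    """
    lo, hi = size_range
    candidates = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if lo <= len(leaves) <= hi:
            candidates.append(leaves)
    candidates.sort(key=lambda s: (len(s), sorted(s)))
    chosen: list[frozenset[str]] = []
    for cand in candidates:
        if all(cand.isdisjoint(c) for c in chosen):
            chosen.append(cand)
        if len(chosen) == n_groups:
            break
    if len(chosen) < n_groups:
        raise PhylomosaicError(
            f"tree supports only {len(chosen)} disjoint clades of size "
            f"{lo}-{hi}, {n_groups} groups requested"
        )
    return {f"G{i + 1:02d}": set(c) for i, c in enumerate(sorted(chosen, key=min))}


def make_dataset(
    config: SimulationConfig,
) -> tuple[dendropy.Tree, list[Alignment], TaxonomyMap, dict[str, dendropy.Tree]]:
    """Full synthetic study: species tree, per-marker alignments (masked),
    taxonomy of monophyletic groups, and per-marker gene trees.

    Gene trees carry branch lengths scaled by the marker's rate multiplier
    (what a per-marker estimate would see); in discordant mode they are
    additionally NNI-perturbed before sequence simulation.
    """
    rng = np.random.default_rng(config.seed)
    species_tree = simulate_yule_tree(
        config.n_taxa, config.birth_rate, seed=int(rng.integers(2**31))
    )
    species_tree = scale_to_height(species_tree, config.tree_height)
    gene_trees: dict[str, dendropy.Tree] = {}
    alignments: list[Alignment] = []
    for name, length, mult in config.markers:
        topo = species_tree
        if config.nni_perturbations > 0:
            topo = nni_perturb(
                species_tree, config.nni_perturbations, seed=int(rng.integers(2**31))
            )
        gene_tree = _scaled_clone(topo, mult)
        gene_trees[name] = gene_tree
        aln = simulate_alignment_gtr(
            topo,
            length,
            config.gtr_exchangeabilities,
            config.base_frequencies,
            rate_multiplier=mult,
            seed=int(rng.integers(2**31)),
            marker=name,
        )
        alignments.append(aln)
    alignments = apply_missing_mask(
        alignments, config.dropout, seed=int(rng.integers(2**31))
    )
    # restrict gene trees to the taxa that survived the mask for each marker
    masked_trees = {}
    for aln in alignments:
        gt = gene_trees[aln.marker]
        keep = set(aln.rows)
        if keep < leaf_labels(gt):
            from .treekit import prune_to_taxa

            gt = prune_to_taxa(gt, keep)
        masked_trees[aln.marker] = gt
    groups = _carve_groups(species_tree, config.n_groups, config.group_size_range)
    assignments = {t: g for g, members in groups.items() for t in members}
    for leaf in leaf_labels(species_tree):
        assignments.setdefault(leaf, UNGROUPED)
    taxonomy = TaxonomyMap(assignments)
    return species_tree, alignments, taxonomy, masked_trees
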