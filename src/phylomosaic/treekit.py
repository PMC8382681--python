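"""Core tree algebra on dendropy trees.

Trees are handled unrooted throughout: rooted inputs are interpreted as
unrooted for bipartition extraction and Robinson-Foulds comparison, so the
basal bifurcation introduced by rooting never creates a spurious split.

The neighbor-joining engine here is the desk-scale topology inference used by
the pipeline wherever a tree must be built from data. It deliberately replaces
heavyweight maximum-likelihood searches: with JC-corrected distances on long,
weakly divergent alignments it recovers the generating topology reliably, and
on exactly additive distance matrices it reproduces topology and branch
lengths exactly.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .errors import (
    DegenerateInputError,
    LengthMismatchError,
    MissingTaxonError,
    PhylomosaicError,
    SaturationError,
)
from .supermatrix import UNAMBIGUOUS, Alignment

#: Minimum shared unambiguous sites for a defined pairwise p-distance.
DEFAULT_MIN_OVERLAP = 30


def leaf_labels(tree: dendropy.Tree) -> frozenset[str]:
    return frozenset(leaf.taxon.label for leaf in tree.leaf_node_iter())


@dataclass(frozen=True)
class Bipartition:
    """A two-way split of the taxon set induced by one internal branch.

    ``side`` is canonical: of the two halves, the one containing the
    lexicographically smallest taxon of the universe (which makes that half
    the lexicographically smaller side, and canonicalization idempotent).
    """

    side: frozenset[str]
    universe: frozenset[str]

    @classmethod
    def from_side(cls, side, universe) -> "Bipartition":
        side, universe = frozenset(side), frozenset(universe)
        if not side or not side < universe:
            raise PhylomosaicError("bipartition side must be a non-empty proper subset")
        if min(universe) not in side:
            side = universe - side
        return cls(side, universe)

    @property
    def other_side(self) -> frozenset[str]:
        return self.universe - self.side

    def restricted(self, taxa) -> "Bipartition | None":
        """Restrict to a taxon subset; None when either side drops below 2."""
        taxa = frozenset(taxa)
        a = self.side & taxa
        b = self.other_side & taxa
        if len(a) < 2 or len(b) < 2:
            return None
        return Bipartition.from_side(a, a | b)


def bipartitions(tree: dendropy.Tree) -> set[Bipartition]:
    """Non-trivial bipartitions of the (unrooted) tree, one per internal branch.

    Trees with fewer than 4 leaves have none. A fully resolved unrooted tree
    of n leaves yields exactly n - 3.
    """
    universe = leaf_labels(tree)
    n = len(universe)
    if n < 4:
        return set()
    out: set[Bipartition] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 2 <= len(side) <= n - 2:
            out.add(Bipartition.from_side(side, universe))
    return out


def prune_to_taxa(tree: dendropy.Tree, keep) -> dendropy.Tree:
    """Restrict a tree to a leaf subset, suppressing the resulting degree-2
    nodes with their branch lengths summed. The input tree is not modified."""
    keep = set(keep)
    leaves = leaf_labels(tree)
    missing = keep - leaves
    if missing:
        raise MissingTaxonError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise DegenerateInputError("cannot prune a tree below 2 leaves")
    pruned = tree.clone(depth=1)
    pruned.retain_taxa_with_labels(keep)
    # dendropy may leave a unifurcate seed; collapse it into its child
    seed = pruned.seed_node
    while len(seed.child_nodes()) == 1:
        child = seed.child_nodes()[0]
        pruned.seed_node = child
        child.parent_node = None
        seed = child
    return pruned


def _leaf_index(tree: dendropy.Tree) -> dict[str, dendropy.Node]:
    return {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}


def patristic_distance(tree: dendropy.Tree, a: str, b: str) -> float:
    """Sum of branch lengths on the unique path between two leaves."""
    leaves = _leaf_index(tree)
    for t in (a, b):
        if t not in leaves:
            raise MissingTaxonError(f"taxon {t!r} not in tree")
    if a == b:
        return 0.0
    ancestors_a = {}
    dist = 0.0
    node = leaves[a]
    while node is not None:
        ancestors_a[node] = dist
        if node.edge.length is not None:
            dist += node.edge.length
        elif node.parent_node is not None:
            dist = float("nan")
        node = node.parent_node
    dist_b = 0.0
    node = leaves[b]
    while node is not None:
        if node in ancestors_a:
            total = ancestors_a[node] + dist_b
            if np.isnan(total):
                raise PhylomosaicError(
                    f"branch length absent on the path {a!r}..{b!r}"
                )
            return float(total)
        if node.edge.length is not None:
            dist_b += node.edge.length
        elif node.parent_node is not None:
            dist_b = float("nan")
        node = node.parent_node
    raise PhylomosaicError("leaves do not share an ancestor (disconnected tree?)")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with NaN marking undefined pairs."""

    taxa: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.taxa)
        if self.values.shape != (n, n):
            raise PhylomosaicError(
                f"distance matrix shape {self.values.shape} != ({n}, {n})"
            )
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise PhylomosaicError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise PhylomosaicError("distance matrix diagonal not zero")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values) < -1e-12:
                raise PhylomosaicError("negative distances")
        self._index = {t: i for i, t in enumerate(self.taxa)}

    def get(self, a: str, b: str) -> float | None:
        v = self.values[self._index[a], self._index[b]]
        return None if np.isnan(v) else float(v)

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    def subset(self, taxa) -> "DistanceMatrix":
        idx = [self._index[t] for t in taxa]
        return DistanceMatrix(list(taxa), self.values[np.ix_(idx, idx)])

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("\t" + "\t".join(self.taxa) + "\n")
            for t, row in zip(self.taxa, self.values):
                cells = ["NA" if np.isnan(v) else f"{v:.10g}" for v in row]
                fh.write(t + "\t" + "\t".join(cells) + "\n")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        lines = Path(path).read_text().splitlines()
        taxa = lines[0].split("\t")[1:]
        rows = []
        for line in lines[1:]:
            cells = line.split("\t")[1:]
            rows.append([np.nan if c == "NA" else float(c) for c in cells])
        return cls(taxa, np.array(rows))


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs patristic distances via one postorder accumulation."""
    taxa = sorted(leaf_labels(tree))
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    D = np.zeros((n, n))
    below: dict[dendropy.Node, list[tuple[int, float]]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = [(index[node.taxon.label], 0.0)]
            continue
        groups = []
        for child in node.child_nodes():
            ln = child.edge.length
            if ln is None:
                raise PhylomosaicError(
                    "branch length absent; patristic distances undefined"
                )
            groups.append([(i, d + ln) for i, d in below.pop(child)])
        for g1, g2 in itertools.combinations(groups, 2):
            for i, di in g1:
                for j, dj in g2:
                    D[i, j] = D[j, i] = di + dj
        below[node] = [pair for g in groups for pair in g]
    return DistanceMatrix(taxa, D)


def robinson_foulds(
    t1: dendropy.Tree, t2: dendropy.Tree
) -> tuple[int, float]:
    """Symmetric-difference (Robinson-Foulds) distance between two trees on
    the same leaf set, plus its normalization by 2(n-3)."""
    l1, l2 = leaf_labels(t1), leaf_labels(t2)
    if l1 != l2:
        raise MissingTaxonError(
            f"leaf sets differ: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    rf = len(bipartitions(t1) ^ bipartitions(t2))
    n = len(l1)
    norm = rf / (2 * (n - 3)) if n > 3 else 0.0
    return rf, norm


def p_distance(
    a: str, b: str, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float | None:
    """Proportion of mismatches over shared unambiguous sites.

    Only positions where both residues are in {A,C,G,T} are compared
    (pairwise deletion); returns None when fewer than *min_overlap* such
    positions exist.
    """
    if len(a) != len(b):
        raise LengthMismatchError(f"sequence lengths differ: {len(a)} vs {len(b)}")
    shared = 0
    mismatch = 0
    for x, y in zip(a, b):
        if x in UNAMBIGUOUS and y in UNAMBIGUOUS:
            shared += 1
            if x != y:
                mismatch += 1
    if shared < max(min_overlap, 1):
        return None
    return mismatch / shared


def jc_correct(p: float) -> float:
    """Jukes-Cantor distance from a p-distance: -(3/4) ln(1 - 4p/3)."""
    if p < 0:
        raise ValueError(f"p-distance cannot be negative: {p}")
    if p >= 0.75:
        raise SaturationError(
            f"p = {p} >= 0.75: Jukes-Cantor distance undefined (saturated pair)"
        )
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def distance_matrix(
    aln: Alignment,
    correction: str = "none",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> DistanceMatrix:
    """All-pairs p-distances (optionally JC-corrected) for an alignment.

    Pairs below the overlap floor, and JC-saturated pairs, are marked absent
    (the latter with a warning), never raised.
    """
    if correction not in ("none", "jc"):
        raise ValueError(f"correction must be 'none' or 'jc', got {correction!r}")
    taxa = aln.taxa
    if len(taxa) < 3:
        raise DegenerateInputError("distance matrix needs at least 3 taxa")
    n = len(taxa)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        p = p_distance(aln.rows[taxa[i]], aln.rows[taxa[j]], min_overlap)
        if p is None:
            v = np.nan
        elif correction == "jc":
            try:
                v = jc_correct(p)
            except SaturationError:
                warnings.warn(
                    f"saturated pair ({taxa[i]}, {taxa[j]}): p={p:.3f} >= 0.75; "
                    "distance marked absent"
                )
                v = np.nan
        else:
            v = p
        D[i, j] = D[j, i] = v
    return DistanceMatrix(taxa, D)


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor joining via the Q-criterion.

    Deterministic: ties in Q are broken by the lowest (row, column) index
    pair. Negative estimated branch lengths are clamped to zero. An additive
    input matrix is recovered exactly in topology and branch lengths.
    """
    if not dm.is_complete:
        raise PhylomosaicError(
            "distance matrix has absent entries; impute them or drop the "
            "affected taxa before neighbor joining"
        )
    if len(dm.taxa) < 3:
        raise DegenerateInputError("neighbor joining needs at least 3 taxa")

    tns = dendropy.TaxonNamespace(list(dm.taxa))
    nodes = [dendropy.Node(taxon=tns.get_taxon(t)) for t in dm.taxa]
    D = dm.values.astype(float).copy()

    while len(nodes) > 3:
        r = len(nodes)
        rowsum = D.sum(axis=1)
        Q = (r - 2) * D - rowsum[:, None] - rowsum[None, :]
        Q[np.tril_indices(r)] = np.inf  # keep i < j; row-major argmin = lowest pair
        i, j = np.unravel_index(np.argmin(Q), Q.shape)
        li = 0.5 * D[i, j] + (rowsum[i] - rowsum[j]) / (2 * (r - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        D[i, :] = dnew
        D[:, i] = dnew
        D[i, i] = 0.0
        keep = [k for k in range(r) if k != j]
        D = D[np.ix_(keep, keep)]
        nodes[i] = parent
        del nodes[j]

    # final trifurcation: three-point formula
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2,
        (d01 + d12 - d02) / 2,
        (d02 + d12 - d01) / 2,
    ]
    tree = dendropy.Tree(taxon_namespace=tns)
    for node, ln in zip(nodes, lengths):
        node.edge.length = max(ln, 0.0)
        tree.seed_node.add_child(node)
    tree.is_rooted = False
    return tree


def nj_from_alignment(
    aln: Alignment,
    correction: str = "jc",
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> dendropy.Tree:
    """Distance-based tree from an alignment: p-distances, optional JC
    correction, then NJ. Taxa involved in absent pairs are removed greedily
    (fewest defined pairs first) until the matrix is complete."""
    dm = distance_matrix(aln, correction=correction, min_overlap=min_overlap)
    while not dm.is_complete:
        defined = (~np.isnan(dm.values)).sum(axis=1)
        worst = int(np.argmin(defined))
        keep = [t for k, t in enumerate(dm.taxa) if k != worst]
        warnings.warn(
            f"dropping taxon {dm.taxa[worst]!r}: too little overlap for "
            "complete pairwise distances"
        )
        if len(keep) < 3:
            raise DegenerateInputError(
                "fewer than 3 taxa with complete pairwise distances"
            )
        dm = dm.subset(keep)
    return neighbor_joining(dm)
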