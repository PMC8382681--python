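"""Gene- and site-concordance accounting against a reference tree.

Every internal branch (bipartition) of a resolved reference tree can be
interrogated against each gene tree: after restricting the branch's two sides
to the taxa the gene tree actually samples, the branch is

* MISSING for that gene when either restricted side keeps fewer than 2 taxa
  (the gene cannot assess the branch at all),
* CONCORDANT when the restricted bipartition occurs in the gene tree,
* DISCORDANT otherwise (an unresolved restricted split counts as discordant,
  not missing: the gene could assess the branch but does not support it).

Per-marker concordance is the percentage of concordant branches among the
assessable ones. The gene concordance factor (gCF) inverts the bookkeeping:
per branch, the percentage of gene trees (among those assessing it) that
contain it. The site concordance factor (sCF) asks the alignment directly:
for quartets sampled around a branch, the mean fraction of decisive sites
whose pattern supports the branch's quartet arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np

from .errors import DegenerateInputError, MissingTaxonError, PhylomosaicError
from .supermatrix import Supermatrix
from .treekit import Bipartition, bipartitions, leaf_labels

_ACGT = np.array(list("ACGT"))


@dataclass
class MarkerConcordance:
    """One marker's node bookkeeping against the reference tree."""

    marker: str
    n_concordant: int
    n_discordant: int
    n_missing: int
    n_total: int
    percentage: Optional[float]  # over assessable nodes; None if none assessable

    def __post_init__(self) -> None:
        if self.n_concordant + self.n_discordant + self.n_missing != self.n_total:
            raise PhylomosaicError("concordance counts do not sum to the total")


@dataclass
class NodeConcordance:
    """Per-reference-branch concordance factors."""

    bipartition: Bipartition
    gcf: Optional[float] = None
    n_decisive: int = 0  # gene trees able to assess this branch
    scf: Optional[float] = None
    n_quartets: int = 0  # sampled quartets with at least one decisive site


def concordance_percentage(
    n_concordant: int, n_total: int, n_missing: int
) -> Optional[float]:
    """Concordant branches as a percentage of assessable ones:
    100 * concordant / (total - missing); None when nothing is assessable."""
    assessable = n_total - n_missing
    if assessable <= 0:
        return None
    return 100.0 * n_concordant / assessable


def marker_concordance(
    gene_tree: dendropy.Tree,
    reference: dendropy.Tree,
    marker: str | None = None,
) -> MarkerConcordance:
    """Classify every reference branch as concordant/discordant/missing for
    one gene tree whose taxa are a subset of the reference's."""
    ref_taxa = leaf_labels(reference)
    gene_taxa = leaf_labels(gene_tree)
    extra = gene_taxa - ref_taxa
    if extra:
        raise MissingTaxonError(
            f"gene-tree taxa absent from reference: {sorted(extra)}"
        )
    ref_bips = bipartitions(reference)
    n_total = len(ref_bips)
    name = marker if marker is not None else (gene_tree.label or "gene")
    if len(gene_taxa) < 4:
        return MarkerConcordance(name, 0, 0, n_total, n_total, None)
    gene_bips = bipartitions(gene_tree)
    n_conc = n_disc = n_miss = 0
    for bip in ref_bips:
        restricted = bip.restricted(gene_taxa)
        if restricted is None:
            n_miss += 1
        elif restricted in gene_bips:
            n_conc += 1
        else:
            n_disc += 1
    return MarkerConcordance(
        name, n_conc, n_disc, n_miss, n_total,
        concordance_percentage(n_conc, n_total, n_miss),
    )


def node_concordance_factors(
    reference: dendropy.Tree,
    gene_trees: Sequence[dendropy.Tree],
) -> list[NodeConcordance]:
    """gCF per reference branch over a collection of gene trees.

    gCF = 100 * (gene trees containing the restricted branch) /
    (gene trees able to assess it); absent when no gene tree can assess it.
    Output is ordered by canonical bipartition side for reproducibility.
    """
    if not gene_trees:
        raise DegenerateInputError("need at least one gene tree")
    ref_bips = sorted(bipartitions(reference), key=lambda b: sorted(b.side))
    gene_info = []
    for gt in gene_trees:
        taxa = leaf_labels(gt)
        gene_info.append((taxa, bipartitions(gt) if len(taxa) >= 4 else set()))
    out = []
    for bip in ref_bips:
        assessable = concordant = 0
        for taxa, gbips in gene_info:
            restricted = bip.restricted(taxa)
            if restricted is None:
                continue
            assessable += 1
            if restricted in gbips:
                concordant += 1
        out.append(
            NodeConcordance(
                bipartition=bip,
                gcf=100.0 * concordant / assessable if assessable else None,
                n_decisive=assessable,
            )
        )
    return out


def _quartet_blocks(tree: dendropy.Tree) -> dict[Bipartition, tuple]:
    """For each internal branch, the four leaf blocks around it.

    Removing an internal branch and the two nodes it joins splits the leaves
    into four blocks (A,B) below and (C,D) above; quartets for sCF draw one
    taxon from each. Branches whose local node is a polytomy are skipped.
    """
    universe = leaf_labels(tree)
    seed = tree.seed_node
    # collapse a basal bifurcation so the "up" side always splits in two
    if len(seed.child_nodes()) == 2:
        tree = tree.clone(depth=1)
        seed = tree.seed_node
        c1, c2 = seed.child_nodes()
        donor = c2 if not c2.is_leaf() else c1
        keeper = c1 if donor is c2 else c2
        if not donor.is_leaf():
            keeper.edge.length = (keeper.edge.length or 0.0) + (donor.edge.length or 0.0)
            for child in list(donor.child_nodes()):
                donor.remove_child(child)
                seed.add_child(child)
            seed.remove_child(donor)
    blocks: dict[Bipartition, tuple] = {}
    for node in tree.preorder_node_iter():
        if node is seed or node.is_leaf():
            continue
        kids = node.child_nodes()
        if len(kids) != 2:
            continue
        A = frozenset(l.taxon.label for l in kids[0].leaf_iter())
        B = frozenset(l.taxon.label for l in kids[1].leaf_iter())
        side = A | B
        if len(side) > len(universe) - 2 or len(side) < 2:
            continue
        parent = node.parent_node
        others = [c for c in parent.child_nodes() if c is not node]
        C = frozenset(l.taxon.label for l in others[0].leaf_iter())
        D = universe - side - C
        if not C or not D:
            continue
        bip = Bipartition.from_side(side, universe)
        blocks[bip] = (sorted(A), sorted(B), sorted(C), sorted(D))
    return blocks


def site_concordance_factors(
    reference: dendropy.Tree,
    matrix: Supermatrix,
    n_quartets: int = 100,
    seed: int = 0,
) -> list[NodeConcordance]:
    """sCF per reference branch from quartet-sampled site patterns.

    Per branch, *n_quartets* quartets (a,b,c,d) are drawn uniformly (with the
    given seed) from the four blocks around the branch. A site is decisive for
    a quartet iff all four residues are unambiguous and show exactly two
    states, twice each; a decisive site supports the branch iff the two states
    pair a with b and c with d. sCF is the mean over quartets (with >= 1
    decisive site) of the fraction of decisive sites supporting the branch.
    """
    if n_quartets < 1:
        raise ValueError("n_quartets must be >= 1")
    missing_taxa = leaf_labels(reference) - set(matrix.taxa)
    if missing_taxa:
        raise MissingTaxonError(
            f"reference taxa absent from matrix: {sorted(missing_taxa)}"
        )
    rng = np.random.default_rng(seed)
    chars = {t: np.frombuffer(s.encode(), dtype="S1") for t, s in matrix.rows.items()}
    acgt = _ACGT.astype("S1")
    valid = {t: np.isin(s, acgt) for t, s in chars.items()}
    blocks = _quartet_blocks(reference)
    out = []
    for bip in sorted(bipartitions(reference), key=lambda b: sorted(b.side)):
        nc = NodeConcordance(bipartition=bip)
        if bip in blocks:
            A, B, C, D = blocks[bip]
            fractions = []
            for _ in range(n_quartets):
                a = A[rng.integers(len(A))]
                b = B[rng.integers(len(B))]
                c = C[rng.integers(len(C))]
                d = D[rng.integers(len(D))]
                sa, sb, sc, sd = chars[a], chars[b], chars[c], chars[d]
                ok = valid[a] & valid[b] & valid[c] & valid[d]
                # decisive: exactly two states, twice each
                ab = sa == sb
                cd = sc == sd
                ac = sa == sc
                ad = sa == sd
                bc = sb == sc
                bd = sb == sd
                support = ok & ab & cd & ~ac
                pat_acbd = ok & ac & bd & ~ab
                pat_adbc = ok & ad & bc & ~ab & ~ac
                decisive = support | pat_acbd | pat_adbc
                n_dec = int(decisive.sum())
                if n_dec:
                    fractions.append(support.sum() / n_dec)
            if fractions:
                nc.scf = 100.0 * float(np.mean(fractions))
                nc.n_quartets = len(fractions)
        out.append(nc)
    return out


def concordance_summary(
    rows: Sequence[MarkerConcordance], subset: Sequence[str] | None = None
) -> tuple[float, float, float]:
    """Arithmetic mean, minimum and maximum concordance percentage over a
    marker subset (all rows by default)."""
    wanted = set(subset) if subset is not None else {r.marker for r in rows}
    picked = [r for r in rows if r.marker in wanted]
    if subset is not None and len(picked) != len(set(subset)):
        missing = set(subset) - {r.marker for r in picked}
        raise PhylomosaicError(f"markers not in rows: {sorted(missing)}")
    if not picked:
        raise DegenerateInputError("empty marker subset")
    pcts = [r.percentage for r in picked]
    if any(p is None for p in pcts):
        raise DegenerateInputError("subset contains markers with undefined percentage")
    return float(np.mean(pcts)), float(min(pcts)), float(max(pcts))
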