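"""Composite-taxon construction for sparse supermatrices.

A composite taxon replaces a monophyletic group of species with a single
terminal assembled per marker from the group's least-diverging available
sequence. Because selection is independent per marker, one composite row may
chimerically combine different source species across markers — that is the
point: it raises occupancy (fewer all-missing segments) while biasing toward
slow-evolving sequences, which shortens branches and stabilizes inference on
sparse matrices. Provenance of every chosen segment is kept in a
:class:`CompositeSpec` sidecar.

"Least diverging" is operationalized as the group member with minimal mean
patristic distance to all other leaves of the marker's gene tree; when no gene
tree is available the fallback is minimal mean defined p-distance to the other
rows of the marker alignment. Ties break lexicographically by taxon name.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np

from .errors import MonophylyError, PhylomosaicError
from .seqio import UNGROUPED, TaxonomyMap
from .supermatrix import Alignment, Supermatrix, concatenate
from .treekit import bipartitions, leaf_labels, p_distance, patristic_matrix


@dataclass
class CompositeSpec:
    """Provenance for one composite taxon: which source sequence was chosen
    for each marker, and the divergence score that won the selection."""

    group: str
    selections: dict[str, str] = field(default_factory=dict)  # marker -> taxon
    scores: dict[str, float] = field(default_factory=dict)  # marker -> criterion


def check_group_monophyly(
    tree: dendropy.Tree, taxonomy: TaxonomyMap
) -> dict[str, bool]:
    """Monophyly verdict per group on an unrooted tree.

    A group with >= 2 members present is monophyletic iff its member set
    equals one side of some bipartition; singletons are trivially
    monophyletic. Groups with no member in the tree are omitted.
    """
    tree_taxa = leaf_labels(tree)
    # taxa absent from the taxonomy are simply ungrouped; no error
    sides = set()
    for bip in bipartitions(tree):
        sides.add(bip.side)
        sides.add(bip.other_side)
    verdicts: dict[str, bool] = {}
    for group, members in taxonomy.groups().items():
        present = frozenset(members & tree_taxa)
        if not present:
            continue
        if len(present) == 1 or present == tree_taxa:
            verdicts[group] = True
        else:
            verdicts[group] = present in sides
    return verdicts


def select_representative(
    group_taxa: set[str],
    marker: Alignment,
    gene_tree: Optional[dendropy.Tree] = None,
) -> Optional[tuple[str, float]]:
    """Pick the least-diverging group member with data for this marker.

    Returns ``(taxon, score)`` or None when no member has data. The score is
    the mean patristic distance to all other gene-tree leaves (tree route) or
    the mean defined p-distance to all other marker rows (alignment route).
    """
    candidates = sorted(t for t in group_taxa if t in marker.rows)
    if gene_tree is not None:
        tree_taxa = leaf_labels(gene_tree)
        candidates = [t for t in candidates if t in tree_taxa]
    if not candidates:
        return None
    if len(candidates) == 1:
        return candidates[0], 0.0

    scores: dict[str, float] = {}
    if gene_tree is not None:
        pm = patristic_matrix(gene_tree)
        others = [t for t in pm.taxa]
        for cand in candidates:
            ds = [pm.get(cand, o) for o in others if o != cand]
            scores[cand] = float(np.mean(ds)) if ds else 0.0
    else:
        for cand in candidates:
            ds = [
                d
                for other in marker.rows
                if other != cand
                for d in [p_distance(marker.rows[cand], marker.rows[other], 1)]
                if d is not None
            ]
            scores[cand] = float(np.mean(ds)) if ds else float("inf")
    best = min(candidates, key=lambda t: (scores[t], t))
    return best, scores[best]


def build_composite_matrix(
    alignments: Sequence[Alignment],
    taxonomy: TaxonomyMap,
    reference: dendropy.Tree,
    gene_trees: Optional[dict[str, dendropy.Tree]] = None,
    allow_non_monophyletic: bool = False,
) -> tuple[Supermatrix, list[CompositeSpec]]:
    """Build the reduced matrix: one row per composite group plus one row per
    ungrouped taxon.

    Groups flagged non-monophyletic on the reference tree are a hard error
    unless *allow_non_monophyletic* is set. Groups with no data in any marker
    are dropped. Ungrouped taxa keep their own sequences untouched.
    """
    gene_trees = gene_trees or {}
    groups = taxonomy.groups()
    all_taxa = {t for aln in alignments for t in aln.rows}
    collisions = set(groups) & all_taxa
    if collisions:
        raise PhylomosaicError(
            f"group names collide with taxon names: {sorted(collisions)}"
        )
    verdicts = check_group_monophyly(reference, taxonomy)
    bad = sorted(g for g, ok in verdicts.items() if not ok)
    if bad and not allow_non_monophyletic:
        raise MonophylyError(
            f"groups not monophyletic on the reference tree: {bad}; composite "
            "construction requires unambiguous monophyletic units "
            "(pass allow_non_monophyletic=True to override)"
        )

    specs: list[CompositeSpec] = []
    for group in sorted(groups):
        spec = CompositeSpec(group)
        for aln in alignments:
            choice = select_representative(
                groups[group], aln, gene_trees.get(aln.marker)
            )
            if choice is None:
                continue
            taxon, score = choice
            spec.selections[aln.marker] = taxon
            spec.scores[aln.marker] = score
        if spec.selections:
            specs.append(spec)

    grouped_taxa = {t for members in groups.values() for t in members}
    per_marker: list[Alignment] = []
    for aln in alignments:
        rows: dict[str, str] = {}
        for spec in specs:
            if aln.marker in spec.selections:
                rows[spec.group] = aln.rows[spec.selections[aln.marker]]
        for taxon, seq in aln.rows.items():
            if taxon not in grouped_taxa:
                rows[taxon] = seq
        if rows:
            per_marker.append(Alignment(aln.marker, rows))
    matrix = concatenate(per_marker)
    return matrix, specs


def write_provenance_tsv(specs: Sequence[CompositeSpec], path) -> None:
    """Sidecar TSV: group, marker, chosen source taxon, criterion value."""
    with open(path, "w") as fh:
        fh.write("group\tmarker\tsource_taxon\tcriterion\n")
        for spec in specs:
            for marker, taxon in spec.selections.items():
                fh.write(
                    f"{spec.group}\t{marker}\t{taxon}\t{spec.scores[marker]:.6g}\n"
                )
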