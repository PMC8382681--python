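"""Contamination and misplacement screening.

Two screens mirror the manual curation step of multilocus dataset assembly:

* near-identical sequences shared by taxonomically distant taxa (the classic
  signature of cross-contamination or index hopping) — flagged when the
  pairwise p-distance falls below a small threshold and the two taxa belong
  to different groups;
* taxa whose placement in a gene tree breaks an otherwise monophyletic group
  — flagged when the group (with >= 3 members in the tree) is monophyletic
  with the taxon excluded but not with it included.

Both screens only *flag*; nothing is deleted automatically, mirroring the
careful-manual-examination workflow they emulate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

from .seqio import UNGROUPED, TaxonomyMap
from .supermatrix import Alignment
from .treekit import leaf_labels, p_distance, patristic_matrix, prune_to_taxa
from .composite import check_group_monophyly

#: Default p-distance below which cross-group pairs are suspicious.
DEFAULT_NEAR_IDENTICAL_THRESHOLD = 0.005


@dataclass(frozen=True)
class QCFlag:
    """One suspicious sequence or sequence pair."""

    marker: str
    taxa: tuple[str, ...]
    kind: str  # "near_identical_cross_group" | "misplaced"
    evidence: float  # p-distance of the pair, or displacement distance

    def __post_init__(self) -> None:
        if self.evidence < 0:
            raise ValueError("evidence must be nonnegative")


def flag_near_identical_cross_group(
    aln: Alignment,
    taxonomy: TaxonomyMap,
    threshold: float = DEFAULT_NEAR_IDENTICAL_THRESHOLD,
    min_overlap: int = 30,
) -> list[QCFlag]:
    """Flag cross-group taxon pairs with p-distance below *threshold*.

    Same-group pairs are never flagged (close relatives are expected to be
    similar); ungrouped taxa count as mutually unrelated.
    """
    if not 0.0 < threshold <= 0.1:
        raise ValueError(f"threshold must be in (0, 0.1], got {threshold}")
    flags = []
    for a, b in itertools.combinations(aln.taxa, 2):
        ga, gb = taxonomy.group_of(a), taxonomy.group_of(b)
        if ga == gb and ga != UNGROUPED:
            continue
        d = p_distance(aln.rows[a], aln.rows[b], min_overlap)
        if d is not None and d < threshold:
            flags.append(
                QCFlag(aln.marker, tuple(sorted((a, b))), "near_identical_cross_group", d)
            )
    return flags


def flag_misplaced_taxa(
    gene_tree: dendropy.Tree,
    taxonomy: TaxonomyMap,
    marker: str = "",
) -> list[QCFlag]:
    """Flag taxa whose exclusion restores their group's monophyly.

    Only groups with >= 3 members present in the tree are tested: with two
    members any one exclusion leaves a trivially monophyletic singleton, so
    the test would be vacuous. Evidence is the taxon's mean patristic distance
    to its own group members when branch lengths are available, else 0.
    """
    tree_taxa = leaf_labels(gene_tree)
    verdicts = check_group_monophyly(gene_tree, taxonomy)
    try:
        pm = patristic_matrix(gene_tree)
    except Exception:
        pm = None
    flags = []
    for group, members in sorted(taxonomy.groups().items()):
        present = sorted(members & tree_taxa)
        if len(present) < 3 or verdicts.get(group, True):
            continue
        for taxon in present:
            rest_tree = prune_to_taxa(gene_tree, tree_taxa - {taxon})
            rest_members = set(present) - {taxon}
            sub_taxonomy = TaxonomyMap({t: group for t in rest_members})
            if check_group_monophyly(rest_tree, sub_taxonomy).get(group, False):
                if pm is not None:
                    evidence = float(
                        np.mean([pm.get(taxon, o) for o in rest_members])
                    )
                else:
                    evidence = 0.0
                flags.append(QCFlag(marker, (taxon,), "misplaced", evidence))
    return flags


def write_flags_tsv(flags: Sequence[QCFlag], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\tkind\ttaxa\tevidence\n")
        for f in flags:
            fh.write(f"{f.marker}\t{f.kind}\t{','.join(f.taxa)}\t{f.evidence:.6g}\n")
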