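"""Leave-one-marker-out (marker jackknife) robustness scan.

Dropping each marker in turn and re-inferring the tree measures how much any
single locus drives the topology. The report per dropped marker is the
Robinson-Foulds distance to the full-matrix tree over the shared taxon set,
its normalization, and the list of leaves whose local neighborhood changed —
a quantitative proxy for the qualitative "which clades moved" reading of such
scans.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import dendropy

from .errors import DegenerateInputError, PhylomosaicError
from .supermatrix import Alignment, Supermatrix, concatenate
from .treekit import (
    bipartitions,
    leaf_labels,
    nj_from_alignment,
    prune_to_taxa,
    robinson_foulds,
)

logger = logging.getLogger(__name__)


@dataclass
class JackknifeResult:
    dropped_marker: str
    rf_to_full: Optional[int]
    normalized_rf: Optional[float]
    moved_taxa: list[str] = field(default_factory=list)
    error: Optional[str] = None


def drop_marker(matrix: Supermatrix, marker: str) -> Supermatrix:
    """Remove one marker's columns; taxa left with no defined sites at all
    are dropped with a warning."""
    if marker not in matrix.partitions:
        raise PhylomosaicError(f"no such marker: {marker!r}")
    if len(matrix.partitions) < 2:
        raise DegenerateInputError("cannot drop the last remaining marker")
    keep = [
        matrix.marker_alignment(m, drop_all_missing=True)
        for m in matrix.markers
        if m != marker
    ]
    reduced = concatenate(keep)
    empty = [
        t for t, row in reduced.rows.items() if set(row) <= {"-", "?"}
    ]
    if empty:
        warnings.warn(
            f"dropping marker {marker!r} leaves taxa without data, removed: {empty}"
        )
        reduced = Supermatrix(
            {t: r for t, r in reduced.rows.items() if t not in empty},
            reduced.partitions,
        )
    return reduced


def default_engine(matrix: Supermatrix) -> dendropy.Tree:
    """JC-corrected neighbor joining over the whole matrix."""
    aln = Alignment("supermatrix", dict(matrix.rows))
    return nj_from_alignment(aln, correction="jc")


def _leaf_contexts(tree: dendropy.Tree) -> dict[str, frozenset[str]]:
    """Per leaf, the smallest non-trivial bipartition side containing it —
    the leaf's nearest-neighbor context."""
    contexts: dict[str, frozenset[str]] = {}
    universe = leaf_labels(tree)
    for bip in bipartitions(tree):
        for side in (bip.side, bip.other_side):
            for taxon in side:
                if taxon not in contexts or len(side) < len(contexts[taxon]):
                    contexts[taxon] = side
    for taxon in universe:
        contexts.setdefault(taxon, universe - {taxon})
    return contexts


def moved_taxa(t1: dendropy.Tree, t2: dendropy.Tree) -> list[str]:
    """Leaves whose nearest-neighbor context differs between two trees on the
    same leaf set."""
    c1, c2 = _leaf_contexts(t1), _leaf_contexts(t2)
    return sorted(t for t in c1 if c1[t] != c2.get(t))


def jackknife_topology_scan(
    matrix: Supermatrix,
    engine: Callable[[Supermatrix], dendropy.Tree] = default_engine,
) -> list[JackknifeResult]:
    """Drop each marker in turn, re-infer, and compare to the full tree.

    Both trees are restricted to their shared taxa before comparison (a taxon
    can leave the analysis with its only marker). An engine failure on one
    reduced matrix is recorded in that row; the scan continues.
    """
    if len(matrix.partitions) < 2:
        raise DegenerateInputError("jackknife needs at least 2 markers")
    full_tree = engine(matrix)
    results = []
    for marker in matrix.markers:
        try:
            reduced = drop_marker(matrix, marker)
            tree = engine(reduced)
            shared = leaf_labels(full_tree) & leaf_labels(tree)
            if len(shared) < 4:
                raise DegenerateInputError("fewer than 4 shared taxa")
            a = prune_to_taxa(full_tree, shared)
            b = prune_to_taxa(tree, shared)
            rf, norm = robinson_foulds(a, b)
            results.append(
                JackknifeResult(marker, rf, norm, moved_taxa(a, b))
            )
        except Exception as exc:
            logger.warning("jackknife failed for marker %s: %s", marker, exc)
            results.append(JackknifeResult(marker, None, None, error=str(exc)))
    return results


def write_jackknife_tsv(results: Sequence[JackknifeResult], path) -> None:
    with open(path, "w") as fh:
        fh.write("marker\trf\tnormalized_rf\tn_moved_taxa\tmoved_taxa\terror\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.dropped_marker,
                        "NA" if r.rf_to_full is None else str(r.rf_to_full),
                        "NA" if r.normalized_rf is None else f"{r.normalized_rf:.4f}",
                        str(len(r.moved_taxa)),
                        ",".join(r.moved_taxa),
                        r.error or "",
                    ]
                )
                + "\n"
            )
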