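"""Readers and writers for every external format the pipeline touches.

FASTA parsing is delegated to Biopython, Newick to dendropy; this module adds
the strict validation the downstream analysis relies on (equal row lengths,
unique taxa, legal residue alphabet) and the two small bespoke formats: the
RAxML-dialect partition file and the per-marker statistics report.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import dendropy
from Bio import SeqIO

from .errors import (
    DuplicateTaxonError,
    ParseError,
    PhylomosaicError,
    TaxonomyConflictError,
)
from .supermatrix import Alignment, Supermatrix

#: Reserved group label for taxa not assigned to any composite group.
UNGROUPED = "UNGROUPED"


@dataclass
class TaxonomyMap:
    """Taxon -> group-label assignment driving composite construction.

    Taxa absent from the map are treated as ungrouped on lookup; the reserved
    sentinel :data:`UNGROUPED` is the label for them.
    """

    assignments: dict[str, str]

    def __post_init__(self) -> None:
        for taxon, group in self.assignments.items():
            if not taxon or not group:
                raise ParseError(f"empty taxon or group label: {taxon!r} -> {group!r}")

    def group_of(self, taxon: str) -> str:
        return self.assignments.get(taxon, UNGROUPED)

    def groups(self) -> dict[str, set[str]]:
        """Mapping of real group label -> member taxa (sentinel excluded)."""
        out: dict[str, set[str]] = {}
        for taxon, group in self.assignments.items():
            if group != UNGROUPED:
                out.setdefault(group, set()).add(taxon)
        return out


def read_fasta(path: str | Path, marker: str | None = None) -> Alignment:
    """Read one marker's aligned FASTA into an :class:`Alignment`.

    Residues are uppercased and ``U`` is mapped to ``T``. Record order is
    preserved. The marker name defaults to the file stem.
    """
    path = Path(path)
    rows: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in rows:
            raise DuplicateTaxonError(f"duplicate taxon {rec.id!r} in {path}")
        rows[rec.id] = str(rec.seq).upper().replace("U", "T")
    if not rows:
        raise ParseError(f"no FASTA records in {path}")
    return Alignment(marker or path.stem, rows)


def write_fasta(aln: Alignment | Supermatrix, path: str | Path, width: int = 80) -> None:
    """Write an alignment or supermatrix as wrapped multi-FASTA."""
    with open(path, "w") as fh:
        for taxon, seq in aln.rows.items():
            fh.write(f">{taxon}\n")
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i : i + width] + "\n")


def read_newick(text: str) -> dendropy.Tree:
    """Parse a Newick string into a dendropy tree.

    Branch lengths stay absent (``None``) when omitted; internal node labels
    are retained as opaque support annotations and never interpreted
    numerically here.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        if "Duplicate" in type(exc).__name__ or "Duplicate taxon" in str(exc):
            raise DuplicateTaxonError(f"duplicate leaf labels: {exc}") from exc
        raise ParseError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise DuplicateTaxonError(f"duplicate leaf labels: {dupes}")
    return tree


def read_newick_file(path: str | Path) -> dendropy.Tree:
    return read_newick(Path(path).read_text())


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to a single-line Newick string."""
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def write_newick_file(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column tab-separated taxon -> group file.

    A group field of ``-`` marks the taxon as explicitly ungrouped. A taxon
    listed twice with the same group is tolerated; with different groups it is
    a conflict.
    """
    assignments: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        taxon, group = parts[0].strip(), parts[1].strip()
        if group == "-":
            group = UNGROUPED
        if taxon in assignments and assignments[taxon] != group:
            raise TaxonomyConflictError(
                f"{path}:{lineno}: taxon {taxon!r} assigned to both "
                f"{assignments[taxon]!r} and {group!r}"
            )
        assignments[taxon] = group
    return TaxonomyMap(assignments)


_PARTITION_RE = re.compile(r"^DNA,\s*(\S+)\s*=\s*(\d+)-(\d+)\s*$")


def write_partition_file(matrix: Supermatrix, path: str | Path) -> None:
    """Write the partition table in the RAxML dialect.

    One line per marker, 1-based inclusive coordinates, matrix order:
    ``DNA, <name> = <start>-<end>``.
    """
    if not matrix.partitions:
        raise PhylomosaicError("empty partition table")
    with open(path, "w") as fh:
        for name, (start, end) in matrix.partitions.items():
            fh.write(f"DNA, {name} = {start + 1}-{end}\n")


def read_partition_file(path: str | Path) -> dict[str, tuple[int, int]]:
    """Parse a RAxML-dialect partition file back to 0-based half-open intervals."""
    partitions: dict[str, tuple[int, int]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip():
            continue
        m = _PARTITION_RE.match(line)
        if not m:
            raise ParseError(f"{path}:{lineno}: not a 'DNA, name = a-b' line")
        name, a, b = m.group(1), int(m.group(2)), int(m.group(3))
        if name in partitions:
            raise DuplicateTaxonError(f"{path}:{lineno}: duplicate partition {name!r}")
        partitions[name] = (a - 1, b)
    return partitions


@dataclass
class MarkerStats:
    """One row of the per-marker dataset-statistics report.

    Column roles follow the conventional multilocus summary table: occupancy
    (sequences present / total taxa), alignment length, percentage of
    parsimony-informative sites, mean inferred (patristic) and observed
    (p-) pairwise distances, the saturation slope, and the concordance
    bookkeeping against a reference tree (concordant / total internal nodes,
    missing nodes, concordance percentage over assessable nodes).
    """

    marker: str
    n_sequences: Optional[int] = None
    n_taxa_total: Optional[int] = None
    n_sites: Optional[int] = None
    informative_pct: Optional[float] = None
    mean_inferred: Optional[float] = None
    mean_observed: Optional[float] = None
    saturation: Optional[float] = None
    n_concordant: Optional[int] = None
    n_nodes_total: Optional[int] = None
    n_missing: Optional[int] = None
    concordance_pct: Optional[float] = None


REPORT_COLUMNS = [
    "marker",
    "sequences",
    "sites",
    "informative_pct",
    "inferred_distance",
    "observed_distance",
    "saturation",
    "concordant_nodes",
    "missing_nodes",
    "concordance_pct",
]


def _ratio(a: Optional[int], b: Optional[int]) -> str:
    if a is None:
        return "NA"
    return f"{a}/{b}" if b is not None else str(a)


def _num(x: Optional[float], nd: int) -> str:
    return "NA" if x is None else f"{x:.{nd}f}"


def write_report_tsv(stats: list[MarkerStats], path: str | Path) -> None:
    """Write the per-marker statistics report.

    Percentages carry one decimal, distances and slopes three.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for s in stats:
            fields = [
                s.marker,
                _ratio(s.n_sequences, s.n_taxa_total),
                "NA" if s.n_sites is None else str(s.n_sites),
                _num(s.informative_pct, 1),
                _num(s.mean_inferred, 3),
                _num(s.mean_observed, 3),
                _num(s.saturation, 3),
                _ratio(s.n_concordant, s.n_nodes_total),
                "NA" if s.n_missing is None else str(s.n_missing),
                _num(s.concordance_pct, 1),
            ]
            fh.write("\t".join(fields) + "\n")


def read_report_tsv(path: str | Path) -> list[MarkerStats]:
    """Parse a statistics report written by :func:`write_report_tsv`."""

    def _maybe_float(s: str) -> Optional[float]:
        return None if s == "NA" else float(s)

    def _maybe_ratio(s: str) -> tuple[Optional[int], Optional[int]]:
        if s == "NA":
            return None, None
        if "/" in s:
            a, b = s.split("/")
            return int(a), int(b)
        return int(s), None

    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t") != REPORT_COLUMNS:
        raise ParseError(f"{path}: missing or unexpected report header")
    out = []
    for line in lines[1:]:
        f = line.split("\t")
        if len(f) != len(REPORT_COLUMNS):
            raise ParseError(f"{path}: bad row {line!r}")
        nseq, ntot = _maybe_ratio(f[1])
        nconc, nnodes = _maybe_ratio(f[7])
        out.append(
            MarkerStats(
                marker=f[0],
                n_sequences=nseq,
                n_taxa_total=ntot,
                n_sites=None if f[2] == "NA" else int(f[2]),
                informative_pct=_maybe_float(f[3]),
                mean_inferred=_maybe_float(f[4]),
                mean_observed=_maybe_float(f[5]),
                saturation=_maybe_float(f[6]),
                n_concordant=nconc,
                n_nodes_total=nnodes,
                n_missing=None if f[8] == "NA" else int(f[8]),
                concordance_pct=_maybe_float(f[9]),
            )
        )
    return out
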