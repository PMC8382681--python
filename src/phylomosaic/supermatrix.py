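"""Multi-marker supermatrix assembly and column-level statistics.

The central objects are :class:`Alignment` (one marker, equal-length rows keyed
by taxon) and :class:`Supermatrix` (the concatenation of several markers over
the union of their taxa, with a partition table mapping each marker to its
column interval).

Character conventions
---------------------
``?``    the taxon was never sequenced for this marker (whole-segment missing)
``-``    an alignment gap inside a sequenced marker
A,C,G,T  unambiguous nucleotide states
IUPAC ambiguity codes (R, Y, N, ...) are carried through verbatim but are
treated like missing data in every distance and site-pattern computation:
only {A,C,G,T} ever count as states.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateInputError,
    DuplicateTaxonError,
    LengthMismatchError,
    ParseError,
    PhylomosaicError,
)

UNAMBIGUOUS = frozenset("ACGT")
MISSING = frozenset("-?")
AMBIGUITY = frozenset("RYSWKMBDHVN")
LEGAL = UNAMBIGUOUS | MISSING | AMBIGUITY


@dataclass
class Alignment:
    """One marker's aligned nucleotide rows, keyed by taxon.

    Rows are stored in insertion order; all rows must be equal length and
    contain only IUPAC nucleotide codes plus ``-`` and ``?``.
    """

    marker: str
    rows: dict[str, str]

    def __post_init__(self) -> None:
        if not self.rows:
            raise PhylomosaicError(f"alignment {self.marker!r} has no rows")
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            detail = ", ".join(
                f"{t}={len(s)}" for t, s in sorted(self.rows.items(), key=lambda kv: len(kv[1]))
            )
            raise LengthMismatchError(
                f"alignment {self.marker!r} has ragged rows ({detail})"
            )
        for taxon, seq in self.rows.items():
            if not taxon:
                raise ParseError("empty taxon label")
            bad = set(seq) - LEGAL
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ParseError(
                    f"illegal character {seq[pos]!r} at position {pos} in taxon {taxon!r}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    def column(self, j: int) -> list[str]:
        return [seq[j] for seq in self.rows.values()]

    def subset_taxa(self, keep: Iterable[str]) -> "Alignment":
        keep = set(keep)
        return Alignment(self.marker, {t: s for t, s in self.rows.items() if t in keep})


@dataclass
class Supermatrix:
    """Concatenated alignment plus an ordered marker -> column-interval table.

    Intervals are 0-based half-open internally; :mod:`phylomosaic.seqio` writes
    them out 1-based inclusive in the RAxML partition dialect.
    """

    rows: dict[str, str]
    partitions: dict[str, tuple[int, int]]

    def __post_init__(self) -> None:
        L = self.length
        covered = 0
        prev_end = 0
        for name, (start, end) in self.partitions.items():
            if not (0 <= start < end <= L):
                raise PhylomosaicError(f"partition {name!r} interval {start, end} out of range")
            if start != prev_end:
                raise PhylomosaicError(
                    f"partition {name!r} does not abut the previous partition"
                )
            prev_end = end
            covered += end - start
        if covered != L:
            raise PhylomosaicError(
                f"partitions cover {covered} of {L} columns; they must tile the matrix"
            )
        for taxon, seq in self.rows.items():
            if len(seq) != L:
                raise LengthMismatchError(
                    f"row {taxon!r} has length {len(seq)}, expected {L}"
                )

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def markers(self) -> list[str]:
        return list(self.partitions)

    def segment(self, taxon: str, marker: str) -> str:
        start, end = self.partitions[marker]
        return self.rows[taxon][start:end]

    def marker_alignment(self, marker: str, drop_all_missing: bool = True) -> Alignment:
        """Extract one marker back out as an :class:`Alignment`.

        Taxa whose segment is entirely ``?`` (never sequenced for the marker)
        are dropped unless *drop_all_missing* is false.
        """
        start, end = self.partitions[marker]
        rows = {}
        for taxon, seq in self.rows.items():
            seg = seq[start:end]
            if drop_all_missing and set(seg) <= {"?"}:
                continue
            rows[taxon] = seg
        return Alignment(marker, rows)


def concatenate(alignments: Sequence[Alignment]) -> Supermatrix:
    """Concatenate per-marker alignments into a supermatrix.

    The taxon set is the union over markers; a taxon absent from a marker gets
    an all-``?`` segment there. Marker input order is preserved in the
    partition table; taxa are ordered by first appearance.
    """
    if not alignments:
        raise PhylomosaicError("cannot concatenate an empty list of alignments")
    names = [a.marker for a in alignments]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise DuplicateTaxonError(f"duplicate marker names: {dup}")

    taxa: dict[str, None] = {}
    for aln in alignments:
        for t in aln.rows:
            taxa.setdefault(t)

    partitions: dict[str, tuple[int, int]] = {}
    pos = 0
    for aln in alignments:
        partitions[aln.marker] = (pos, pos + aln.length)
        pos += aln.length

    rows = {
        t: "".join(aln.rows.get(t, "?" * aln.length) for aln in alignments)
        for t in taxa
    }
    return Supermatrix(rows, partitions)


def gap_threshold_trim(aln: Alignment, gt: float) -> tuple[Alignment, list[int]]:
    """Drop columns whose fraction of non-missing residues falls below *gt*.

    A column is retained iff the fraction of its residues outside ``{-, ?}``
    is >= *gt* (the gap-threshold rule of trimAl's ``-gt``; the similarity
    score ``-st`` is deliberately not emulated). Returns the trimmed alignment
    together with the retained original column indices. May return a
    zero-column alignment.
    """
    if not 0.0 <= gt <= 1.0:
        raise ValueError(f"gap threshold must be in [0, 1], got {gt}")
    mat = np.array([list(s) for s in aln.rows.values()])
    defined = ~np.isin(mat, ["-", "?"])
    frac = defined.mean(axis=0)
    kept = [j for j in range(aln.length) if frac[j] >= gt]
    rows = {t: "".join(s[j] for j in kept) for t, s in aln.rows.items()}
    return Alignment(aln.marker, rows), kept


def count_informative_sites(aln: Alignment) -> tuple[int, float]:
    """Count parsimony-informative columns and their percentage of the length.

    A column is parsimony-informative iff, counting only unambiguous states
    {A,C,G,T}, at least two distinct states each occur in at least two taxa.
    """
    if aln.length == 0:
        raise DegenerateInputError(f"alignment {aln.marker!r} has zero columns")
    mat = np.array([list(s) for s in aln.rows.values()])
    count = 0
    for j in range(mat.shape[1]):
        states, n = np.unique(mat[:, j], return_counts=True)
        keep = np.isin(states, list(UNAMBIGUOUS))
        if (n[keep] >= 2).sum() >= 2:
            count += 1
    return count, 100.0 * count / aln.length


def missing_fraction(
    matrix: Supermatrix, per: str = "global"
) -> float | dict[str, float]:
    """Fraction of cells in ``{-, ?}`` at taxon, marker, or global granularity."""
    mat = np.array([list(s) for s in matrix.rows.values()])
    miss = np.isin(mat, ["-", "?"])
    if per == "global":
        return float(miss.mean())
    if per == "taxon":
        return {t: float(miss[i].mean()) for i, t in enumerate(matrix.taxa)}
    if per == "marker":
        return {
            m: float(miss[:, s:e].mean()) for m, (s, e) in matrix.partitions.items()
        }
    raise ValueError(f"per must be 'taxon', 'marker' or 'global', got {per!r}")
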