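"""Exception hierarchy.

All package-specific failures derive from :class:`PhylomosaicError` so callers
can catch one type at pipeline boundaries.
"""


class PhylomosaicError(Exception):
    """Base class for all phylomosaic errors."""


class ParseError(PhylomosaicError):
    """Malformed input file or string."""


class DuplicateTaxonError(ParseError):
    """The same taxon label appears more than once where uniqueness is required."""


class LengthMismatchError(PhylomosaicError):
    """Sequences that must be equal length are not."""


class TaxonomyConflictError(ParseError):
    """A taxon is assigned to two different groups."""


class MissingTaxonError(PhylomosaicError):
    """A required taxon is absent from a tree or alignment."""


class SaturationError(PhylomosaicError):
    """A distance is undefined because the observed divergence exceeds the
    model's resolvable range (e.g. p >= 0.75 under Jukes-Cantor)."""


class DegenerateInputError(PhylomosaicError):
    """An input is too small or too uniform for the requested computation."""


class MonophylyError(PhylomosaicError):
    """A composite group is not monophyletic on the reference tree."""
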