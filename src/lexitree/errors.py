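"""Exception hierarchy.

All package errors derive from :class:`LexitreeError` so callers can catch
one base class; subclasses distinguish malformed input, degenerate data and
undefined scores.
"""


class LexitreeError(Exception):
    """Base class for all lexitree errors."""


class DataFormatError(LexitreeError):
    """A file does not conform to the expected dialect (bad header, etc.)."""


class EmptyInputError(LexitreeError):
    """Structurally valid input that contains no usable data."""


class NoOverlapError(LexitreeError):
    """Two lexicons share no attested meaning, so no distance is defined."""


class DegenerateNormalizerError(LexitreeError):
    """The LDND cross-meaning normalizer is zero or cannot be formed."""


class NewickParseError(DataFormatError):
    """Malformed Newick text (unbalanced parentheses, duplicate leaves...)."""


class LeafSetMismatchError(LexitreeError):
    """An operation requires two trees (or a split and a tree) on the same leaves."""


class UndefinedScoreError(LexitreeError):
    """A tree score is undefined for this input (e.g. GRF of a star tree)."""
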