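"""Exception hierarchy.

``InputError`` subclasses map to CLI exit code 2, ``StatsError`` to 3.
"""


class MitotyperError(Exception):
    """Base class for all package errors."""


class InputError(MitotyperError):
    """Malformed or inconsistent user input (CLI exit code 2)."""


class AlignmentError(InputError):
    """Sequences of unequal length or otherwise not a valid alignment."""


class LabelingError(InputError):
    """Sample sheet does not cover the alignment, or labels are invalid."""


class AlphabetError(InputError):
    """A symbol outside the IUPAC nucleotide alphabet (or a misuse of one)."""


class CoordinateError(InputError):
    """Feature coordinates fall outside the sequence they refer to."""


class AnnotationError(InputError):
    """A named element is missing from, or inconsistent with, the model."""


class GroupingError(InputError):
    """A sample grouping (mitotype/population) selects an empty set."""


class StatsError(MitotyperError):
    """A statistic is undefined for the given input (CLI exit code 3)."""


class UndefinedIdentityError(StatsError):
    """Percent identity requested over zero comparable columns."""


class UndefinedDistanceError(StatsError):
    """Distance requested over zero comparable columns."""
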