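"""Exception hierarchy for the pipeline.

Every error raised on bad user input or contract violation derives from
:class:`MlstError`, so callers (and the CLI) can catch one base class.
"""


class MlstError(Exception):
    """Base class for all mlstpop errors."""


class ConfigurationError(MlstError):
    """Invalid simulation or pipeline configuration."""


class AlphabetError(MlstError):
    """Sequence contains characters outside {A, C, G, T}."""


class FormatError(MlstError):
    """Malformed on-disk input (FASTA headers, TSV columns...)."""


class TrimError(MlstError):
    """Raw sequence cannot be trimmed to the scheme length."""


class LocusMismatchError(TrimError):
    """Best trim window falls below the identity floor for the locus."""


class TypingError(MlstError):
    """Allele or ST assignment contract violated."""


class AlignmentError(MlstError):
    """Sequences do not form a rectangular alignment."""


class StatsError(MlstError):
    """Statistic undefined for the given input (e.g. too few sequences)."""


class PhiTestError(StatsError):
    """Too few parsimony-informative sites for the recombination test."""


class ScanError(MlstError):
    """Recombinant-segment scan received an empty or unlabeled alignment."""


class MatrixError(MlstError):
    """Distance matrix is not symmetric/zero-diagonal, or is saturated."""


class LabelingError(MlstError):
    """Tree leaf lacks a group label."""
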