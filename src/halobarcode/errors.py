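"""Exception types shared across the pipeline.

Every stage raises one of these instead of a bare ``ValueError`` so the
pipeline driver can abort with the stage name and the offending record.
"""


class HalobarcodeError(Exception):
    """Base class for all package errors."""


class AlignmentError(HalobarcodeError):
    """Rows of an alignment disagree in length, or the alignment is empty."""


class ReconciliationError(HalobarcodeError):
    """A sequence/tip identifier cannot be matched to a metadata record."""


class SequenceParseError(HalobarcodeError):
    """An unknown residue character (with position) or malformed input."""


class UndefinedDistanceError(HalobarcodeError):
    """An operation that requires defined distances met an undefined entry."""


class UndefinedComparisonError(HalobarcodeError):
    """A pairwise site comparison has no valid (ungapped, unambiguous) sites."""


class SubsampleError(HalobarcodeError):
    """A proportional subsample cannot preserve every haplotype."""


class ConfigError(HalobarcodeError):
    """A pipeline configuration is missing a mandatory key (e.g. the seed)."""
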