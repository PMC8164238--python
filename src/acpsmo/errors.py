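"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`AcpsmoError`, so callers (and the CLI) can distinguish data
problems from genuine bugs.
"""


class AcpsmoError(Exception):
    """Base class for all errors raised by acpsmo."""


class FastaParseError(AcpsmoError):
    """A FASTA file could not be parsed (bad header, empty record...)."""


class DataSizeError(AcpsmoError):
    """A dataset is too small for the requested operation."""


class FeatureMismatchError(AcpsmoError):
    """Feature vectors are incompatible (dimension or recipe mismatch)."""


class UndefinedMetricError(AcpsmoError):
    """A metric denominator is zero; the value is undefined, not 0."""


class NotCalibratedError(AcpsmoError):
    """Probability output requested from a model without Platt parameters."""
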