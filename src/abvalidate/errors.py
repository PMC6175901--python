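"""Exception hierarchy.

Every parser/operation failure mode has a named exception so callers (and the
CLI) can distinguish bad input files from bad configuration from genuinely
degenerate biology. Degenerate *biological* situations that a validation pillar
knows how to score (zero-variance series, undetected proteins) do NOT raise —
they map to the ``uncertain`` status instead; these exceptions are for contract
violations.
"""


class AbvalidateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(AbvalidateError):
    """A file does not conform to the expected tabular layout."""


class DuplicateKeyError(AbvalidateError):
    """A gene, sample, or pillar appears more than once where uniqueness is required."""


class DataValueError(AbvalidateError):
    """A cell holds a value outside its domain (negative abundance, non-numeric)."""


class ConfigurationError(AbvalidateError):
    """Missing or inconsistent configuration (e.g. migration without a ladder)."""


class CalibrationError(AbvalidateError):
    """A molecular-weight ladder is unusable (<2 points, non-monotone)."""


class GelRangeError(AbvalidateError):
    """A migration distance or band MW falls outside the calibrated/gel range."""


class SequenceError(AbvalidateError):
    """An amino-acid sequence is empty or contains a non-standard letter."""


class DegenerateSeriesError(AbvalidateError):
    """A series has zero variance or is otherwise unusable for the statistic."""


class EmptyLaneError(AbvalidateError):
    """A lane with no bands was passed where at least one band is required."""


class ProteinNotCoveredError(AbvalidateError):
    """The protein is absent from the capture-MS slice counts (distinct from all-zero)."""


class UsageError(AbvalidateError):
    """Operations combined incorrectly (mismatched targets, duplicate pillars)."""


class ParameterError(AbvalidateError):
    """A generator or statistical parameter is outside its valid range."""
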