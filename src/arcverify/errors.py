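"""Exception hierarchy for arcverify."""


class ArcverifyError(Exception):
    """Base class for all arcverify errors."""


class FormatError(ArcverifyError):
    """A file does not conform to its documented dialect."""


class ValidationError(ArcverifyError):
    """Structurally parseable content violates a domain invariant."""


class TrajectoryError(ArcverifyError):
    """Gantry angle sequence cannot be unwrapped unambiguously."""


class RangeError(ArcverifyError):
    """Requested MU lies outside the plan range and clamping is disabled."""


class PairingError(ArcverifyError):
    """Plan and record (or keyed series) do not refer to the same field."""


class UndefinedMetricError(ArcverifyError):
    """A metric has no included samples to aggregate."""


class UndefinedCorrelationError(ArcverifyError):
    """Correlation is undefined (constant series or too few points)."""


class DegenerateSegmentError(ArcverifyError):
    """A plan segment has zero gantry travel where motion is required."""


class ConfigurationError(ArcverifyError):
    """An alert rule or config file references unknown content."""


class UnsupportedContentError(ArcverifyError):
    """A DICOM file lacks the structures needed to build an arc plan."""
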