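"""Exception hierarchy."""


class PhenocloudError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PhenocloudError):
    """A camera/acquisition/run configuration value is invalid."""


class NegativeOverlapError(InvalidConfigError):
    """Image step exceeds the field of view, implying negative overlap."""


class FormatError(PhenocloudError):
    """A file (PLY, CSV, config) does not match the expected schema."""


class EmptySegmentError(PhenocloudError):
    """A crop region or selection produced no points."""


class DegenerateClusterError(PhenocloudError):
    """Clustering input cannot be split into two clusters."""


class NoPlantError(PhenocloudError):
    """No plant points were detected in a segment."""
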