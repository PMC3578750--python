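"""Exception types raised by the analysis pipeline."""


class ReplitimeError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(ReplitimeError, ValueError):
    """A simulation or run configuration violates its invariants."""


class InsufficientDataError(ReplitimeError, ValueError):
    """Too few observations to fit a model."""


class DegenerateInputError(ReplitimeError, ValueError):
    """Input with no usable variation (e.g. all values identical)."""


class MissingMeasurementError(ReplitimeError, KeyError):
    """A required qPCR measurement (fraction, reference, sample) is absent."""


class EmptyGroupError(ReplitimeError, ValueError):
    """A comparison group is empty after filtering."""
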