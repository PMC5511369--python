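"""Exception hierarchy shared across the package."""


class ClonalCircuitsError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ClonalCircuitsError, ValueError):
    """A domain object or parameter violates its invariants."""


class SimulationError(ClonalCircuitsError, RuntimeError):
    """Numerical integration produced a non-finite state."""


class ProtocolError(ClonalCircuitsError, RuntimeError):
    """A recording session lacks the epochs a detector needs."""


class InsufficientDataError(ClonalCircuitsError, RuntimeError):
    """Fewer trials than the detection criteria require."""


class FeatureUndefinedError(ClonalCircuitsError, ValueError):
    """Subtype classification was asked for with undefined features."""

    def __init__(self, missing):
        self.missing = list(missing)
        super().__init__(f"undefined features: {', '.join(self.missing)}")


class DegenerateTableError(ClonalCircuitsError, ValueError):
    """A contingency table has a zero margin; the test is undefined."""


class FormatError(ClonalCircuitsError, ValueError):
    """A file does not conform to the expected container layout."""
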