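"""Exception hierarchy for the plate-scan counting pipeline."""


class TilecountError(Exception):
    """Base class for all package errors."""


class ImageIOError(TilecountError):
    """An image file could not be read or written."""


class MetadataError(TilecountError):
    """A filename did not match the expected well-naming pattern."""


class ConfigurationError(TilecountError):
    """An invalid parameter value or config file entry."""


class GenerationError(TilecountError):
    """The synthetic renderer could not satisfy its constraints."""


class NoWellFoundError(TilecountError):
    """No sufficiently large object survived the well size gate.

    Carries the equivalent diameter of the largest candidate (or 0.0 if the
    frame was featureless) for diagnostics.
    """

    def __init__(self, message: str, largest_diameter: float = 0.0):
        super().__init__(message)
        self.largest_diameter = float(largest_diameter)


class LowMaskAreaError(TilecountError):
    """Mask erosion removed every remaining pixel."""


class ContractError(TilecountError):
    """Caller violated an operation precondition (e.g. shape mismatch)."""


class UndefinedPDError(TilecountError):
    """Population doubling is undefined (zero count at an endpoint)."""


class AggregationError(TilecountError):
    """A replicate group was empty after exclusions."""


class RunError(TilecountError):
    """A whole-plate run could not start (e.g. no parseable inputs)."""
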