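"""Exception hierarchy shared across the package."""


class PiosphereError(Exception):
    """Base class for all package-specific errors."""


class FormatError(PiosphereError):
    """Input file does not conform to the expected layout (e.g. missing columns)."""


class ValidationError(PiosphereError):
    """Data violate a declared invariant (counts, categories, uniqueness...)."""


class EmptySelectionError(PiosphereError):
    """A filter or aggregation produced no samples; never silently a 0x0 matrix."""


class DegenerateMatrixError(PiosphereError):
    """A matrix operation received an all-zero or otherwise degenerate matrix."""


class UndefinedPairError(PiosphereError):
    """A pairwise dissimilarity is undefined (e.g. two completely empty samples)."""


class UndefinedDiversityError(PiosphereError):
    """Alpha diversity requested for an empty community."""


class ConfigurationError(PiosphereError):
    """A run or generator configuration is internally inconsistent."""
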