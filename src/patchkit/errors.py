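"""Exception types shared across the package."""


class PatchkitError(Exception):
    """Base class for all package errors."""


class InvalidTrackError(PatchkitError, ValueError):
    """A track violates the basic trajectory invariants."""


class InsufficientDataError(PatchkitError, ValueError):
    """Too few points/tracks/bins for the requested computation."""


class DegenerateInputError(PatchkitError, ValueError):
    """Input is structurally valid but carries no usable signal."""


class TrackFormatError(PatchkitError, ValueError):
    """A trajectory or localization file could not be parsed."""


class PairingError(PatchkitError, ValueError):
    """Two-channel event pairs do not share an event."""


class UnresolvableGraphError(PatchkitError, ValueError):
    """A ratio-graph component has no anchored absolute count."""


class ConfigurationError(PatchkitError, ValueError):
    """A required configuration entry (e.g. a fluorophore) is missing."""
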