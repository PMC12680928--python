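"""Exception hierarchy for the astromorph pipeline."""


class AstromorphError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AstromorphError):
    """A config value is invalid or an unavailable backend was requested."""


class PlacementInfeasibleError(AstromorphError):
    """Rejection sampling could not place somata at the requested density."""


class NoForegroundError(AstromorphError):
    """The image has no separable foreground (e.g., constant intensity)."""


class UndefinedThresholdError(AstromorphError):
    """The per-sample threshold is undefined (empty or full foreground)."""


class DisconnectedMaskError(AstromorphError):
    """An operation requiring a single connected mask got several components."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(f"mask has {n_components} connected components; expected 1")


class MissingUpstreamError(AstromorphError):
    """A pipeline stage was invoked before its upstream artifacts exist."""
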