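"""Exception hierarchy shared across the pipeline."""


class InterbrainError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(InterbrainError, ValueError):
    """Invalid configuration value or combination."""


class GridError(InterbrainError, ValueError):
    """Scale grid cannot be constructed from the requested frequencies."""


class DegenerateInputError(InterbrainError, ValueError):
    """Input signal carries no usable information (e.g. zero variance)."""


class NoBandError(InterbrainError, ValueError):
    """Mean coherence curve has no interior peak; no band can be selected."""


class EmptyWindowError(InterbrainError, ValueError):
    """A block window contains no usable volumes."""
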