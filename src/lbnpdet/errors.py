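"""Exception types shared across the pipeline."""


class LbnpError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(LbnpError, ValueError):
    """A configuration value violates its documented constraints."""


class InvalidInputError(LbnpError, ValueError):
    """An input array or table violates a precondition (ordering, grid, labels)."""


class InsufficientDataError(LbnpError, ValueError):
    """Not enough data to compute the requested quantity (too few beats, troughs, ...)."""
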