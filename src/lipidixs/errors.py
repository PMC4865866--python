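"""Exception hierarchy for lipidixs."""


class LipidIXSError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(LipidIXSError, ValueError):
    """A physical parameter violates its constraints (e.g. fwhm <= 0)."""


class InvalidInputError(LipidIXSError, ValueError):
    """An input array or grid violates its contract."""


class UnderDeterminedError(LipidIXSError, ValueError):
    """Fewer data points than free parameters."""


class InsufficientDataError(LipidIXSError, ValueError):
    """Not enough usable points for a derived-quantity estimate."""


class SpectrumParseError(LipidIXSError, ValueError):
    """A spectrum file is malformed; the message names the offending line/key."""


class ConfigError(LipidIXSError, ValueError):
    """A run configuration is malformed or contains unknown keys."""


class EmptyResultError(LipidIXSError, RuntimeError):
    """Every per-Q analysis failed; the pipeline has nothing to report."""
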