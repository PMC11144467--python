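"""Exception hierarchy shared across the package."""


class MRTargetError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MRTargetError):
    """A required column, file, or configuration entry is missing or malformed."""


class EmptyInputError(MRTargetError):
    """An input yielded zero usable records."""


class NoInstrumentsError(MRTargetError):
    """No variants survived selection or harmonization."""


class DegenerateInstrumentError(MRTargetError):
    """An instrument's exposure effect is zero (or otherwise unusable)."""


class DomainError(MRTargetError):
    """A numeric argument lies outside the domain of a formula."""


class CollinearityError(MRTargetError):
    """Regression design is degenerate (e.g. all exposure effects identical)."""
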