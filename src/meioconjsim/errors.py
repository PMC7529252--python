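"""Exception hierarchy shared across the package.

All errors derive from :class:`MeioconjsimError` so callers can catch the
package's failures with a single ``except`` clause while still
distinguishing configuration mistakes from degenerate data.
"""


class MeioconjsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MeioconjsimError):
    """A scenario or config file is malformed or inconsistent."""


class ScenarioSizeError(MeioconjsimError):
    """Exact enumeration was requested for a state space that is too large."""


class ValidationError(MeioconjsimError):
    """An input record violates a documented precondition."""


class UndefinedRatioError(MeioconjsimError):
    """A ratio was requested whose denominator is exactly zero.

    Raised instead of returning ``inf``/``nan`` so that undefined ratios
    can never leak silently into downstream aggregates.
    """


class DegenerateInputError(MeioconjsimError):
    """Numerically degenerate input (e.g. an all-zero intensity trace)."""


class LayoutError(MeioconjsimError):
    """Synthetic image layout cannot satisfy the packing constraints."""
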