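"""Exception hierarchy shared across the package.

Validation errors map to CLI exit code 2, numerical failures to exit code 3.
"""


class MvplnError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MvplnError, ValueError):
    """Malformed input data or configuration."""


class DefinitenessError(MvplnError, ValueError):
    """A matrix required to be symmetric positive definite is not."""


class DegenerateComponentError(MvplnError, RuntimeError):
    """A mixture component collapsed (effective size ~ 0) during fitting."""


class SamplerError(MvplnError, RuntimeError):
    """The MCMC sampler failed (e.g. zero acceptance after adaptation)."""


class NormalizationError(MvplnError, ValueError):
    """Library-size normalization cannot be computed (e.g. all-zero sample)."""
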