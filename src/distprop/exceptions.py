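"""Exception hierarchy."""


class DistpropError(Exception):
    """Base class for all package errors."""


class DomainError(DistpropError, ValueError):
    """Invalid parameter or input value (wrong sign, out of domain, non-finite)."""


class ConfigError(DistpropError, ValueError):
    """Inconsistent analysis configuration (duplicate labels, bad level, ...)."""


class DegenerateTailError(DistpropError):
    """The cut-point is so extreme that the tail proportion is numerically 0 or 1.

    Dichotomising at such a cut-point is not meaningful: the delta-method
    standard error degenerates and ratio estimates are undefined.
    """


class NumericalError(DistpropError, ArithmeticError):
    """A numerical routine (quadrature, optimisation) failed to converge."""
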