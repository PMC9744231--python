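"""Exception hierarchy used across the package."""


class UbiquifoldError(Exception):
    """Base class for all package errors."""


class ParameterError(UbiquifoldError, ValueError):
    """A parameter violates its documented invariant."""


class InputError(UbiquifoldError, ValueError):
    """Input data is structurally valid but unusable (empty, mismatched)."""


class FormatError(UbiquifoldError, ValueError):
    """A file on disk does not conform to the expected format."""


class EstimationError(UbiquifoldError, RuntimeError):
    """An estimator has no usable data; caller should fall back to a fixed value."""


class FitError(UbiquifoldError, RuntimeError):
    """Nonlinear fit failed to converge from every start."""
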