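"""Exception and warning types shared across hydrokin."""


class HydrokinError(Exception):
    """Base class for all hydrokin errors."""


class ConfigurationError(HydrokinError, ValueError):
    """An assay or study configuration value is invalid."""


class InputDataError(HydrokinError, ValueError):
    """Input data violate a structural requirement (ordering, sign, shape)."""


class DegenerateDataError(InputDataError):
    """Data are structurally valid but carry no information to fit (e.g. all-zero product)."""


class FitError(HydrokinError, RuntimeError):
    """Nonlinear fit failed to converge; carries solver diagnostics.

    Attributes
    ----------
    diagnostics : dict
        Solver status, message and the starting points that were tried.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class MonotonicityWarning(UserWarning):
    """A cumulative titrant trace decreased and was corrected."""


class ExtrapolationWarning(UserWarning):
    """A prediction was requested outside the fitted design region."""


class BoundaryWarning(UserWarning):
    """A fitted parameter ended on its bound; a limiting model was reported."""
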