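"""Exception and warning types shared across the pipeline."""


class PlimoxError(Exception):
    """Base class for all package errors."""


class ConfigError(PlimoxError):
    """Invalid, inconsistent or unknown configuration."""


class DegenerateInputError(PlimoxError):
    """Input is structurally valid but carries no usable signal
    (e.g. a decay with zero dynamic range)."""


class CalibrationError(PlimoxError):
    """A measured lifetime is incompatible with the calibration
    (tau > tau0 beyond tolerance)."""


class IntegrityError(PlimoxError):
    """A stored container is truncated or violates its schema."""


class FitNonConvergenceError(PlimoxError):
    """The nonlinear fit failed to converge; carries the optimizer message."""


class FewDecaysWarning(UserWarning):
    """Outlier rejection requested on fewer than 3 decays; passed through."""


class UnresolvableFluxWarning(UserWarning):
    """More than 95% of trace samples sit inside valleys; the counted
    flux is a lower bound only."""


class UnclassifiedVesselWarning(UserWarning):
    """A penetrating vessel lacks a day-0 surface pO2 and cannot be
    classified as arteriole/venule."""


class EmptyLayerWarning(UserWarning):
    """A layer requested in a summary has no records of the required class."""
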