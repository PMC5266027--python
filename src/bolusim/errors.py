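"""Exception hierarchy.

All bolusim errors derive from :class:`BolusimError` so callers can catch the
package's failures with one clause while letting programming errors surface.
"""


class BolusimError(Exception):
    """Base class for all bolusim errors."""


class ValidationError(BolusimError, ValueError):
    """An input value violates a domain invariant (names the offending field)."""


class ConfigurationError(BolusimError, ValueError):
    """A configuration table is inconsistent (bad fractions, unknown names)."""


class ConstructionError(BolusimError, ValueError):
    """The compartment topology cannot be assembled into a valid model."""


class IntegrationError(BolusimError, RuntimeError):
    """The ODE solver failed or produced non-finite state."""


class CalibrationError(BolusimError, KeyError):
    """No enhancement calibration for the requested tube voltage."""


class ParseError(BolusimError, ValueError):
    """A TDC file could not be parsed; message carries the line number."""


class DegenerateCurveError(BolusimError, ValueError):
    """A curve carries no usable signal (e.g. flat curve with auto baseline)."""


class EmptyCohortError(BolusimError, ValueError):
    """A cohort specification produces zero patients."""
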