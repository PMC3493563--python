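"""Exception hierarchy.

All package-specific failures derive from :class:`ClquantError` so callers
can catch one base class at pipeline boundaries.
"""


class ClquantError(Exception):
    """Base class for all clquant errors."""


class ConfigurationError(ClquantError):
    """Invalid parameter set (infeasible truncation, bad step list, unknown config keys)."""


class ProtocolError(ClquantError):
    """Protocol/trace mismatch, e.g. a step window outside the recorded trace."""


class CalibrationError(ClquantError):
    """Unusable calibration: missing 0 mM anchor, too few steps, non-physical fit."""


class DataError(ClquantError):
    """Malformed or insufficient measurement data (short traces, non-positive fluorescence)."""


class FitError(ClquantError):
    """Degenerate or impossible curve fit (e.g. flat dose-response data)."""
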