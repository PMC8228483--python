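"""Exception hierarchy for the DER package."""


class DERError(Exception):
    """Base class for all DER errors."""


class FormatError(DERError):
    """A file does not follow the documented container layout."""


class ShapeError(DERError):
    """An array has the wrong shape (e.g. a waveform that is not 64 samples)."""


class ReferentialIntegrityError(DERError):
    """An event references a cluster or channel id that does not resolve."""


class CalibrationError(DERError):
    """Threshold calibration cannot proceed (e.g. too few events)."""


class ConfigError(DERError):
    """An invalid algorithm parameter (e.g. an even number of correlogram bins)."""


class SimulationSpecError(DERError):
    """An infeasible synthetic-session specification."""
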