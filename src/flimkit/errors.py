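"""Exception hierarchy shared across flimkit."""


class FlimkitError(Exception):
    """Base class for all flimkit errors."""


class ConfigError(FlimkitError):
    """Invalid configuration value or missing required configuration block."""


class AxisMismatchError(FlimkitError):
    """Two objects that must share a time axis (and period) do not."""


class MissingWindowError(FlimkitError, KeyError):
    """A spectral window is not defined for the probe model at hand."""


class UndefinedResultError(FlimkitError, ValueError):
    """The requested quantity is mathematically undefined for this input
    (e.g. GP of two zero intensities, phasor of an empty histogram)."""


class EmptySelectionError(FlimkitError):
    """An ROI or mask selects no pixels."""


class CalibrationError(FlimkitError):
    """Phasor calibration is impossible (zero-modulus reference point)."""


class EmptyProfileError(FlimkitError):
    """Every spectral window failed quality control; no profile can be built."""


class FormatError(FlimkitError):
    """A file does not conform to the documented on-disk format."""
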