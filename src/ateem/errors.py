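"""Exception hierarchy shared across the package."""


class ATEEMError(ValueError):
    """Base class for all domain errors raised by this package."""


class FormatError(ATEEMError):
    """A file does not conform to the expected plain-text layout."""


class GridError(ATEEMError):
    """A wavelength grid is invalid or a requested wavelength misses it."""


class AlignmentError(ATEEMError):
    """Objects that must share a wavelength grid do not."""


class RangeError(ATEEMError):
    """A wavelength range selects no grid points."""


class DimensionError(ATEEMError):
    """An array dimension does not match its contract."""


class CoverageError(ATEEMError):
    """An absorbance spectrum does not cover the EEM wavelength range."""


class ClassError(ATEEMError):
    """Class labels are missing, unbalanced to degeneracy, or not two-class."""


class ConfigError(ATEEMError):
    """A configuration value violates its invariant."""
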