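"""Exception hierarchy for the saliva Raman pipeline.

Every stage raises a subclass of :class:`SalivaRamanError` so callers (and the
CLI's per-stage exit codes) can distinguish I/O, validation, preprocessing and
modelling failures.
"""


class SalivaRamanError(Exception):
    """Base class for all package errors."""


class SpectrumParseError(SalivaRamanError):
    """A spectrum file could not be parsed (malformed line, bad dialect)."""


class SpectrumContentError(SalivaRamanError):
    """A parsed spectrum violates content rules (too short, duplicate axis)."""


class ClinicalValidationError(SalivaRamanError):
    """A clinical record violates its invariants (e.g. OSAS with AHI < 5)."""


class LinkageError(SalivaRamanError):
    """A spectrum references a subject absent from the clinical table."""


class StageError(SalivaRamanError):
    """A processing stage received a spectrum in the wrong pipeline stage."""


class CoverageError(SalivaRamanError):
    """A wavenumber window or grid extends beyond the spectrum's axis."""


class AlignmentError(SalivaRamanError):
    """The reference-peak shift is implausibly large (miscalibration)."""


class GridMismatchError(SalivaRamanError):
    """Operands are not on the same wavenumber grid."""


class NormalizationError(SalivaRamanError):
    """A spectrum cannot be normalized (all-zero intensities)."""


class FitError(SalivaRamanError):
    """A model fit failed (too few points, rank deficiency)."""


class DegenerateDataError(SalivaRamanError):
    """A statistic is undefined on this input (constant sample, empty group)."""


class ConfigError(SalivaRamanError):
    """A run or generator configuration is invalid."""
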