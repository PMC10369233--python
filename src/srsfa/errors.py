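"""Exception hierarchy for srsfa.

Every error raised on a user-facing contract violation derives from
:class:`SrsfaError`, so callers can catch the package's failures with a
single except clause while still distinguishing the specific condition.
"""


class SrsfaError(Exception):
    """Base class for all srsfa errors."""


class InvalidSpectrumError(SrsfaError):
    """Spectrum cannot be normalized (all-zero or non-positive area)."""


class AxisMismatchError(SrsfaError):
    """Two spectral objects do not share a common wavenumber axis."""


class DegenerateWeightsError(SrsfaError):
    """A weighted combination was requested with all-zero weights."""


class AugmentationDegenerateError(SrsfaError):
    """GC-MS augmentation produced all-zero fatty-acid shares."""


class CalibrationError(SrsfaError):
    """Chain-length calibration is underdetermined."""


class UndefinedRatioError(SrsfaError):
    """A band-ratio denominator vanished."""


class ConvergenceError(SrsfaError):
    """Iterative solver exhausted its iteration budget.

    Carries the last iterate in :attr:`last_iterate`.
    """

    def __init__(self, message, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class EmptySelectionError(SrsfaError):
    """A component selection matched nothing (e.g. no fatty-acid maps)."""


class PackingError(SrsfaError):
    """Scene generator could not place the requested geometry."""


class NoRegionsError(SrsfaError):
    """A label mask contains no foreground regions."""


class SpacingError(SrsfaError):
    """Trajectory timestamps are not uniformly spaced."""


class FormatError(SrsfaError):
    """An on-disk file violates its documented schema."""


class ValidationError(FormatError):
    """Tabular input failed schema validation; message lists offending rows."""
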