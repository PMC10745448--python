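"""Exception hierarchy for nirerr.

All domain errors derive from :class:`NirErrError` so callers can catch the
package's failures with a single ``except`` clause while still discriminating
between alignment problems, degenerate inputs and configuration mistakes.
"""


class NirErrError(ValueError):
    """Base class for all nirerr domain errors."""


class AlignmentError(NirErrError):
    """Spectra matrix and design table disagree on the number of rows."""


class FormatError(NirErrError):
    """A file violates the expected CSV layout (header, monotonicity, cells)."""


class SelectionError(NirErrError):
    """A subset selector names an unknown factor or level."""


class InsufficientReplicatesError(NirErrError):
    """A replicate group contains fewer rows than the operation requires."""


class RankError(NirErrError):
    """Requested number of components exceeds what the data can support."""


class DegenerateSpectrumError(NirErrError):
    """A spectrum is constant (or nearly so) where variation is required."""


class ConfigError(NirErrError):
    """Invalid simulation or workflow configuration."""


class ConfoundingError(NirErrError):
    """Two design factors induce identical row partitions."""


class DegenerateFactorError(NirErrError):
    """A factor has fewer than two levels in the analysed subset."""


class DomainError(NirErrError):
    """A numeric argument lies outside its mathematical domain."""
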