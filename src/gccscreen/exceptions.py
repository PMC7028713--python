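"""Exception hierarchy for gccscreen.

All package errors derive from :class:`GCCScreenError` so callers can catch
one base class at pipeline boundaries.
"""


class GCCScreenError(Exception):
    """Base class for all gccscreen errors."""


class SchemaError(GCCScreenError):
    """A required column is absent or the column mapping is inconsistent."""


class FormatError(GCCScreenError):
    """Input file content cannot be parsed into the expected types."""


class ConfigError(GCCScreenError):
    """A configuration value violates its contract."""


class DomainError(GCCScreenError):
    """A numeric input lies outside the mathematically valid domain."""


class TrainingError(GCCScreenError):
    """Autoencoder optimisation diverged (non-finite loss)."""


class OrientationError(GCCScreenError):
    """Score orientation is undefined (e.g. zero-variance anchor)."""


class UndefinedAUCError(GCCScreenError):
    """AUC requested with fewer than two classes present."""


class PairingError(GCCScreenError):
    """Paired comparison requested on incompatible fold structures."""


class ImputationError(GCCScreenError):
    """Chained-equation imputation cannot proceed (e.g. fully missing column)."""
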