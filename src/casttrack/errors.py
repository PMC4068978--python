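"""Exception hierarchy.

All failures raise a subclass of :class:`CastTrackError` so callers (and the
CLI) can distinguish configuration mistakes (exit code 2) from runtime
failures (exit code 1).
"""


class CastTrackError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CastTrackError):
    """Invalid user-supplied configuration or parameters."""


class DegeneracyError(CastTrackError):
    """Geometric degeneracy: collinear points, rank-deficient fits, empty sets."""


class AnchoringError(CastTrackError):
    """Too few (or contaminated) reference teeth to superimpose casts."""


class IntegrityError(CastTrackError):
    """Inconsistent on-disk artifacts (e.g. label/point count mismatch)."""


class ScanParseError(CastTrackError):
    """Malformed scan, transform or manifest file."""


class UndefinedEfficacyError(CastTrackError):
    """Efficacy requested against a zero planned movement."""
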