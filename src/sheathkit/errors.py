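"""Exception hierarchy used across sheathkit."""


class SheathkitError(Exception):
    """Base class for all sheathkit errors."""


class DegenerateHelixError(SheathkitError, ValueError):
    """Raised when a helix parameter makes the geometry undefined (e.g. zero twist)."""


class IncompatibleStatesError(SheathkitError, ValueError):
    """Raised when two helical states cannot be compared (different n-start/handedness)."""


class InsufficientOverlapError(SheathkitError, ValueError):
    """Raised when a rise is so large that fewer than two screw copies fit in the box."""


class UndefinedScoreError(SheathkitError, ValueError):
    """Raised when a symmetry score is requested on a zero-variance masked region."""


class MeasurementError(SheathkitError, RuntimeError):
    """Raised when a measurement (e.g. coil pitch) cannot be extracted from an image."""


class NoSheathDetectedError(SheathkitError, ValueError):
    """Raised when an axial profile contains no above-threshold sheath region."""


class AtlasFormatError(SheathkitError, ValueError):
    """Raised when an atlas CSV is missing columns or contains unparsable values."""


class MapFormatError(SheathkitError, ValueError):
    """Raised for malformed or non-cubic-voxel density map files."""
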