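"""Exception hierarchy for rplcpore.

Every error raised on a user-facing code path derives from
:class:`RplcPoreError` so callers can catch the package's failures with a
single except clause.
"""


class RplcPoreError(Exception):
    """Base class for all rplcpore errors."""


class ParseError(RplcPoreError):
    """Malformed input file; the message names the offending line."""


class TopologyError(RplcPoreError):
    """Frame/topology mismatch or an ill-formed topology record."""


class GeometryError(RplcPoreError):
    """Geometrically impossible or inconsistent input (e.g. a slab frame
    passed to a bulk-only routine, a zero-length molecular vector)."""


class ConfigError(RplcPoreError):
    """Invalid generator or pipeline configuration."""


class EmptySelectionError(RplcPoreError):
    """A density-profile selector matched no molecules."""


class WindowError(RplcPoreError):
    """Frames do not span the requested observation window."""


class NoStationaryPhaseError(RplcPoreError):
    """Contact profile is everywhere below one contact."""


class NoMinimumError(RplcPoreError):
    """A radial distribution function has no first minimum to locate."""


class TruncationError(RplcPoreError):
    """Contact profile never drops below one contact (pore too small)."""


class UndefinedAverageError(RplcPoreError):
    """A density-weighted average has zero total weight."""


class UndefinedDecompositionError(RplcPoreError):
    """Peak decomposition of an all-zero stationary-phase profile."""


class CriteriaError(RplcPoreError):
    """Hydrogen-bond criteria missing for an annotated site class."""


class GeometryWarning(UserWarning):
    """Particle outside the expected slab geometry; value clamped."""
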