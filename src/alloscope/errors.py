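"""Exception hierarchy.

All package errors derive from :class:`AlloscopeError` so callers can catch
one base class; subclasses mark the failure mode named in each operation's
contract.
"""


class AlloscopeError(Exception):
    """Base class for all package errors."""


class InputError(AlloscopeError):
    """Unreadable, empty or otherwise unusable input."""


class TopologyFormatError(AlloscopeError):
    """Malformed topology file (e.g. duplicate atom serials)."""


class TopologyMismatchError(AlloscopeError):
    """Trajectory does not match the topology (atom-count mismatch etc.)."""


class EmptySelectionError(AlloscopeError):
    """A domain-map entry resolved to zero residues/atoms."""


class InsufficientDataError(AlloscopeError):
    """Too few frames (or atoms) for the requested statistic."""


class DegenerateGeometryError(AlloscopeError):
    """Geometrically degenerate input (collinear fit set, coincident COMs)."""


class ParameterizationError(AlloscopeError):
    """Missing physical parameters (e.g. no radius for an element)."""


class ConfigurationError(AlloscopeError):
    """Invalid run/analysis configuration."""


class SpecError(AlloscopeError):
    """Invalid synthetic-trajectory specification."""
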