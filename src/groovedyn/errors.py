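"""Exception hierarchy.

All package errors derive from :class:`GrooveDynError` so callers can catch
one base class; the CLI maps subclasses onto exit codes (2 = configuration,
3 = data/geometry).
"""


class GrooveDynError(Exception):
    """Base class for all groovedyn errors."""


class ConfigError(GrooveDynError):
    """Invalid configuration, selection spec, or parameter value."""


class StructureParseError(GrooveDynError):
    """A structure or trajectory file could not be parsed."""


class SelectionError(GrooveDynError):
    """A selection resolved to no atoms where atoms were required."""


class DegenerateGeometryError(GrooveDynError):
    """Geometry is ill-conditioned (collinear vectors, near-spherical
    inertia tensor, too few points) and the requested quantity is undefined."""


class ConstraintError(GrooveDynError):
    """A builder placement constraint could not be satisfied; the message
    names the violated constraint(s)."""
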