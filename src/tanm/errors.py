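"""Exception hierarchy.

Every error raised by the library derives from :class:`TanmError`, so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class TanmError(Exception):
    """Base class for all tanm-specific failures."""


class PdbParseError(TanmError):
    """A PDB file could not be parsed or contained no usable CA atoms."""


class MappingError(TanmError):
    """Residue mapping between two structures failed."""


class DegenerateSpringError(TanmError):
    """Two network nodes coincide; the connecting spring has no direction."""


class DisconnectedNetworkError(TanmError):
    """The contact graph of an elastic network is not connected."""


class CuspNotFoundError(TanmError):
    """No energy-gap sign change along the interpolated image series."""


class StepUnderflowError(TanmError):
    """Step-size shrinking fell below the representable floor (1e-12)."""


class MaxIterationsError(TanmError):
    """An iterative search exceeded its iteration budget."""


class EndpointRecoveryError(TanmError):
    """A descent failed to return to its end-state basin minimum."""


class IntegrityError(TanmError):
    """Cached path energies disagree with re-evaluation from coordinates."""


class DegenerateLineError(TanmError):
    """A residue pair defining a line segment has (near-)zero length."""


class PlacementError(TanmError):
    """Self-avoiding chain generation failed after bounded retries."""


class ConfigError(TanmError):
    """Run configuration contains unknown keys or invalid values."""
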