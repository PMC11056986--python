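"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigurationError-family -> 2,
data errors (parse/shape) -> 3.
"""


class TrajDivergeError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TrajDivergeError):
    """Invalid parameter, unknown format, missing radius, bad plan."""


class SelectionError(ConfigurationError):
    """Selection text could not be parsed."""


class EmptySelectionError(SelectionError):
    """Selection resolved to zero beads (never returned silently)."""


class ParseError(TrajDivergeError):
    """A structure/trajectory file failed to parse."""


class ShapeError(TrajDivergeError):
    """Bead/residue counts disagree between objects that must match."""


class GeometryError(TrajDivergeError):
    """Histogram bin geometries differ where identity is required."""


class DegenerateInputError(TrajDivergeError):
    """Point set too small or collinear for superposition."""


class EmptyWindowError(TrajDivergeError):
    """A frame range selected no frames."""
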