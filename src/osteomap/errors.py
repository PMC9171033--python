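"""Exception hierarchy for osteomap."""


class OsteomapError(Exception):
    """Base class for all osteomap errors."""


class MeshParseError(OsteomapError):
    """A mesh file could not be parsed (message names the offending location)."""


class MeshInvariantError(OsteomapError):
    """A mesh violates a structural invariant (bad indices, degenerate faces...)."""


class DegenerateGeometryError(OsteomapError):
    """Geometry too degenerate for the requested operation (e.g. collinear points)."""


class NoCandidateError(OsteomapError):
    """No correspondence candidate found within the search radius."""

    def __init__(self, vertex: int, radius: float):
        self.vertex = vertex
        self.radius = radius
        super().__init__(
            f"no candidate target vertex within search radius {radius:g} "
            f"of source vertex {vertex}; enlarge rho"
        )


class UndefinedScoreError(OsteomapError):
    """Correlation score undefined (zero variance in a neighborhood)."""


class ChainMismatchError(OsteomapError):
    """Correspondence maps do not chain (target of one != source of the next)."""


class ConfigError(OsteomapError):
    """Invalid pipeline configuration."""
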