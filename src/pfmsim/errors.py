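"""Exception hierarchy for pfmsim."""


class PFMSimError(Exception):
    """Base class for all pfmsim errors."""


class InvalidParameterError(PFMSimError, ValueError):
    """A geometry/material/config parameter violates its invariant."""


class MeshingError(PFMSimError):
    """Tetrahedralization failed (degenerate or inverted elements)."""


class SelectionError(PFMSimError):
    """A node-set selection came back empty."""


class DegenerateContactError(PFMSimError):
    """A node coincides with the sphere center; contact normal undefined."""


class SetupError(PFMSimError):
    """Initial configuration is inconsistent (e.g. initial penetration)."""


class InstabilityError(PFMSimError):
    """Explicit integration diverged (NaN or runaway displacement)."""

    def __init__(self, message: str, dt: float | None = None):
        super().__init__(message)
        self.dt = dt


class ConfigError(PFMSimError, ValueError):
    """Configuration file could not be validated."""
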