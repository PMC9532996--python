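"""Exception hierarchy shared across the package."""


class CannonboneError(Exception):
    """Base class for all package-specific errors."""


class InvalidGeometryError(CannonboneError, ValueError):
    """A section, profile or morphotype violates a geometric invariant."""


class InvalidInputError(CannonboneError, ValueError):
    """A non-geometric input (measurement list, table, range) is unusable."""


class DiscretizationError(CannonboneError, ValueError):
    """Requested mesh resolution is too coarse to represent the model."""


class BoundaryConditionError(CannonboneError, ValueError):
    """The assembled system is singular, e.g. no node is clamped."""


class StabilityError(CannonboneError, RuntimeError):
    """Explicit integration diverged; reduce ``dt_safety`` and retry."""


class CalibrationError(CannonboneError, RuntimeError):
    """Reference-fixture calibration could not bracket the target band."""


class MeshError(CannonboneError, ValueError):
    """A surface mesh is open, degenerate or otherwise unmeasurable."""


class ConfigError(CannonboneError, ValueError):
    """A configuration file contains an unknown key or a bad value."""
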