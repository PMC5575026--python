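"""Exception hierarchy shared across the package."""


class DomainError(ValueError):
    """An argument is outside the mathematical domain of an operation."""


class EstimationError(RuntimeError):
    """A statistical estimate cannot be formed from the data provided."""


class GeometryError(ValueError):
    """Rasters, masks or phantom primitives are geometrically inconsistent."""
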