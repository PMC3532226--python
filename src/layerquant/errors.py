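"""Exception hierarchy shared across the package."""


class LayerquantError(Exception):
    """Base class for all layerquant errors."""


class InvalidGeometryError(LayerquantError):
    """A node ring or parameter set does not describe a valid embryo geometry."""


class IncompatibleGeometryError(LayerquantError):
    """Two geometries cannot be combined (node counts or markers differ)."""


class DecompositionError(LayerquantError):
    """Cell-layer decomposition produced crossing or non-monotone segment edges."""


class RegistrationError(LayerquantError):
    """Point-set registration is underdetermined or degenerate."""


class EditError(LayerquantError):
    """A profile editing operation received invalid arguments."""


class NoExpressionError(LayerquantError):
    """Standardization of an all-zero profile was requested without allow_zero."""


class ZeroVarianceError(LayerquantError):
    """Constant profiles cannot enter a Pearson similarity matrix."""

    def __init__(self, labels):
        self.labels = list(labels)
        super().__init__(f"zero-variance profiles: {self.labels}")


class ReconstructionError(LayerquantError):
    """View alignment or volume reconstruction received inconsistent inputs."""
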