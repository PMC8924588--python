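"""Exception hierarchy shared across the toolkit."""


class GGCloneError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(GGCloneError):
    """Input violates a structural precondition (bad base, bad label, ...)."""


class FrameError(ValidationError):
    """Coding sequence length is not a multiple of three."""


class EntangledCutError(GGCloneError):
    """Two type IIS cut windows overlap; digestion outcome is undefined."""


class AssemblyFailure(GGCloneError):
    """No circular closure containing the backbone exists for a design."""

    def __init__(self, message: str, longest_linear=None):
        super().__init__(message)
        self.longest_linear = longest_linear
        self.side_products: list = []


class RegistryError(GGCloneError):
    """Catalog loading or lookup failure."""


class CapacityError(GGCloneError):
    """A pathway set does not fit any backbone of the toolkit."""


class UndomesticatableSite(GGCloneError):
    """No synonymous substitution can destroy a forbidden motif."""

    def __init__(self, message: str, position: int):
        super().__init__(message)
        self.position = position


class ExcisionError(GGCloneError):
    """Marker-recycling precondition not met (nothing to excise, etc.)."""
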