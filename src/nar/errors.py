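"""Exception types shared across the package."""


class NarError(Exception):
    """Base class for all package errors."""


class SpecError(NarError, ValueError):
    """An architecture specification violates a structural invariant."""


class ShapeError(NarError, ValueError):
    """Shape inference failed; carries the offending layer id.

    Parameters
    ----------
    layer_id:
        Dotted path of the layer at which inference failed.
    message:
        Human-readable description of the failure.
    """

    def __init__(self, layer_id: str, message: str):
        self.layer_id = layer_id
        super().__init__(f"{layer_id}: {message}")


class ParseError(NarError, ValueError):
    """A serialized architecture document is malformed; carries a location."""

    def __init__(self, location: str, message: str):
        self.location = location
        super().__init__(f"{location}: {message}")


class BudgetError(NarError, ValueError):
    """A requested FLOPs budget cannot be met within the supported phi range."""
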