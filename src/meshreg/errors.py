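"""Exception types shared across the package."""


class MeshregError(Exception):
    """Base class for meshreg errors."""


class ShapeMismatchError(MeshregError, ValueError):
    """Two gridded objects that must share a grid do not."""


class DegenerateInputError(MeshregError, ValueError):
    """Input is valid in type but degenerate for the requested operation
    (e.g. two constant images passed to a correlation)."""
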