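"""Exception hierarchy shared across the package."""


class MirscreenError(Exception):
    """Base class for all mirscreen errors."""


class ValidationError(MirscreenError):
    """Input data or configuration violates a documented contract."""


class SizingError(ValidationError):
    """A simulated screen cannot be laid out on the requested plates."""
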