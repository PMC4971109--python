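"""Exception hierarchy shared by all pancub modules."""


class PancubError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(PancubError):
    """Malformed or contract-violating input data."""


class UndefinedInputError(ValidationError):
    """Input for which the requested quantity is mathematically undefined
    (e.g. a zero-norm vector handed to a cosine, or GC of an empty gene)."""


class DegenerateResultError(PancubError):
    """A computation whose result carries no information (e.g. correspondence
    analysis of identical rows, which has zero inertia)."""
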