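"""Exception hierarchy for usmile."""


class UsmileError(Exception):
    """Base class for all usmile errors."""


class ValidationError(UsmileError, ValueError):
    """Raised when user-supplied data violates an input contract."""


class DegenerateReferenceError(UsmileError, ValueError):
    """Raised when the reference model is already (near-)perfect for a class.

    The relative likelihood ratio divides by the maximum achievable
    improvement over the reference; when that ceiling is zero the
    coefficient is undefined and silently returning NaN would hide it.
    """
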