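"""Exception types shared across the pipeline."""


class VtamosaicError(Exception):
    """Base class for pipeline errors."""


class ParameterError(VtamosaicError, ValueError):
    """A configuration or simulation parameter is invalid."""


class InputError(VtamosaicError, ValueError):
    """An input table or volume violates its contract."""


class IntegrityError(VtamosaicError, RuntimeError):
    """A structural invariant (e.g. funnel nesting) was violated."""
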