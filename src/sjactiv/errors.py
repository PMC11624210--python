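"""Exception types raised by sjactiv readers and models."""


class SchemaError(ValueError):
    """A required column or field is missing from an input table."""


class ValidationError(ValueError):
    """A row or value violates an invariant (e.g. start >= end, negative count)."""


class ModelVersionError(ValueError):
    """A serialized model declares an unsupported format version."""


class FitError(RuntimeError):
    """A model fit cannot proceed (e.g. no informative samples, single-class labels)."""
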