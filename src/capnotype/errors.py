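"""Exception hierarchy shared across the pipeline stages."""


class CapnotypeError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(CapnotypeError, ValueError):
    """A configuration value violates its documented invariant."""


class SchemaError(CapnotypeError, ValueError):
    """An on-disk recording or table does not match the documented schema."""


class FormatError(CapnotypeError, ValueError):
    """A file is syntactically readable but numerically malformed
    (e.g. an irregular time base)."""


class DegenerateDataError(CapnotypeError, RuntimeError):
    """The data cannot support the requested analysis
    (e.g. a single-class label table passed to the classifier)."""
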