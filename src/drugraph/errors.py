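"""Exception hierarchy for drugraph."""


class DrugraphError(Exception):
    """Base class for all package errors."""


class SchemaError(DrugraphError):
    """An input table is missing a required column or has a bad header."""


class ValidationError(DrugraphError):
    """A value violates a declared range or invariant; message carries the row."""


class EmptyNetworkError(DrugraphError):
    """No edges survive the confidence filter."""


class GraphFormatError(DrugraphError):
    """A graph container file is corrupt, truncated, or has an unknown version."""


class OneClassError(DrugraphError):
    """An operation requiring both classes received a single-class input."""
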