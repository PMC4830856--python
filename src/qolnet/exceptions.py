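"""Exception hierarchy for qolnet."""


class QolnetError(Exception):
    """Base class for all qolnet errors."""


class DataError(QolnetError):
    """Malformed or out-of-range ordinal input data."""


class DegenerateItemError(DataError):
    """An item has all responses in a single category (no variance)."""


class EstimationError(QolnetError):
    """A numerical estimation step failed (non-convergence, invalid input)."""
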