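"""Exception hierarchy for genodb."""


class GenodbError(Exception):
    """Base class for all genodb errors."""


class SchemaError(GenodbError):
    """Database schema is missing tables or has an unsupported version."""


class ReferentialError(GenodbError):
    """A link field points at a key that does not exist."""

    def __init__(self, table: str, field: str, value) -> None:
        self.table = table
        self.field = field
        self.value = value
        super().__init__(f"dangling reference: {table}.{field} = {value!r}")


class InvariantError(GenodbError):
    """A stored payload or derived table violates a structural invariant."""


class ParseError(GenodbError):
    """An input file could not be parsed; carries a 1-based line number."""

    def __init__(self, message: str, line: int | None = None) -> None:
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class PolymorphicMarkerError(GenodbError):
    """More than two distinct alleles observed at a marker: 2-bit
    compression cannot represent it."""


class RegionCallbackError(GenodbError):
    """A user callback raised inside a region iteration; names the range."""
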