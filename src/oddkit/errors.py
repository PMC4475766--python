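"""Exception hierarchy shared across the toolkit."""


class OddkitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(OddkitError):
    """A molecular file could not be parsed; carries record/line context."""

    def __init__(self, message: str, line: int | None = None, record: int | None = None):
        ctx = []
        if record is not None:
            ctx.append(f"record {record}")
        if line is not None:
            ctx.append(f"line {line}")
        if ctx:
            message = f"{message} ({', '.join(ctx)})"
        super().__init__(message)
        self.line = line
        self.record = record


class CapacityError(OddkitError):
    """A format limit (e.g. V2000's 999-atom table) was exceeded."""


class GeometryError(OddkitError):
    """Degenerate or missing geometry (collinear ring, absent coordinates)."""


class ConfigError(OddkitError):
    """Invalid configuration: unknown rule property, unregistered engine, bad paths."""


class IntegrityError(OddkitError):
    """A persisted model file is corrupt or truncated."""


class VersionError(OddkitError):
    """A persisted model file was written by an unsupported format version."""


class DescriptorMismatchError(OddkitError):
    """Descriptors offered for prediction do not match the model's training descriptors."""
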