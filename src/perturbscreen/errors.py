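"""Structured exceptions raised across the package."""


class PerturbScreenError(Exception):
    """Base class for all package errors."""


class HeaderError(PerturbScreenError):
    """No data-header row found (first two columns must be 'Date Time', 'Elapsed')."""


class LabelParseError(PerturbScreenError):
    """A condition header cell could not be parsed into a descriptor."""

    def __init__(self, message: str, raw_label: str):
        super().__init__(f"{message} (label: {raw_label!r})")
        self.raw_label = raw_label


class ExportFormatError(PerturbScreenError):
    """Malformed data cell/row in a device export; carries row/column coordinates."""

    def __init__(self, message: str, row: int | None = None, column: int | None = None):
        loc = ""
        if row is not None:
            loc += f" at row {row}"
        if column is not None:
            loc += f", column {column}"
        super().__init__(message + loc)
        self.row = row
        self.column = column


class ReplicateError(PerturbScreenError):
    """Replicate screens disagree on time grid or descriptor set."""


class StoreError(PerturbScreenError):
    """Hierarchical store file unreadable or of an incompatible version."""


class ControlError(PerturbScreenError):
    """No control condition could be identified."""


class CategorizationError(PerturbScreenError):
    """Experiment layout inconsistent with every known experiment type."""


class NormalizationError(PerturbScreenError):
    """Control read-out unusable (zero/negative) at some time point."""


class ValidationError(PerturbScreenError):
    """Invalid argument combination (e.g. ZIP requested for a genetic-chemical screen)."""
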