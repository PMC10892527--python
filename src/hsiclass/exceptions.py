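"""Exception hierarchy shared across the package."""


class HsiError(Exception):
    """Base class for all package-specific errors."""


class EnviFormatError(HsiError, ValueError):
    """Malformed or inconsistent ENVI header / data pair."""


class SizeError(HsiError, ValueError):
    """A requested window or shape does not fit the data."""


class DegeneracyError(HsiError, ValueError):
    """The input carries no usable variance (e.g. a constant cube)."""


class EmptyDatasetError(HsiError, ValueError):
    """An operation received zero usable samples."""


class StratificationError(HsiError, ValueError):
    """A stratified partition cannot be formed (class too small)."""


class DivergenceError(HsiError, RuntimeError):
    """Training produced a non-finite loss."""

    def __init__(self, epoch: int, message: str | None = None):
        self.epoch = epoch
        super().__init__(message or f"non-finite loss at epoch {epoch}")
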