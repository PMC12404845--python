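"""Exception hierarchy shared across the pipeline."""

from __future__ import annotations


class ScreenerError(Exception):
    """Base class for all picoscreen errors."""


class ConfigurationError(ScreenerError):
    """Invalid configuration: unknown format, missing criteria dimension, bad profile."""


class RecordParseError(ScreenerError):
    """A bibliographic entry could not be parsed; carries the entry index."""

    def __init__(self, message: str, index: int | None = None):
        super().__init__(message)
        self.index = index


class UnreadablePageError(ScreenerError):
    """Image-only page(s) encountered with no OCR contract supplied."""

    def __init__(self, message: str, pages: list[int] | None = None):
        super().__init__(message)
        self.pages = pages or []


class MalformedResponseError(ScreenerError):
    """Backend response could not be parsed/validated; carries the raw text."""

    def __init__(self, message: str, raw: str = ""):
        super().__init__(message)
        self.raw = raw


class TransportError(ScreenerError):
    """Retryable transport-level backend failure."""


class BackendUnavailableError(ScreenerError):
    """All retries exhausted against a backend."""

    def __init__(self, message: str, partial_trace: list | None = None):
        super().__init__(message)
        self.partial_trace = partial_trace or []


class AccountingError(ScreenerError):
    """Flow/coverage accounting mismatch; carries the offending record ids."""

    def __init__(self, message: str, record_ids: list[str] | None = None):
        super().__init__(message)
        self.record_ids = record_ids or []
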