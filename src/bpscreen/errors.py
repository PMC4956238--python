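"""Structured error classes shared across the pipeline."""


class BpscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(BpscreenError):
    """An item-spec, weight-spec or run configuration is inconsistent."""


class RangeError(BpscreenError):
    """A raw item value lies outside its scale bounds."""

    def __init__(self, item_id, value, lo, hi):
        self.item_id = item_id
        self.value = value
        super().__init__(
            f"item {item_id}: value {value!r} outside scale [{lo}, {hi}]"
        )


class InvalidRecordError(BpscreenError):
    """A questionnaire record failed validation (too many missing, out of range)."""

    def __init__(self, participant_id, reason):
        self.participant_id = participant_id
        self.reason = reason
        super().__init__(f"record {participant_id!r}: {reason}")


class DegenerateDataError(BpscreenError):
    """Input lacks the structure a statistic needs (single class, empty, zero variance)."""


class ParseError(BpscreenError):
    """A delimited input file violates the documented schema."""

    def __init__(self, path, message, row=None, column=None):
        self.path = path
        self.row = row
        self.column = column
        loc = "".join(
            [f", row {row}" if row is not None else "",
             f", column {column!r}" if column is not None else ""]
        )
        super().__init__(f"{path}{loc}: {message}")
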