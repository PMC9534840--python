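"""Structured exceptions raised across the pipeline."""


class EgolayersError(Exception):
    """Base class for all package errors."""


class ParseError(EgolayersError):
    """A tabular input failed to parse; names the offending row and field."""

    def __init__(self, message: str, row=None, field=None):
        self.row = row
        self.field = field
        detail = message
        if row is not None:
            detail += f" (row {row}"
            detail += f", field {field!r})" if field is not None else ")"
        super().__init__(detail)


class ReferentialIntegrityError(ParseError):
    """An event references a follow_id absent from the follows table."""


class CrossGroupDyadError(EgolayersError):
    """A grooming dyad spans two groups, which the study design forbids."""


class DegenerateNetworkError(EgolayersError):
    """All weights equal: the normalised-cost transform is undefined."""


class InsufficientDataError(EgolayersError):
    """Too few alters (or follows) to attempt a fit."""


class ConfigError(EgolayersError):
    """Invalid or inconsistent configuration."""
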