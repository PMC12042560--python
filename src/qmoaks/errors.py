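"""Exception hierarchy shared across the package.

``ValidationError`` covers malformed inputs and configuration (CLI exit
code 2); ``DegenerateDataError`` signals statistics that are undefined on
the data supplied (zero variance, empty rows) and is distinct from a NaN
result so callers can render "n/a" deliberately.
"""


class QmoaksError(Exception):
    """Base class for all package errors."""


class ValidationError(QmoaksError):
    """Input file, record, or configuration failed validation."""


class DegenerateDataError(QmoaksError):
    """A statistic is undefined on this data (e.g. zero variance)."""
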