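"""Exception hierarchy shared across the package."""


class MR2SError(Exception):
    """Base class for all package errors."""


class DomainError(MR2SError, ValueError):
    """An argument lies outside its mathematical domain (names the offending field)."""


class FormatError(MR2SError, ValueError):
    """A file or record violates the expected format contract."""


class InsufficientDataError(MR2SError, ValueError):
    """Too few instruments/estimates for the requested operation."""


class DegenerateInstrumentError(DomainError):
    """An instrument with zero exposure effect cannot anchor a ratio estimate."""


class DegenerateVariantError(DomainError):
    """A dosage column is constant, so no correlation is defined for it."""


class VariantLookupError(MR2SError, KeyError):
    """A variant id is missing from a table that must contain it."""
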