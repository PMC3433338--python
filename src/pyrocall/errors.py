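"""Exception hierarchy shared across the package."""

from __future__ import annotations


class PyrocallError(Exception):
    """Base class for all package errors."""


class InvalidInputError(PyrocallError, ValueError):
    """An argument violates a documented precondition."""


class CatalogValidationError(PyrocallError, ValueError):
    """A catalog file or assay definition failed validation.

    Carries the full list of failures so a user can fix them in one pass.
    """

    def __init__(self, failures: list[str]):
        self.failures = list(failures)
        super().__init__(
            "catalog validation failed:\n" + "\n".join(f"  - {f}" for f in self.failures)
        )


class ParseError(PyrocallError, ValueError):
    """A pyrogram TSV file could not be parsed; ``line`` is 1-based."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        where = f" (line {line})" if line is not None else ""
        super().__init__(f"{message}{where}")


class DegenerateSignalError(PyrocallError):
    """The pyrogram carries no usable signal (e.g. reference mean B = 0)."""


class UndefinedFractionError(PyrocallError):
    """Wildtype and mutant expected patterns coincide; the fraction is unidentifiable."""


class UnknownAssayError(PyrocallError, KeyError):
    """Requested assay name is not in the catalog."""


class UnknownVariantError(PyrocallError, KeyError):
    """Requested variant id is not in the assay's catalog."""
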