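"""Exception hierarchy.

All package errors derive from :class:`ChemmixError` so callers (and the
CLI) can distinguish classes of failure: file-format problems, chemical
resolution problems, contract violations (e.g. the 2-4 chemical limit)
and numeric domain errors.
"""


class ChemmixError(Exception):
    """Base class for all chemmix errors."""


class FormatError(ChemmixError):
    """An input file is malformed (bad header, bad field, empty file)."""


class ChemicalNotFoundError(ChemmixError):
    """A chemical query could not be resolved to a chemical identifier."""

    def __init__(self, query: str, message: str | None = None):
        self.query = query
        super().__init__(message or f"chemical not found: {query!r}")


class AmbiguousAliasError(ChemmixError):
    """An alias maps to more than one chemical identifier."""

    def __init__(self, alias: str, candidates):
        self.alias = alias
        self.candidates = sorted(candidates)
        super().__init__(
            f"alias {alias!r} is ambiguous; candidates: {', '.join(self.candidates)}"
        )


class ContractError(ChemmixError):
    """A call violates an interface contract (e.g. set-count limits)."""


class DomainError(ChemmixError):
    """A numeric argument is outside its mathematical domain."""


class ConfigError(ChemmixError):
    """A fixture configuration is invalid or infeasible."""
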