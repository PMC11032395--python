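"""Exception hierarchy shared across the package."""


class MetaprofError(Exception):
    """Base class for all package-specific errors."""


class TaxonomyError(MetaprofError):
    """Structural problem in a taxonomy (missing root, dangling parent, cycle)."""


class TaxonNotFoundError(TaxonomyError, KeyError):
    """A taxon id could not be resolved, directly or via the merged-id map."""

    def __init__(self, taxon_id: str):
        super().__init__(taxon_id)
        self.taxon_id = taxon_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unknown taxon id: {self.taxon_id!r}"


class ParseError(MetaprofError):
    """Malformed input file; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class ValidationError(MetaprofError):
    """An invariant on a domain object was violated."""


class UnsupportedParameterError(MetaprofError, ValueError):
    """A parameter value outside the supported range (e.g. f < 0.5)."""
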