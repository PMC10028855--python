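"""Exception hierarchy shared across modules."""


class SigcompassError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SigcompassError):
    """Invalid option, unknown filter field, or malformed run configuration."""


class CatalogLookupError(SigcompassError, KeyError):
    """Requested signature name absent from the catalog."""

    def __init__(self, name: str, suggestions: list[str] | None = None):
        self.name = name
        self.suggestions = suggestions or []
        msg = f"signature {name!r} not found in catalog"
        if self.suggestions:
            msg += f"; nearest matches: {', '.join(self.suggestions)}"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its args otherwise
        return self.args[0]


class SignatureValidationError(SigcompassError):
    """A signature definition failed one or more inclusion criteria."""

    def __init__(self, report):
        self.report = report
        super().__init__("invalid signature definition:\n" + report.summary())


class DuplicateSignatureError(SigcompassError):
    """Registering a name already present in the catalog."""


class FormatError(SigcompassError):
    """Malformed input file (parse failures, dimension mismatches)."""


class UnsupportedConversionError(SigcompassError):
    """No defined path between two expression metrics."""


class AlignmentError(SigcompassError):
    """Observation ids of a score vector do not align with the dataset."""


class CoverageError(SigcompassError):
    """Too few signature genes present in the dataset to score."""


class EmptySelectionError(SigcompassError):
    """A catalog filter matched no scoreable signature."""


class GenesUnavailableError(SigcompassError):
    """Signature is metadata-only (gene list not packaged)."""
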