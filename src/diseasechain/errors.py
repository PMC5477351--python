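"""Exception hierarchy shared across the package."""


class DiseaseChainError(Exception):
    """Base class for all package errors."""


class UnknownIdentifierError(DiseaseChainError, KeyError):
    """An id was referenced that is not present in the ontology."""

    def __init__(self, kind: str, identifier: str):
        super().__init__(f"unknown {kind} id: {identifier!r}")
        self.kind = kind
        self.identifier = identifier


class ArgumentError(DiseaseChainError, ValueError):
    """An operation was called with inconsistent arguments."""


class MissingRuleError(DiseaseChainError, LookupError):
    """No conversion rule covers the requested tuple."""


class OutOfRangeError(DiseaseChainError, ValueError):
    """A magnitude falls in no interval of the matching rule."""


class UnitMismatchError(DiseaseChainError, ValueError):
    """Datum unit differs from the rule's unit; no silent conversion."""


class RuleTableError(DiseaseChainError, ValueError):
    """A rule table violates its own consistency constraints."""


class FormatError(DiseaseChainError, ValueError):
    """Malformed serialized input (TSV or RDF)."""


class InvalidOntologyError(DiseaseChainError, ValueError):
    """An operation requiring a valid ontology received findings."""

    def __init__(self, report):
        super().__init__(f"ontology failed validation with {len(report)} finding(s)")
        self.report = report


class ConfigError(DiseaseChainError, ValueError):
    """Infeasible or contradictory configuration."""
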