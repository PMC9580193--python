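"""Exception hierarchy for vaxalign."""

from __future__ import annotations


class VaxalignError(Exception):
    """Base class for all vaxalign errors."""


class OntologyError(VaxalignError):
    """Base class for ontology model errors."""


class ValidationError(OntologyError):
    """Referential-integrity or structural violation in an ontology or table."""


class CycleError(ValidationError):
    """A cycle among parent links; carries the offending class ids."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("cycle in parent links: " + " -> ".join(self.cycle))


class UnknownIdentifierError(OntologyError):
    """A class or property identifier that is not declared in the ontology."""

    def __init__(self, identifier: str, kind: str = "identifier"):
        self.identifier = identifier
        super().__init__(f"unknown {kind}: {identifier!r}")


class OntologyParseError(OntologyError):
    """Malformed ontology file; message carries record context."""


class ConfigurationError(VaxalignError):
    """Invalid method name, threshold, or configuration value."""
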