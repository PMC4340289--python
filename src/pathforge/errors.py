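"""Exception hierarchy shared by all pathforge modules.

Every error carries a short machine-readable ``code`` so that the CLI can
emit structured, module-qualified error reports.
"""

from __future__ import annotations


class PathforgeError(Exception):
    """Base class for all toolkit errors."""

    code = "pathforge.error"

    def __init__(self, message: str, *, details: object = None):
        super().__init__(message)
        self.details = details

    def report(self) -> dict:
        return {"code": self.code, "message": str(self), "details": self.details}


class ReferenceResolutionError(PathforgeError):
    """An id-valued field does not resolve to an existing record."""

    code = "metamodel.unresolved-reference"


class DuplicateIdError(PathforgeError):
    code = "metamodel.duplicate-id"


class AcyclicityError(PathforgeError):
    """Control-flow edges form a directed cycle; details holds a witness."""

    code = "metamodel.cycle"


class ValidationRefusedError(PathforgeError):
    """An operation that requires a valid pathway was given an invalid one."""

    code = "metamodel.validation-refused"


class EnumerationError(PathforgeError):
    code = "derivation.unknown-kind"


class ConfigurationError(PathforgeError):
    """An attribute schema or other config record is missing or malformed."""

    code = "derivation.configuration"


class KindMismatchError(PathforgeError):
    code = "derivation.kind-mismatch"


class CompositionError(PathforgeError):
    """Pathway composition rejected (incomplete activity, bad assignment)."""

    code = "derivation.composition"


class XmlParseError(PathforgeError):
    code = "hl7_io.parse"


class VersionError(PathforgeError):
    code = "hl7_io.version"


class MappingIntegrityError(PathforgeError):
    """A mapping entry references a concept absent from its graph."""

    code = "mapping.integrity"


class QueryError(PathforgeError):
    code = "mapping.query"


class UnresolvedChoiceError(PathforgeError):
    """Strict resolution with pending elements left uncovered."""

    code = "deployment.unresolved-choice"


class InvalidChoiceError(PathforgeError):
    code = "deployment.invalid-choice"


class CoverageError(PathforgeError):
    """Unmapped elements block deployment (fail-closed default)."""

    code = "deployment.coverage"


class DialectGapError(PathforgeError):
    """A chosen representation option has no template for the dialect."""

    code = "deployment.dialect-gap"
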