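"""Exception hierarchy.

Contract violations (``ContractError`` subclasses) map to CLI exit code 4,
format/parse/data problems to exit code 3.
"""


class MolkitError(Exception):
    """Base class for all molkit errors."""


class FormatError(MolkitError):
    """Malformed or unsupported file content."""


class ParseError(MolkitError):
    """Selection-expression parse failure, with character position."""

    def __init__(self, message: str, pos: int | None = None):
        self.pos = pos
        if pos is not None:
            message = f"{message} (at position {pos})"
        super().__init__(message)


class EmptySelectionError(MolkitError):
    """A selection expression matched no atoms."""


class ContractError(MolkitError):
    """Violation of a selection-kind access contract."""


class OverlapError(ContractError):
    """Attempt to create a MutableParallel selection overlapping a live one."""


class StaleSelectionError(ContractError):
    """BuilderSerial selection used after a structural edit invalidated it."""


class ConsumedSelectionError(ContractError):
    """Selection used after fragmentation consumed it."""


class AccessKindError(ContractError):
    """Operation not permitted for the selection's access kind."""


class RegistryError(ContractError):
    """Internal inconsistency of the used-index registry (library bug surface)."""
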