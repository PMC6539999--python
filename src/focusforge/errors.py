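"""Exception hierarchy for the design pipeline."""


class FocusForgeError(Exception):
    """Base class for all package errors."""


class DefinitionError(FocusForgeError):
    """A template or constraint definition references unknown atoms or is malformed."""


class TopologyError(FocusForgeError):
    """Bond graph is disconnected or a dihedral path is not bonded in sequence."""


class SamplingExhaustedError(FocusForgeError):
    """The chi grid cannot yield the requested number of distinct clash-free conformers."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"requested {requested} conformers but only {achievable} distinct "
            f"clash-free chi vectors are achievable"
        )


class ParseError(FocusForgeError):
    """Malformed structure file; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class AnchorError(FocusForgeError):
    """The configured substrate anchor residue is missing or incomplete."""


class UnderdeterminedError(FocusForgeError):
    """Fewer than three corresponding atoms for a rigid superposition."""


class ConfigurationError(FocusForgeError):
    """Inconsistent run configuration (e.g. an allowed identity with no rotamers)."""


class ScoringError(FocusForgeError):
    """A residue required for scoring is missing atoms."""


class SequenceError(FocusForgeError):
    """A variant references a position absent from the scaffold."""


class ComparabilityError(FocusForgeError):
    """Models cannot be compared (e.g. inconsistent ligand atom sets)."""


class CompletenessError(FocusForgeError):
    """A design model lacks a required designable position."""


class CurationError(FocusForgeError):
    """Curation emptied a position's allowed identity set."""

    def __init__(self, position: int):
        self.position = position
        super().__init__(f"curation emptied the allowed set at position {position}")


class SpecError(FocusForgeError):
    """A library specification is invalid (e.g. empty identity set)."""


class SizeGuardError(FocusForgeError):
    """Requested enumeration exceeds the configured diversity cap."""


class PlacementError(FocusForgeError):
    """Fixture geometry request is infeasible."""
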