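"""Exception hierarchy for the UNF toolkit.

All errors raised on purpose by this package derive from :class:`UnfError`
so callers (and the CLI) can distinguish domain failures from bugs.
"""


class UnfError(Exception):
    """Base class for all UNF toolkit errors."""


class LookupIdError(UnfError):
    """An object ID could not be resolved (unknown, sentinel, or duplicated)."""


class TopologyError(UnfError):
    """A strand/chain linked list is broken: cycle, dead end, or dangling link."""


class ContainerError(UnfError):
    """The hybrid JSON-plus-attachments container is malformed."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (byte offset {offset})")
        self.offset = offset


class IntegrityError(UnfError):
    """An embedded payload does not match its recorded MD5 hash."""

    def __init__(self, message: str, file_id: int | None = None):
        super().__init__(message)
        self.file_id = file_id


class MissingAttachmentError(UnfError):
    """An external file is marked as included but no attachment carries it."""


class NotIncludedError(UnfError):
    """The requested external file is referenced on disk, not embedded."""


class ReferenceError_(UnfError):
    """An attachment or record points at an ID the document does not define."""


class GeometryError(UnfError):
    """Degenerate geometry: collinear ring, zero projection, unknown lattice."""


class UnplaceableNucleotideError(UnfError):
    """A nucleotide has neither explicit positions nor a referencing lattice cell."""


class AmbiguousPlacementError(UnfError):
    """A nucleotide is referenced by more than one lattice cell."""


class CadnanoError(UnfError):
    """Invalid Cadnano design content (dangling pointers, conflicting skip/loop)."""


class DegeneratePathError(CadnanoError):
    """A routed path is too short (or not circular) for the requested operation."""


class IncompleteResidueError(UnfError):
    """An atomistic residue lacks the atoms needed for coarse-graining."""


class ChainTypingError(UnfError):
    """An atomistic chain mixes nucleic and amino residues."""


class OxDnaError(UnfError):
    """Malformed or inconsistent oxDNA topology/configuration input."""


class FixtureSpecError(UnfError):
    """A toy-design specification is infeasible or out of bounds."""
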