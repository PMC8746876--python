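"""UNF v1.0 domain model.

The Unified Nanotechnology Format describes DNA/RNA/protein nanostructures
at a coarse-grained level. A document combines four categories of data:

* general file information (version, units, author, external file refs),
* design data (origami lattices of virtual helices made of cells),
* structural data (nucleic acid strands, amino acid chains, molecules),
* annotations (groups, modifications, connections, comments, misc).

Every object carries a document-wide unique non-negative integer ID; the
sentinel ``-1`` means "none". Nucleotides store their spatial state as a
four-vector frame: backbone center, nucleobase center, base-plane normal
(the stacking direction, oxDNA's ``a3``) and hydrogen-face direction
(the Watson-Crick edge, oxDNA's ``a1``). Amino acids are alpha-carbon beads.

This module defines the types, a validator, and topology helpers. It does
no file I/O (see :mod:`unf.io`) and no geometry (see :mod:`unf.geometry`).
"""

from __future__ import annotations

import datetime
import math
import re
from dataclasses import dataclass, field
from typing import Any, Iterator

from .errors import LookupIdError, TopologyError

NONE_ID = -1

UNF_VERSION = "1.0"

LATTICE_TYPES = ("square", "honeycomb")
CELL_TYPES = ("normal", "insertion", "deletion")
NA_TYPES = ("DNA", "RNA")
BASES = ("A", "C", "G", "T", "U", "N")

_COLOR_RE = re.compile(r"^#[0-9A-F]{6}$")
_MD5_RE = re.compile(r"^[0-9a-f]{32}$")

Vec3 = tuple[float, float, float]


def _vec3(x) -> Vec3:
    a, b, c = x
    return (float(a), float(b), float(c))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class NucleotideFrame:
    """Spatial frame of one nucleotide: two centers and two unit directions.

    ``baseNormal`` is the normal of the nucleobase plane (stacking direction);
    ``hydrogenFaceDir`` points toward the Watson-Crick hydrogen-bonding edge.
    Both must be unit length and mutually orthogonal.
    """

    backboneCenter: Vec3
    nucleobaseCenter: Vec3
    baseNormal: Vec3
    hydrogenFaceDir: Vec3

    def __post_init__(self):
        self.backboneCenter = _vec3(self.backboneCenter)
        self.nucleobaseCenter = _vec3(self.nucleobaseCenter)
        self.baseNormal = _vec3(self.baseNormal)
        self.hydrogenFaceDir = _vec3(self.hydrogenFaceDir)


@dataclass
class ExternalFile:
    id: int
    path: str
    type: str = "pdb"
    isIncluded: bool = False
    hash: str = ""


@dataclass
class Cell:
    """One base-pair position along a virtual helix.

    ``fiveToThreeNts`` lists nucleotide IDs of the strand crossing the cell
    in the 5'->3' direction of increasing cell index; ``threeToFiveNts`` the
    complementary strand. Deletion cells reference no nucleotides; an
    insertion of length n references n+1 nucleotides per occupied array.
    Nucleotides inside each array are listed in their own strand's 5'->3'
    order.
    """

    id: int
    index: int
    type: str = "normal"
    fiveToThreeNts: list[int] = field(default_factory=list)
    threeToFiveNts: list[int] = field(default_factory=list)


@dataclass
class VirtualHelix:
    id: int
    row: int
    col: int
    designNumber: int = NONE_ID
    initialAngle: float = 0.0
    cells: list[Cell] = field(default_factory=list)


@dataclass
class Lattice:
    id: int
    name: str = ""
    type: str = "square"
    position: Vec3 = (0.0, 0.0, 0.0)
    orientation: Vec3 = (0.0, 0.0, 0.0)  # intrinsic X-Y-Z Euler angles
    virtualHelices: list[VirtualHelix] = field(default_factory=list)


@dataclass
class Nucleotide:
    id: int
    base: str = "N"
    pair: int = NONE_ID
    prev: int = NONE_ID
    next: int = NONE_ID
    pdbResidueId: int = NONE_ID
    altPositions: list[NucleotideFrame] = field(default_factory=list)


@dataclass
class NaStrand:
    id: int
    name: str = ""
    naType: str = "DNA"
    isScaffold: bool = False
    color: str = "#FFFFFF"
    fivePrimeId: int = NONE_ID
    threePrimeId: int = NONE_ID
    chainName: str = ""
    pdbFileId: int = NONE_ID
    nucleotides: list[Nucleotide] = field(default_factory=list)


@dataclass
class AminoAcid:
    id: int
    code: str = "X"  # one-letter residue code
    prev: int = NONE_ID
    next: int = NONE_ID
    pdbResidueId: int = NONE_ID
    position: Vec3 = (0.0, 0.0, 0.0)  # alpha carbon


@dataclass
class AaChain:
    id: int
    chainName: str = ""
    color: str = "#FFFFFF"
    nTermId: int = NONE_ID
    cTermId: int = NONE_ID
    pdbFileId: int = NONE_ID
    aminoAcids: list[AminoAcid] = field(default_factory=list)


@dataclass
class Structure:
    id: int
    name: str = ""
    naStrands: list[NaStrand] = field(default_factory=list)
    aaChains: list[AaChain] = field(default_factory=list)


@dataclass
class LigandAtom:
    element: str
    name: str
    position: Vec3


@dataclass
class Ligand:
    id: int
    name: str = ""
    atoms: list[LigandAtom] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)  # atom indices


@dataclass
class PlacedMolecule:
    """A nanostructure or other molecule referencing an external file."""

    id: int
    name: str = ""
    externalFileId: int = NONE_ID
    position: Vec3 = (0.0, 0.0, 0.0)
    orientation: Vec3 = (0.0, 0.0, 0.0)


@dataclass
class MoleculeSet:
    ligands: list[Ligand] = field(default_factory=list)
    nanostructures: list[PlacedMolecule] = field(default_factory=list)
    others: list[PlacedMolecule] = field(default_factory=list)


@dataclass
class Group:
    id: int
    name: str = ""
    includedObjects: list[int] = field(default_factory=list)


@dataclass
class Modification:
    location: list[int] = field(default_factory=list)
    code: str = ""


@dataclass
class Connection:
    id: int
    includedObjects: list[int] = field(default_factory=list)
    interaction: str = ""


@dataclass
class Comment:
    id: int
    objectId: int = NONE_ID
    content: str = ""


@dataclass
class UnfDocument:
    """Root container of a UNF file."""

    version: str = UNF_VERSION
    lengthUnits: str = "A"
    angularUnits: str = "deg"
    name: str = ""
    author: str = ""
    creationDate: str = ""
    doi: str = ""
    externalFiles: list[ExternalFile] = field(default_factory=list)
    lattices: list[Lattice] = field(default_factory=list)
    structures: list[Structure] = field(default_factory=list)
    molecules: MoleculeSet = field(default_factory=MoleculeSet)
    groups: list[Group] = field(default_factory=list)
    modifications: list[Modification] = field(default_factory=list)
    connections: list[Connection] = field(default_factory=list)
    comments: list[Comment] = field(default_factory=list)
    simulationBox: Vec3 | None = None
    misc: dict[str, Any] = field(default_factory=dict)

    _next_id: int = field(default=0, repr=False, compare=False)
    _queued_attachments: list = field(default_factory=list, repr=False, compare=False)

    def allocate_id(self) -> int:
        """Return a fresh document-wide unique ID."""
        nid = self._next_id
        self._next_id = nid + 1
        return nid

    def bump_id_floor(self) -> None:
        """Ensure future :meth:`allocate_id` calls never collide with
        existing IDs (used after parsing a document)."""
        high = NONE_ID
        for _, obj in iter_objects(self):
            high = max(high, obj.id)
        self._next_id = max(self._next_id, high + 1)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def new_document(name: str, author: str) -> UnfDocument:
    """Create an empty, valid UNF v1.0 document.

    Defaults: Angstrom length units, degrees for angles, creation date set
    to the current UTC time in ISO-8601, all collections empty, and an
    independent ID registry starting at zero.
    """
    now = datetime.datetime.now(datetime.timezone.utc)
    return UnfDocument(
        name=name,
        author=author,
        creationDate=now.strftime("%Y-%m-%dT%H:%M:%SZ"),
    )


def iter_objects(doc: UnfDocument) -> Iterator[tuple[str, Any]]:
    """Yield every identified object in the document as ``(kind, object)``."""
    for f in doc.externalFiles:
        yield "externalFile", f
    for lat in doc.lattices:
        yield "lattice", lat
        for vh in lat.virtualHelices:
            yield "virtualHelix", vh
            for cell in vh.cells:
                yield "cell", cell
    for st in doc.structures:
        yield "structure", st
        for strand in st.naStrands:
            yield "naStrand", strand
            for nt in strand.nucleotides:
                yield "nucleotide", nt
        for chain in st.aaChains:
            yield "aaChain", chain
            for aa in chain.aminoAcids:
                yield "aminoAcid", aa
    for lig in doc.molecules.ligands:
        yield "ligand", lig
    for ns in doc.molecules.nanostructures:
        yield "nanostructure", ns
    for other in doc.molecules.others:
        yield "other", other
    for g in doc.groups:
        yield "group", g
    for c in doc.connections:
        yield "connection", c
    for c in doc.comments:
        yield "comment", c


def build_index(doc: UnfDocument) -> dict[int, tuple[str, Any]]:
    """Map every ID to its ``(kind, object)``.

    Raises :class:`LookupIdError` if two objects share an ID.
    """
    index: dict[int, tuple[str, Any]] = {}
    for kind, obj in iter_objects(doc):
        if obj.id in index:
            raise LookupIdError(
                f"duplicate id {obj.id}: {index[obj.id][0]} and {kind}"
            )
        index[obj.id] = (kind, obj)
    return index


def resolve_object(doc: UnfDocument, object_id: int) -> tuple[str, Any]:
    """Resolve an ID to its unique object, returning ``(kind, object)``.

    The sentinel ``-1`` is not resolvable and raises :class:`LookupIdError`,
    as does an unknown or duplicated ID.
    """
    if object_id < 0:
        raise LookupIdError(f"id {object_id} is a sentinel, not a resolvable id")
    index = build_index(doc)
    if object_id not in index:
        raise LookupIdError(f"unknown id {object_id}")
    return index[object_id]


def walk_strand(strand: NaStrand) -> list[Nucleotide]:
    """Walk a strand 5'->3' following ``next`` pointers.

    Raises :class:`TopologyError` on a cycle, a dead end that is not the
    recorded 3' terminus, or a walk that misses nucleotides.
    """
    by_id = {nt.id: nt for nt in strand.nucleotides}
    if not strand.nucleotides:
        return []
    if strand.fivePrimeId not in by_id:
        raise TopologyError(
            f"strand {strand.id}: fivePrimeId {strand.fivePrimeId} is not one of its nucleotides"
        )
    seen: set[int] = set()
    order: list[Nucleotide] = []
    cur = by_id[strand.fivePrimeId]
    while True:
        if cur.id in seen:
            raise TopologyError(f"strand {strand.id}: next-chain revisits nucleotide {cur.id}")
        seen.add(cur.id)
        order.append(cur)
        if cur.next == NONE_ID:
            break
        if cur.next not in by_id:
            raise TopologyError(
                f"strand {strand.id}: nucleotide {cur.id} points outside the strand (next={cur.next})"
            )
        cur = by_id[cur.next]
    if order[-1].id != strand.threePrimeId:
        raise TopologyError(
            f"strand {strand.id}: walk ends at {order[-1].id}, not threePrimeId {strand.threePrimeId}"
        )
    if len(order) != len(strand.nucleotides):
        raise TopologyError(
            f"strand {strand.id}: walk visits {len(order)} of {len(strand.nucleotides)} nucleotides"
        )
    return order


def walk_chain(chain: AaChain) -> list[AminoAcid]:
    """Walk an amino acid chain N-terminus to C-terminus."""
    by_id = {aa.id: aa for aa in chain.aminoAcids}
    if not chain.aminoAcids:
        return []
    if chain.nTermId not in by_id:
        raise TopologyError(f"chain {chain.id}: nTermId {chain.nTermId} is not one of its residues")
    seen: set[int] = set()
    order: list[AminoAcid] = []
    cur = by_id[chain.nTermId]
    while True:
        if cur.id in seen:
            raise TopologyError(f"chain {chain.id}: next-chain revisits residue {cur.id}")
        seen.add(cur.id)
        order.append(cur)
        if cur.next == NONE_ID:
            break
        if cur.next not in by_id:
            raise TopologyError(f"chain {chain.id}: residue {cur.id} points outside the chain")
        cur = by_id[cur.next]
    if order[-1].id != chain.cTermId or len(order) != len(chain.aminoAcids):
        raise TopologyError(f"chain {chain.id}: N->C walk does not cover the chain")
    return order


def strand_sequence(strand: NaStrand, doc: UnfDocument | None = None) -> str:
    """Return the strand's base letters in 5'->3' order."""
    return "".join(nt.base for nt in walk_strand(strand))


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class Finding:
    severity: str  # "error" | "warning"
    objectId: int
    message: str


def _unit(v: Vec3) -> float:
    return math.sqrt(v[0] * v[0] + v[1] * v[1] + v[2] * v[2])


def _dot(a: Vec3, b: Vec3) -> float:
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


def validate(doc: UnfDocument) -> list[Finding]:
    """Check every document invariant; problems become report entries.

    Returns an empty list iff the document is fully consistent. Never
    raises: duplicate IDs, broken references and invalid topologies are
    reported as findings with the offending object's ID.
    """
    findings: list[Finding] = []
    err = lambda oid, msg: findings.append(Finding("error", oid, msg))
    warn = lambda oid, msg: findings.append(Finding("warning", oid, msg))

    # --- ID uniqueness
    index: dict[int, tuple[str, Any]] = {}
    for kind, obj in iter_objects(doc):
        if not isinstance(obj.id, int) or obj.id < 0:
            err(obj.id if isinstance(obj.id, int) else NONE_ID,
                f"{kind} has invalid id {obj.id!r} (must be a non-negative integer)")
            continue
        if obj.id in index:
            err(obj.id, f"duplicate id: {index[obj.id][0]} and {kind} share id {obj.id}")
        else:
            index[obj.id] = (kind, obj)

    def check_ref(owner_id: int, ref: int, expect: tuple[str, ...] | None, what: str):
        if ref == NONE_ID:
            return
        if ref not in index:
            err(owner_id, f"{what} references unknown id {ref}")
        elif expect is not None and index[ref][0] not in expect:
            err(owner_id, f"{what} references id {ref} of kind {index[ref][0]}, expected {expect}")

    # --- header
    if not _MD5_RE.match("0" * 32):  # pragma: no cover - sanity of the regex itself
        raise AssertionError
    for f in doc.externalFiles:
        if f.hash and not _MD5_RE.match(f.hash):
            err(f.id, f"external file hash {f.hash!r} is not 32-char lowercase hex MD5")

    nucleotide_cells: dict[int, list[int]] = {}

    # --- lattices
    for lat in doc.lattices:
        if lat.type not in LATTICE_TYPES:
            err(lat.id, f"lattice type {lat.type!r} not in {LATTICE_TYPES}")
        seen_rc: dict[tuple[int, int], int] = {}
        for vh in lat.virtualHelices:
            rc = (vh.row, vh.col)
            if rc in seen_rc:
                err(vh.id, f"virtual helix (row,col)={rc} duplicated within lattice {lat.id}")
            else:
                seen_rc[rc] = vh.id
            for cell in vh.cells:
                if cell.type not in CELL_TYPES:
                    err(cell.id, f"cell type {cell.type!r} not in {CELL_TYPES}")
                    continue
                arrays = (cell.fiveToThreeNts, cell.threeToFiveNts)
                if cell.type == "deletion":
                    if cell.fiveToThreeNts or cell.threeToFiveNts:
                        err(cell.id, "deletion cell must not reference nucleotides")
                elif cell.type == "normal":
                    for arr in arrays:
                        if len(arr) > 1:
                            err(cell.id, f"normal cell references {len(arr)} nucleotides in one array")
                else:  # insertion
                    occupied = [a for a in arrays if a]
                    for arr in occupied:
                        if len(arr) < 2:
                            err(cell.id, "insertion cell array must hold n+1 >= 2 nucleotides")
                    if len(occupied) == 2 and len(occupied[0]) != len(occupied[1]):
                        err(cell.id, "insertion cell arrays differ in length")
                for arr in arrays:
                    for ntid in arr:
                        check_ref(cell.id, ntid, ("nucleotide",), "cell array")
                        nucleotide_cells.setdefault(ntid, []).append(cell.id)

    for ntid, cells in nucleotide_cells.items():
        if len(cells) > 1:
            err(ntid, f"nucleotide referenced by {len(cells)} cells: {cells}")

    # --- structures
    for st in doc.structures:
        for strand in st.naStrands:
            if strand.naType not in NA_TYPES:
                err(strand.id, f"naType {strand.naType!r} not in {NA_TYPES}")
            if strand.color and not _COLOR_RE.match(strand.color):
                warn(strand.id, f"color {strand.color!r} is not #RRGGBB uppercase hex")
            check_ref(strand.id, strand.pdbFileId, ("externalFile",), "strand pdbFileId")
            by_id = {nt.id: nt for nt in strand.nucleotides}
            for nt in strand.nucleotides:
                if nt.base not in BASES:
                    err(nt.id, f"base {nt.base!r} not in {BASES}")
                check_ref(nt.id, nt.pair, ("nucleotide",), "pair")
                check_ref(nt.id, nt.prev, ("nucleotide",), "prev")
                check_ref(nt.id, nt.next, ("nucleotide",), "next")
                # pair symmetry
                if nt.pair != NONE_ID and nt.pair in index:
                    other = index[nt.pair][1]
                    if getattr(other, "pair", NONE_ID) != nt.id:
                        err(nt.id, f"asymmetric pairing: {nt.id}.pair={nt.pair} "
                                   f"but {nt.pair}.pair={getattr(other, 'pair', NONE_ID)}")
                # prev/next mutual consistency (within the strand)
                if nt.next != NONE_ID and nt.next in by_id and by_id[nt.next].prev != nt.id:
                    err(nt.id, f"next/prev mismatch: {nt.id}.next={nt.next} "
                               f"but {nt.next}.prev={by_id[nt.next].prev}")
                for fr in nt.altPositions:
                    n1 = _unit(fr.baseNormal)
                    n2 = _unit(fr.hydrogenFaceDir)
                    if abs(n1 - 1.0) > 1e-6 or abs(n2 - 1.0) > 1e-6:
                        err(nt.id, f"frame direction vectors not unit length ({n1:.8f}, {n2:.8f})")
                    elif abs(_dot(fr.baseNormal, fr.hydrogenFaceDir)) > 1e-6:
                        err(nt.id, "frame baseNormal and hydrogenFaceDir not orthogonal")
            if strand.nucleotides:
                try:
                    walk_strand(strand)
                except TopologyError as e:
                    err(strand.id, str(e))
        for chain in st.aaChains:
            check_ref(chain.id, chain.pdbFileId, ("externalFile",), "chain pdbFileId")
            if chain.aminoAcids:
                try:
                    walk_chain(chain)
                except TopologyError as e:
                    err(chain.id, str(e))

    # --- molecules
    for lig in doc.molecules.ligands:
        natoms = len(lig.atoms)
        for a, b in lig.bonds:
            if not (0 <= a < natoms and 0 <= b < natoms):
                err(lig.id, f"ligand bond ({a},{b}) outside atom range 0..{natoms - 1}")
    for pm in doc.molecules.nanostructures + doc.molecules.others:
        check_ref(pm.id, pm.externalFileId, ("externalFile",), "molecule externalFileId")

    # --- annotations
    for g in doc.groups:
        for oid in g.includedObjects:
            check_ref(g.id, oid, None, f"group {g.name!r}")
    for c in doc.connections:
        for oid in c.includedObjects:
            check_ref(c.id, oid, None, "connection")
    for c in doc.comments:
        check_ref(c.id, c.objectId, None, "comment")
    for m in doc.modifications:
        for oid in m.location:
            check_ref(NONE_ID, oid, None, f"modification {m.code!r}")

    return findings
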