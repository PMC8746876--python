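"""Coarse-graining of atomistic structures (PDB/mmCIF) into UNF.

Each nucleic residue is reduced to the four-vector frame UNF stores:

* ``backboneCenter`` — unweighted mean of the present sugar-phosphate atoms,
* ``nucleobaseCenter`` — unweighted mean of the base atoms (ring plus
  exocyclic substituents),
* ``baseNormal`` (a3) — normal of the base plane from the summed cross
  products of the cyclically ordered ring atoms,
* ``hydrogenFaceDir`` (a1) — direction from the base center toward the
  Watson-Crick edge, projected perpendicular to a3.

Amino acids become alpha-carbon beads; non-water hetero residues become
explicit ligands (atoms plus bonds from CONECT records or a covalent-radius
distance heuristic); waters are dropped. Residues are assumed to be listed
5'->3' per nucleic chain and N->C per protein chain.

File parsing is delegated to gemmi; this module only owns the
coarse-graining itself.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from . import model
from .errors import ChainTypingError, GeometryError, IncompleteResidueError
from .model import NONE_ID, UnfDocument

log = logging.getLogger(__name__)

# --- residue / atom vocabularies -------------------------------------------

AMINO_ACID = "aminoAcid"
DNA_NUCLEOTIDE = "dnaNucleotide"
RNA_NUCLEOTIDE = "rnaNucleotide"
LIGAND = "ligand"
WATER = "water"
UNKNOWN = "unknown"

PURINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9")
PYRIMIDINE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
PURINE_WC_EDGE = ("N1", "C2", "C6")
PYRIMIDINE_WC_EDGE = ("N3", "C2", "C4")
BACKBONE_ATOMS = frozenset(
    {"P", "OP1", "OP2", "O5'", "C5'", "C4'", "O4'", "C3'", "O3'", "C2'", "C1'", "O2'"})

_AMINO_NAMES = frozenset("""
ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL
SEC PYL MSE
""".split())
_DNA_NAMES = frozenset({"DA", "DC", "DG", "DT", "DI"})
_RNA_NAMES = frozenset({"A", "C", "G", "U", "I"})
_WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "SEC": "U", "PYL": "O", "MSE": "M",
}

_BASE_LETTER = {"DA": "A", "DC": "C", "DG": "G", "DT": "T", "DI": "N",
                "A": "A", "C": "C", "G": "G", "U": "U", "I": "N"}

# covalent radii (Angstrom) for the bond-distance heuristic
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "FE": 1.32, "ZN": 1.22,
    "MG": 1.41, "NA": 1.66, "K": 2.03, "CA": 1.76, "MN": 1.39, "AU": 1.36,
}
BOND_TOLERANCE = 0.4  # Angstrom added on top of summed covalent radii


@dataclass
class ResidueAtom:
    name: str
    element: str
    position: tuple[float, float, float]


@dataclass
class ResidueRecord:
    chainId: str
    serial: int
    name: str
    atoms: list[ResidueAtom] = field(default_factory=list)
    isHetero: bool = False

    def atom(self, name: str) -> ResidueAtom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has(self, name: str) -> bool:
        return self.atom(name) is not None


def normalize_atom_name(name: str) -> str:
    """Canonicalize primed-atom spellings (``O5*`` -> ``O5'``)."""
    return name.strip().replace("*", "'")


# --- file reading (gemmi) ---------------------------------------------------

def _structure_to_residues(st: gemmi.Structure) -> list[ResidueRecord]:
    st.setup_entities()
    residues = []
    if len(st) == 0:
        return residues
    mdl = st[0]  # first model only
    for chain in mdl:
        for res in chain:
            rec = ResidueRecord(
                chainId=chain.name, serial=res.seqid.num, name=res.name.strip(),
                isHetero=(res.het_flag == "H"),
            )
            seen = set()
            for atom in res:
                if atom.altloc not in ("", "\0", "A"):
                    continue  # keep blank or "A" alternate locations only
                nm = normalize_atom_name(atom.name)
                if nm in seen:
                    continue
                seen.add(nm)
                rec.atoms.append(ResidueAtom(
                    name=nm, element=atom.element.name.upper(),
                    position=(atom.pos.x, atom.pos.y, atom.pos.z)))
            residues.append(rec)
    return residues


def residues_from_pdb_text(text: str) -> list[ResidueRecord]:
    return _structure_to_residues(gemmi.read_pdb_string(text))


def residues_from_file(path: str) -> list[ResidueRecord]:
    return _structure_to_residues(gemmi.read_structure(str(path)))


def conect_pairs_from_pdb_text(text: str) -> list[tuple[int, int]]:
    """Bonded atom-serial pairs from CONECT records."""
    pairs = []
    for line in text.splitlines():
        if not line.startswith("CONECT"):
            continue
        fields = [line[i:i + 5].strip() for i in range(6, len(line), 5)]
        serials = [int(f) for f in fields if f]
        for other in serials[1:]:
            a, b = sorted((serials[0], other))
            if (a, b) not in pairs:
                pairs.append((a, b))
    return pairs


# --- classification ----------------------------------------------------------

def classify_residue(res: ResidueRecord) -> str:
    """Classify a residue as amino acid, DNA/RNA nucleotide, water, ligand,
    or unknown.

    Nonstandard residues with sugar and base atoms are disambiguated by the
    ribose O2' atom: present means RNA, absent means DNA.
    """
    name = res.name.upper()
    if name in _WATER_NAMES:
        return WATER
    if name in _AMINO_NAMES:
        return AMINO_ACID
    has_sugar = res.has("C1'") and res.has("C4'")
    has_base_ring = sum(res.has(a) for a in PYRIMIDINE_RING) >= 3
    if name in _DNA_NAMES:
        # allow atom content to override a mislabeled ribonucleotide
        return RNA_NUCLEOTIDE if res.has("O2'") else DNA_NUCLEOTIDE
    if name in _RNA_NAMES:
        if has_sugar and not res.has("O2'"):
            return DNA_NUCLEOTIDE
        return RNA_NUCLEOTIDE
    if has_sugar and has_base_ring:
        return RNA_NUCLEOTIDE if res.has("O2'") else DNA_NUCLEOTIDE
    if res.has("CA") and res.has("N") and res.has("C"):
        return AMINO_ACID
    if res.isHetero:
        return LIGAND
    return UNKNOWN


def is_purine(res: ResidueRecord) -> bool:
    return res.has("N9") and res.has("C8")


def _ring_atoms(res: ResidueRecord) -> list[ResidueAtom]:
    order = PURINE_RING if is_purine(res) else PYRIMIDINE_RING
    return [res.atom(n) for n in order if res.has(n)]


def _base_atoms(res: ResidueRecord) -> list[ResidueAtom]:
    """Base = ring plus exocyclic substituents: every heavy atom that is not
    part of the sugar-phosphate backbone."""
    return [a for a in res.atoms
            if a.name not in BACKBONE_ATOMS and a.element not in ("H", "D")]


# --- frame construction ------------------------------------------------------

def base_normal(res: ResidueRecord) -> np.ndarray:
    """Unit normal of the nucleobase plane (stacking direction, a3).

    Computed as the normalized sum of cross products over the cyclically
    ordered ring atoms relative to the base center; the listed ring order
    fixes the sign.
    """
    ring = _ring_atoms(res)
    if len(ring) < 3:
        raise IncompleteResidueError(
            f"residue {res.name} {res.serial}: fewer than 3 ring atoms")
    pts = np.array([a.position for a in ring])
    com = np.array([a.position for a in _base_atoms(res)]).mean(axis=0)
    v = pts - com
    total = np.zeros(3)
    n = len(v)
    for i in range(n):
        total += np.cross(v[i], v[(i + 1) % n])
    norm = np.linalg.norm(total)
    if norm < 1e-9:
        raise GeometryError(
            f"residue {res.name} {res.serial}: degenerate (collinear) ring geometry")
    return total / norm


def hydrogen_face(res: ResidueRecord, a3: np.ndarray) -> np.ndarray:
    """Unit vector toward the Watson-Crick hydrogen-bonding edge (a1).

    Direction from the base center to the centroid of the WC-edge atoms,
    projected into the base plane so a1 is orthogonal to a3 by construction.
    """
    edge_names = PURINE_WC_EDGE if is_purine(res) else PYRIMIDINE_WC_EDGE
    edge = [res.atom(n) for n in edge_names if res.has(n)]
    if len(edge) < len(edge_names):
        raise IncompleteResidueError(
            f"residue {res.name} {res.serial}: missing Watson-Crick edge atoms")
    wc_mid = np.array([a.position for a in edge]).mean(axis=0)
    com = np.array([a.position for a in _base_atoms(res)]).mean(axis=0)
    d = wc_mid - com
    d = d - np.dot(d, a3) * a3
    norm = np.linalg.norm(d)
    if norm < 1e-9:
        raise GeometryError(
            f"residue {res.name} {res.serial}: WC edge projects to zero in the base plane")
    return d / norm


def nucleotide_frame_from_atoms(res: ResidueRecord) -> model.NucleotideFrame:
    """Full coarse-grained frame of one nucleic residue."""
    backbone = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    base = _base_atoms(res)
    if not backbone:
        raise IncompleteResidueError(
            f"residue {res.name} {res.serial}: no backbone atoms")
    if not base:
        raise IncompleteResidueError(
            f"residue {res.name} {res.serial}: no base atoms")
    a3 = base_normal(res)
    a1 = hydrogen_face(res, a3)
    bb = np.array([a.position for a in backbone]).mean(axis=0)
    nb = np.array([a.position for a in base]).mean(axis=0)
    return model.NucleotideFrame(
        backboneCenter=tuple(bb), nucleobaseCenter=tuple(nb),
        baseNormal=tuple(a3), hydrogenFaceDir=tuple(a1))


# --- ligands -----------------------------------------------------------------

def ligand_from_residue(res: ResidueRecord, doc: UnfDocument,
                        conect: list[tuple[int, int]] | None = None,
                        atom_serials: dict[str, int] | None = None) -> model.Ligand:
    """Build an explicit atoms-plus-bonds ligand record.

    Bonds come from CONECT pairs when available (``atom_serials`` maps the
    residue's atom names to file serials); otherwise two atoms are bonded iff
    their distance is at most the sum of covalent radii plus 0.4 A.
    """
    lig = model.Ligand(id=doc.allocate_id(), name=f"{res.name} {res.serial}")
    for a in res.atoms:
        lig.atoms.append(model.LigandAtom(element=a.element, name=a.name,
                                          position=a.position))
    if conect and atom_serials:
        serial_to_idx = {atom_serials[a.name]: i for i, a in enumerate(res.atoms)
                         if a.name in atom_serials}
        for s1, s2 in conect:
            if s1 in serial_to_idx and s2 in serial_to_idx:
                lig.bonds.append((serial_to_idx[s1], serial_to_idx[s2]))
    if not lig.bonds:
        pts = np.array([a.position for a in res.atoms])
        for i in range(len(res.atoms)):
            for j in range(i + 1, len(res.atoms)):
                ri = COVALENT_RADII.get(res.atoms[i].element, 0.75)
                rj = COVALENT_RADII.get(res.atoms[j].element, 0.75)
                if np.linalg.norm(pts[i] - pts[j]) <= ri + rj + BOND_TOLERANCE:
                    lig.bonds.append((i, j))
    return lig


# --- whole-file conversion ---------------------------------------------------

NUCLEIC = (DNA_NUCLEOTIDE, RNA_NUCLEOTIDE)


def pdb_to_unf(residues: list[ResidueRecord], doc: UnfDocument | None = None,
               file_ref: model.ExternalFile | None = None,
               conect: list[tuple[int, int]] | None = None,
               structure_name: str = "atomistic import") -> UnfDocument:
    """Coarse-grain classified residues into one UNF structure.

    Per nucleic chain one strand is created (DNA/RNA by majority
    classification) with a frame per residue and prev/next links in file
    order; per protein chain one alpha-carbon chain; non-water hetero
    residues become ligands; waters and unclassifiable residues are dropped
    (with counts logged). Chains mixing nucleic and amino residues are
    rejected.
    """
    if doc is None:
        doc = model.new_document(structure_name, "")
    st = model.Structure(id=doc.allocate_id(), name=structure_name)
    file_id = file_ref.id if file_ref is not None else NONE_ID

    by_chain: dict[str, list[tuple[ResidueRecord, str]]] = {}
    ligands: list[ResidueRecord] = []
    dropped = 0
    for res in residues:
        cls = classify_residue(res)
        if cls == WATER or cls == UNKNOWN:
            dropped += 1
            continue
        if cls == LIGAND:
            ligands.append(res)
            continue
        by_chain.setdefault(res.chainId, []).append((res, cls))

    for chain_id, members in by_chain.items():
        kinds = {cls for _, cls in members}
        if AMINO_ACID in kinds and kinds & set(NUCLEIC):
            raise ChainTypingError(
                f"chain {chain_id!r} mixes nucleic and amino residues")
        if AMINO_ACID in kinds:
            chain = model.AaChain(id=doc.allocate_id(), chainName=chain_id,
                                  pdbFileId=file_id)
            prev: model.AminoAcid | None = None
            for res, _ in members:
                ca = res.atom("CA")
                if ca is None:
                    raise IncompleteResidueError(
                        f"residue {res.name} {res.serial}: no alpha carbon")
                aa = model.AminoAcid(
                    id=doc.allocate_id(), code=_ONE_LETTER.get(res.name.upper(), "X"),
                    pdbResidueId=res.serial, position=ca.position)
                if prev is not None:
                    prev.next = aa.id
                    aa.prev = prev.id
                chain.aminoAcids.append(aa)
                prev = aa
            chain.nTermId = chain.aminoAcids[0].id
            chain.cTermId = chain.aminoAcids[-1].id
            st.aaChains.append(chain)
        else:
            n_rna = sum(1 for _, cls in members if cls == RNA_NUCLEOTIDE)
            strand = model.NaStrand(
                id=doc.allocate_id(), chainName=chain_id, pdbFileId=file_id,
                naType="RNA" if n_rna * 2 >= len(members) else "DNA")
            prev_nt: model.Nucleotide | None = None
            for res, _ in members:
                nt = model.Nucleotide(
                    id=doc.allocate_id(),
                    base=_BASE_LETTER.get(res.name.upper(), "N"),
                    pdbResidueId=res.serial,
                    altPositions=[nucleotide_frame_from_atoms(res)])
                if prev_nt is not None:
                    prev_nt.next = nt.id
                    nt.prev = prev_nt.id
                strand.nucleotides.append(nt)
                prev_nt = nt
            strand.fivePrimeId = strand.nucleotides[0].id
            strand.threePrimeId = strand.nucleotides[-1].id
            strand.name = f"chain {chain_id}"
            st.naStrands.append(strand)

    for res in ligands:
        doc.molecules.ligands.append(ligand_from_residue(res, doc, conect))

    if dropped:
        log.info("dropped %d water/unclassifiable residues", dropped)
    doc.structures.append(st)
    return doc


def convert_file(path: str, doc: UnfDocument | None = None,
                 embed_source: bool = False) -> UnfDocument:
    """Convert a PDB/mmCIF file on disk, optionally embedding the source."""
    from . import io as unf_io

    residues = residues_from_file(path)
    conect = None
    file_ref = None
    if doc is None:
        doc = model.new_document(str(path), "")
    text = None
    if str(path).lower().endswith(".pdb"):
        with open(path, "r", errors="replace") as fh:
            text = fh.read()
        conect = conect_pairs_from_pdb_text(text)
    if embed_source:
        payload = text.encode() if text is not None else open(path, "rb").read()
        file_ref = unf_io.embed_file(doc, payload, str(path))
    return pdb_to_unf(residues, doc, file_ref=file_ref, conect=conect,
                      structure_name=str(path))
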