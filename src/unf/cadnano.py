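"""Cadnano <-> UNF conversion.

Cadnano stores a multilayer origami as per-helix arrays: each base position
holds a 4-tuple ``[h5, i5, h3, i3]`` pointing at the neighboring positions
of the strand crossing it (``-1`` sentinels at strand ends), with scaffold
and staples in separate arrays. Strand routing is therefore implicit and
must be reconstructed by pointer walking. Skips (``skip = -1``) and loops
(``loop = n``) map to UNF deletion and insertion cells; an insertion of
length n references n+1 nucleotides per crossing strand.

Converting n Cadnano files produces one UNF document with n lattices and n
structures. Circular scaffold strands are cut at a predefined, deterministic
location (the lexicographically smallest ``(helixNum, baseIndex)`` cell of
the cycle); the cut strands are remembered in the document's ``misc`` field
so the reverse conversion can close them again.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

from . import model
from .errors import CadnanoError, DegeneratePathError
from .model import NONE_ID, UnfDocument

log = logging.getLogger(__name__)

SCAFFOLD = "scaffold"
STAPLE = "staple"

#: misc key recording strands that were circular before the conversion cut
CIRCULAR_KEY = "cadnanoCircularStrands"

_BLOCK = {"square": 32, "honeycomb": 21}

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


@dataclass
class VStrand:
    num: int
    row: int
    col: int
    scaf: list[list[int]] = field(default_factory=list)
    stap: list[list[int]] = field(default_factory=list)
    skip: list[int] = field(default_factory=list)
    loop: list[int] = field(default_factory=list)
    stap_colors: list[list[int]] = field(default_factory=list)


@dataclass
class CadnanoDesign:
    name: str = ""
    vstrands: list[VStrand] = field(default_factory=list)

    def helix(self, num: int) -> VStrand:
        for vs in self.vstrands:
            if vs.num == num:
                return vs
        raise CadnanoError(f"no virtual strand with num {num}")


@dataclass
class RoutedPath:
    kind: str  # scaffold | staple
    cells: list[tuple[int, int]]  # (helixNum, baseIndex)
    isCircular: bool = False


# ---------------------------------------------------------------------------
# Cadnano JSON
# ---------------------------------------------------------------------------

def parse_cadnano(text: str, name: str = "") -> CadnanoDesign:
    """Parse a cadnano2 "vstrands" JSON document."""
    d = json.loads(text)
    design = CadnanoDesign(name=d.get("name", name))
    for v in d["vstrands"]:
        vs = VStrand(
            num=v["num"], row=v["row"], col=v["col"],
            scaf=[list(t) for t in v["scaf"]],
            stap=[list(t) for t in v["stap"]],
            skip=list(v.get("skip", [0] * len(v["scaf"]))),
            loop=list(v.get("loop", [0] * len(v["scaf"]))),
            stap_colors=[list(c) for c in v.get("stap_colors", [])],
        )
        n = len(vs.scaf)
        if not (len(vs.stap) == len(vs.skip) == len(vs.loop) == n):
            raise CadnanoError(
                f"helix {vs.num}: scaf/stap/skip/loop arrays differ in length")
        design.vstrands.append(vs)
    return design


def design_to_json(design: CadnanoDesign) -> str:
    """Serialize a design to cadnano2 JSON text."""
    return json.dumps({
        "name": design.name,
        "vstrands": [
            {
                "row": vs.row, "col": vs.col, "num": vs.num,
                "scaf": [list(t) for t in vs.scaf],
                "stap": [list(t) for t in vs.stap],
                "skip": list(vs.skip),
                "loop": list(vs.loop),
                "scafLoop": [],
                "stapLoop": [],
                "stap_colors": [list(c) for c in vs.stap_colors],
            }
            for vs in design.vstrands
        ],
    }, indent=2)


def color_int_to_hex(value: int) -> str:
    return f"#{value & 0xFFFFFF:06X}"


def color_hex_to_int(color: str) -> int:
    return int(color.lstrip("#"), 16)


# ---------------------------------------------------------------------------
# routing reconstruction
# ---------------------------------------------------------------------------

def _tuples(design: CadnanoDesign, kind: str) -> dict[tuple[int, int], list[int]]:
    """Map of occupied (helixNum, baseIndex) -> routing tuple."""
    occupied = {}
    for vs in design.vstrands:
        arr = vs.scaf if kind == SCAFFOLD else vs.stap
        for i, t in enumerate(arr):
            if any(x != NONE_ID for x in t):
                occupied[(vs.num, i)] = t
    return occupied


def trace_strands(design: CadnanoDesign, kind: str) -> list[RoutedPath]:
    """Reconstruct every routed path of one strand kind.

    Linear paths start at a 5' end (``h5 = i5 = -1``) and follow the 3'
    pointers; occupied tuples left over after all linear paths are consumed
    belong to circular paths. Every occupied tuple ends up in exactly one
    path. Pointers into empty cells raise a dangling-pointer error.
    """
    if kind not in (SCAFFOLD, STAPLE):
        raise CadnanoError(f"unknown strand kind {kind!r}")
    occupied = _tuples(design, kind)
    unvisited = set(occupied)
    paths: list[RoutedPath] = []

    def follow(start: tuple[int, int], circular: bool) -> RoutedPath:
        cells = []
        cur = start
        while True:
            if cur not in occupied:
                raise CadnanoError(
                    f"{kind} tuple points at empty cell (helix {cur[0]}, index {cur[1]})")
            if cur not in unvisited:
                raise CadnanoError(
                    f"{kind} routing re-enters cell (helix {cur[0]}, index {cur[1]})")
            unvisited.discard(cur)
            cells.append(cur)
            h3, i3 = occupied[cur][2], occupied[cur][3]
            if h3 == NONE_ID and i3 == NONE_ID:
                return RoutedPath(kind, cells, isCircular=False)
            nxt = (h3, i3)
            if circular and nxt == start:
                return RoutedPath(kind, cells, isCircular=True)
            cur = nxt

    # linear paths first: deterministic scan order over helices and indices
    for (h, i), t in sorted(occupied.items()):
        if (h, i) in unvisited and t[0] == NONE_ID and t[1] == NONE_ID:
            paths.append(follow((h, i), circular=False))
    # leftovers form circular paths
    while unvisited:
        start = min(unvisited)
        paths.append(follow(start, circular=True))
    return paths


def cut_circular(path: RoutedPath) -> RoutedPath:
    """Linearize a circular path at a predefined, deterministic location.

    The cut places the 5' end at the lexicographically smallest
    ``(helixNum, baseIndex)`` cell of the cycle, so converting the same
    design twice yields identical output regardless of traversal order.
    """
    if not path.isCircular:
        raise DegeneratePathError("cut_circular requires a circular path")
    if len(path.cells) < 2:
        raise DegeneratePathError(f"degenerate circular path of length {len(path.cells)}")
    k = path.cells.index(min(path.cells))
    return RoutedPath(path.kind, path.cells[k:] + path.cells[:k], isCircular=False)


def apply_loops_skips(path: RoutedPath, design: CadnanoDesign
                      ) -> list[tuple[tuple[int, int], int]]:
    """Per-cell nucleotide multiplicity along a linear path.

    A skip (``-1``) suppresses the cell's nucleotide entirely; a loop of n
    expands it to n+1 nucleotides; plain cells contribute one.
    """
    if path.isCircular:
        raise DegeneratePathError("apply_loops_skips requires a linear path")
    out = []
    for (h, i) in path.cells:
        vs = design.helix(h)
        skip, loop = vs.skip[i], vs.loop[i]
        if skip == -1 and loop > 0:
            raise CadnanoError(f"cell (helix {h}, index {i}) has both skip and loop set")
        if skip == -1:
            mult = 0
        elif loop > 0:
            mult = loop + 1
        else:
            mult = 1
        out.append(((h, i), mult))
    return out


# ---------------------------------------------------------------------------
# Cadnano -> UNF
# ---------------------------------------------------------------------------

@dataclass
class CadnanoInput:
    design: CadnanoDesign
    latticeType: str = "square"
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    scaffoldSequence: str | None = None


def _cell_direction(path_cells: list[tuple[int, int]], k: int, kind: str) -> int:
    """+1 if the strand crosses cell k with increasing baseIndex, else -1.

    Derived from the actual traversal (neighboring path cells on the same
    helix); single-cell fragments fall back to Cadnano's even/odd helix
    parity convention (scaffold 5'->3' runs left to right on even helices).
    """
    h, i = path_cells[k]
    if k + 1 < len(path_cells) and path_cells[k + 1][0] == h:
        return 1 if path_cells[k + 1][1] > i else -1
    if k > 0 and path_cells[k - 1][0] == h:
        return 1 if i > path_cells[k - 1][1] else -1
    parity = 1 if h % 2 == 0 else -1
    return parity if kind == SCAFFOLD else -parity


def cadnano_to_unf(inputs: list[CadnanoInput], doc: UnfDocument | None = None
                   ) -> UnfDocument:
    """Convert Cadnano designs into one UNF document.

    For n input files, n records are created in both the ``lattices`` and
    ``structures`` fields. Nucleotides are instantiated per skip/loop
    multiplicity, chained 5'->3', referenced from cells by traversal
    direction, and paired where scaffold and staple co-occupy a cell.
    Staple colors become ``#RRGGBB`` strand colors; bases default to "N"
    unless a scaffold sequence is supplied.
    """
    if doc is None:
        doc = model.new_document("cadnano import", "")
    circular_ids: list[int] = doc.misc.setdefault(CIRCULAR_KEY, [])

    for inp in inputs:
        design = inp.design
        lat = model.Lattice(
            id=doc.allocate_id(), name=design.name or "cadnano lattice",
            type=inp.latticeType, position=inp.position, orientation=inp.orientation,
        )
        st = model.Structure(id=doc.allocate_id(), name=design.name or "cadnano structure")

        # cells for every occupied or skip/loop-bearing strand position
        cell_of: dict[tuple[int, int], model.Cell] = {}
        occupied = set(_tuples(design, SCAFFOLD)) | set(_tuples(design, STAPLE))
        for vs in design.vstrands:
            vh = model.VirtualHelix(
                id=doc.allocate_id(), row=vs.row, col=vs.col, designNumber=vs.num)
            for i in range(len(vs.scaf)):
                if (vs.num, i) not in occupied:
                    continue
                if vs.skip[i] == -1 and vs.loop[i] > 0:
                    raise CadnanoError(
                        f"cell (helix {vs.num}, index {i}) has both skip and loop set")
                ctype = ("deletion" if vs.skip[i] == -1
                         else "insertion" if vs.loop[i] > 0 else "normal")
                cell = model.Cell(id=doc.allocate_id(), index=i, type=ctype)
                vh.cells.append(cell)
                cell_of[(vs.num, i)] = cell
            lat.virtualHelices.append(vh)

        color_lookup: dict[tuple[int, int], str] = {}
        for vs in design.vstrands:
            for idx, cint in vs.stap_colors:
                color_lookup[(vs.num, idx)] = color_int_to_hex(cint)

        for kind in (SCAFFOLD, STAPLE):
            for path in trace_strands(design, kind):
                was_circular = path.isCircular
                if was_circular:
                    path = cut_circular(path)
                mults = apply_loops_skips(path, design)
                strand = model.NaStrand(
                    id=doc.allocate_id(), naType="DNA",
                    isScaffold=(kind == SCAFFOLD),
                    color="#0066CC" if kind == SCAFFOLD else "#999999",
                )
                prev_nt: model.Nucleotide | None = None
                for k, ((h, i), mult) in enumerate(mults):
                    cell = cell_of[(h, i)]
                    direction = _cell_direction(path.cells, k, kind)
                    arr = cell.fiveToThreeNts if direction > 0 else cell.threeToFiveNts
                    for _ in range(mult):
                        nt = model.Nucleotide(id=doc.allocate_id(), base="N")
                        if prev_nt is not None:
                            prev_nt.next = nt.id
                            nt.prev = prev_nt.id
                        strand.nucleotides.append(nt)
                        arr.append(nt.id)  # strand 5'->3' order within the cell
                        prev_nt = nt
                if strand.nucleotides:
                    if was_circular:
                        circular_ids.append(strand.id)
                    strand.fivePrimeId = strand.nucleotides[0].id
                    strand.threePrimeId = strand.nucleotides[-1].id
                    if kind == STAPLE:
                        c = color_lookup.get(path.cells[0])
                        if c:
                            strand.color = c
                    strand.name = f"{kind} {strand.id}"
                    st.naStrands.append(strand)

        # pairing: scaffold and staple sharing a cell pair by axial slot
        nt_index = {nt.id: nt for s in st.naStrands for nt in s.nucleotides}
        for cell in (c for vh in lat.virtualHelices for c in vh.cells):
            f, t = cell.fiveToThreeNts, cell.threeToFiveNts
            if f and t and len(f) == len(t):
                m = len(f)
                for k in range(m):
                    a, b = nt_index[f[k]], nt_index[t[m - 1 - k]]
                    a.pair, b.pair = b.id, a.id

        if inp.scaffoldSequence:
            _assign_scaffold_sequence(st, nt_index, inp.scaffoldSequence)

        doc.lattices.append(lat)
        doc.structures.append(st)
    if not circular_ids:
        doc.misc.pop(CIRCULAR_KEY, None)
    return doc


def _assign_scaffold_sequence(st: model.Structure, nt_index, sequence: str) -> None:
    seq = sequence.strip().upper()
    pos = 0
    for strand in st.naStrands:
        if not strand.isScaffold:
            continue
        for nt in model.walk_strand(strand):
            if pos >= len(seq):
                log.warning("scaffold sequence shorter than scaffold; padding with N")
                break
            nt.base = seq[pos]
            pos += 1
            if nt.pair != NONE_ID:
                nt_index[nt.pair].base = _COMPLEMENT.get(nt.base, "N")


# ---------------------------------------------------------------------------
# UNF -> Cadnano
# ---------------------------------------------------------------------------

def unf_to_cadnano(doc: UnfDocument) -> list[CadnanoDesign]:
    """Convert each UNF lattice into a Cadnano design.

    Routing tuples, skip/loop arrays and staple colors are reconstructed
    from the cells and strand topology. Free-form structures and molecules
    cannot be represented in Cadnano and are ignored with a warning.
    """
    designs = []
    lattice_cells: set[int] = set()
    for lat in doc.lattices:
        designs.append(_lattice_to_design(doc, lat, lattice_cells))
    free = [st for st in doc.structures
            if any(nt.id not in lattice_cells
                   for s in st.naStrands for nt in s.nucleotides)]
    if free or doc.molecules.ligands or doc.molecules.nanostructures or doc.molecules.others:
        log.warning("free-form structures/molecules are not representable in "
                    "Cadnano and were ignored")
    return designs


def _lattice_to_design(doc: UnfDocument, lat: model.Lattice,
                       converted_nts: set[int]) -> CadnanoDesign:
    block = _BLOCK.get(lat.type, 32)
    strands = {s.id: s for st in doc.structures for s in st.naStrands}
    nt_strand = {nt.id: s for s in strands.values() for nt in s.nucleotides}

    # assign helix numbers: keep original designNumber, else checkerboard parity
    nums: dict[int, int] = {}
    next_even, next_odd = 0, 1
    for vh in lat.virtualHelices:
        if vh.designNumber != NONE_ID:
            nums[vh.id] = vh.designNumber
        elif (vh.row + vh.col) % 2 == 0:
            nums[vh.id] = next_even
            next_even += 2
        else:
            nums[vh.id] = next_odd
            next_odd += 2

    max_index = max((c.index for vh in lat.virtualHelices for c in vh.cells), default=-1)
    arrlen = ((max_index // block) + 1) * block if max_index >= 0 else 0

    vstrands: dict[int, VStrand] = {}
    cell_at: dict[tuple[int, int], model.Cell] = {}
    for vh in lat.virtualHelices:
        num = nums[vh.id]
        vs = VStrand(
            num=num, row=vh.row, col=vh.col,
            scaf=[[-1, -1, -1, -1] for _ in range(arrlen)],
            stap=[[-1, -1, -1, -1] for _ in range(arrlen)],
            skip=[0] * arrlen, loop=[0] * arrlen,
        )
        vstrands[num] = vs
        for cell in vh.cells:
            cell_at[(num, cell.index)] = cell
            if cell.type == "deletion":
                vs.skip[cell.index] = -1
            elif cell.type == "insertion":
                n = max(len(cell.fiveToThreeNts), len(cell.threeToFiveNts)) - 1
                vs.loop[cell.index] = max(n, 0)

    # locate every nucleotide of this lattice
    nt_cell: dict[int, tuple[int, int]] = {}
    for (num, idx), cell in cell_at.items():
        for ntid in cell.fiveToThreeNts + cell.threeToFiveNts:
            if ntid not in nt_strand:
                raise CadnanoError(
                    f"nucleotide {ntid} referenced by lattice cell but not by any strand")
            nt_cell[ntid] = (num, idx)
            converted_nts.add(ntid)

    circular = set(doc.misc.get(CIRCULAR_KEY, []))
    lattice_strands = [s for s in strands.values()
                       if s.nucleotides and s.nucleotides[0].id in nt_cell]
    for strand in lattice_strands:
        order = model.walk_strand(strand)
        # collapse insertion multiplicities to a cell path
        path: list[tuple[int, int]] = []
        for nt in order:
            if nt.id not in nt_cell:
                raise CadnanoError(
                    f"strand {strand.id}: nucleotide {nt.id} is not referenced "
                    f"by any cell of lattice {lat.id}")
            cell = nt_cell[nt.id]
            if not path or path[-1] != cell:
                path.append(cell)
        path = _route_through_deletions(path, cell_at, circular=strand.id in circular)
        is_circ = strand.id in circular
        arr_name = "scaf" if strand.isScaffold else "stap"
        m = len(path)
        for k, (h, i) in enumerate(path):
            vs = vstrands[h]
            t = getattr(vs, arr_name)[i]
            if any(x != NONE_ID for x in t):
                raise CadnanoError(
                    f"two {arr_name} strands occupy cell (helix {h}, index {i})")
            if k > 0 or is_circ:
                t[0], t[1] = path[(k - 1) % m]
            if k < m - 1 or is_circ:
                t[2], t[3] = path[(k + 1) % m]
        if not strand.isScaffold:
            h5, i5 = path[0]
            vstrands[h5].stap_colors.append([i5, color_hex_to_int(strand.color)])

    for vs in vstrands.values():
        vs.stap_colors.sort()
    design = CadnanoDesign(name=lat.name,
                           vstrands=[vstrands[nums[vh.id]] for vh in lat.virtualHelices])
    return design


def _route_through_deletions(path, cell_at, circular: bool):
    """Re-insert deletion cells into a strand's cell path.

    UNF deletion cells reference no nucleotides, so the nucleotide-derived
    path jumps over them; Cadnano routing must pass through. Any gap between
    consecutive path cells on one helix must be bridged by deletion cells.
    """
    if len(path) < 2:
        return list(path)
    out = []
    pairs = list(zip(path, path[1:]))
    if circular:
        pairs.append((path[-1], path[0]))
    for (h1, i1), (h2, i2) in pairs:
        out.append((h1, i1))
        if h1 == h2 and abs(i2 - i1) > 1:
            step = 1 if i2 > i1 else -1
            for i in range(i1 + step, i2, step):
                cell = cell_at.get((h1, i))
                if cell is None or cell.type != "deletion":
                    raise CadnanoError(
                        f"strand path jumps over non-deletion cell "
                        f"(helix {h1}, index {i})")
                out.append((h1, i))
    if not circular:
        out.append(path[-1])
    return out
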