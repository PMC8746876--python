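"""Deterministic toy-structure generators.

Every converter in this package is exercised against small synthetic
inputs built here: serpentine Cadnano origami designs (2-8 helices, with
skips, loops, circular scaffolds and staple colors), idealized B-form
atomistic duplexes written as PDB text, and ideal-helix oxDNA systems.
All generators are pure functions of their spec plus seed.

The atomistic templates are idealized (planar rings, approximate bond
lengths), not crystallographic: exactly what the coarse-graining math
needs, and fully self-contained.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .cadnano import CadnanoDesign, VStrand
from .errors import FixtureSpecError

_PALETTE = [0xCC0000, 0x00CC00, 0x0066CC, 0xCC6600, 0x9900CC, 0x00CCCC]

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


# ---------------------------------------------------------------------------
# Cadnano designs
# ---------------------------------------------------------------------------

@dataclass
class FixtureSpec:
    """Parameters of a toy serpentine origami design.

    The scaffold runs a serpentine over an even number of helices
    (optionally closed into a circle); staples follow one of two crossover
    patterns. Skips and loops may be placed on interior straight-run cells
    only — positions at strand termini or next to crossovers are rejected,
    because deletion cells carry no routing and such placements would not
    be reconstructible from the converted document.
    """

    nHelices: int = 2
    cellsPerHelix: int = 32
    latticeType: str = "square"
    skips: list[tuple[int, int]] = field(default_factory=list)  # (helix, index)
    loops: list[tuple[int, int, int]] = field(default_factory=list)  # (helix, index, n)
    staples: str = "straight"  # "straight" | "cross" | "none"
    colors: list[int] = field(default_factory=lambda: list(_PALETTE))
    circularScaffold: bool = True
    seed: int = 0


def allowed_modifier_columns(spec: FixtureSpec) -> list[int]:
    """Columns where a skip or loop is structurally reconstructible."""
    L = spec.cellsPerHelix
    m = L // 2
    if spec.staples == "cross":
        return sorted(set(range(4, m - 2)) | set(range(m + 2, L - 4)))
    return list(range(4, L - 4))


def make_toy_cadnano(spec: FixtureSpec) -> CadnanoDesign:
    """Build a Cadnano design from a fixture spec.

    Even helices carry the scaffold 5'->3' left to right, odd helices right
    to left, with crossovers at the columns 0 and L-1 ends; staples run
    antiparallel. Identical specs produce byte-identical designs.
    """
    n, L = spec.nHelices, spec.cellsPerHelix
    if n < 2 or n % 2:
        raise FixtureSpecError("nHelices must be an even number >= 2")
    if L < 16:
        raise FixtureSpecError("cellsPerHelix must be >= 16")
    if spec.latticeType not in ("square", "honeycomb"):
        raise FixtureSpecError(f"unknown lattice type {spec.latticeType!r}")
    if spec.staples not in ("straight", "cross", "none"):
        raise FixtureSpecError(f"unknown staple pattern {spec.staples!r}")
    if n == 1 and spec.staples == "cross":
        raise FixtureSpecError("cross staple pattern needs at least one helix pair")

    block = 32 if spec.latticeType == "square" else 21
    arrlen = ((L - 1) // block + 1) * block
    vstrands = []
    for h in range(n):
        vstrands.append(VStrand(
            num=h, row=h, col=0,
            scaf=[[-1, -1, -1, -1] for _ in range(arrlen)],
            stap=[[-1, -1, -1, -1] for _ in range(arrlen)],
            skip=[0] * arrlen, loop=[0] * arrlen))

    allowed = set(allowed_modifier_columns(spec))
    seen_mod: set[tuple[int, int]] = set()
    for h, i in spec.skips:
        if not 0 <= h < n or i not in allowed or (h, i) in seen_mod:
            raise FixtureSpecError(f"skip at (helix {h}, index {i}) is not placeable")
        seen_mod.add((h, i))
        vstrands[h].skip[i] = -1
    for h, i, count in spec.loops:
        if not 0 <= h < n or i not in allowed or (h, i) in seen_mod or count < 1:
            raise FixtureSpecError(f"loop at (helix {h}, index {i}) is not placeable")
        seen_mod.add((h, i))
        vstrands[h].loop[i] = count

    def write_path(arr_name: str, cells: list[tuple[int, int]], circular: bool):
        m = len(cells)
        for k, (h, i) in enumerate(cells):
            t = getattr(vstrands[h], arr_name)[i]
            if k > 0 or circular:
                t[0], t[1] = cells[(k - 1) % m]
            if k < m - 1 or circular:
                t[2], t[3] = cells[(k + 1) % m]

    # scaffold serpentine
    scaffold_cells = []
    for h in range(n):
        cols = range(L) if h % 2 == 0 else range(L - 1, -1, -1)
        scaffold_cells.extend((h, i) for i in cols)
    write_path("scaf", scaffold_cells, spec.circularScaffold)

    # staples
    staple_paths: list[list[tuple[int, int]]] = []
    if spec.staples == "straight":
        for h in range(n):
            cols = (range(L - 3, 1, -1) if h % 2 == 0 else range(2, L - 2))
            staple_paths.append([(h, i) for i in cols])
    elif spec.staples == "cross":
        m = L // 2
        for p in range(n // 2):
            a, b = 2 * p, 2 * p + 1
            path_a = [(b, i) for i in range(2, m)] + [(a, i) for i in range(m - 1, 1, -1)]
            path_b = [(a, i) for i in range(L - 3, m - 1, -1)] + [(b, i) for i in range(m, L - 2)]
            staple_paths.extend([path_a, path_b])
    rng = random.Random(spec.seed)
    palette = spec.colors or list(_PALETTE)
    for path in staple_paths:
        write_path("stap", path, circular=False)
        h5, i5 = path[0]
        vstrands[h5].stap_colors.append([i5, rng.choice(palette)])
    for vs in vstrands:
        vs.stap_colors.sort()

    return CadnanoDesign(
        name=f"toy-{spec.latticeType}-{n}x{L}-s{spec.seed}", vstrands=vstrands)


def random_fixture_spec(rng: random.Random, lattice_type: str | None = None
                        ) -> FixtureSpec:
    """Draw a randomized but always-valid fixture spec (for property tests)."""
    lt = lattice_type or rng.choice(["square", "honeycomb"])
    n = rng.choice([2, 4, 6, 8])
    L = rng.choice([32, 64]) if lt == "square" else rng.choice([21, 42])
    spec = FixtureSpec(
        nHelices=n, cellsPerHelix=L, latticeType=lt,
        staples=rng.choice(["straight", "cross"]),
        circularScaffold=rng.random() < 0.5,
        seed=rng.randrange(1 << 30),
    )
    cols = allowed_modifier_columns(spec)
    sites = [(h, i) for h in range(n) for i in cols]
    rng.shuffle(sites)
    n_skip = rng.randrange(0, 3)
    n_loop = rng.randrange(0, 3)
    spec.skips = sorted(sites[:n_skip])
    spec.loops = sorted((h, i, rng.randrange(1, 4)) for h, i in sites[n_skip:n_skip + n_loop])
    return spec


# ---------------------------------------------------------------------------
# atomistic duplexes
# ---------------------------------------------------------------------------

# Planar nucleobase templates (z = 0): hexagon ring of radius 1.4 A listed
# counterclockwise, fused pentagon atoms for purines on the -x side, and a
# few exocyclic substituents. Backbone atoms sit off-plane on the +x side.
_HEX = {name: (1.4 * math.cos(math.radians(60 * k)),
               1.4 * math.sin(math.radians(60 * k)), 0.0)
        for k, name in enumerate(["N1", "C2", "N3", "C4", "C5", "C6"])}
# pentagon fused on the C4-C5 edge, placed so the cyclic ring traversal
# N1..C6,N7,C8,N9 keeps a positive signed area (normal = +z like pyrimidines)
_PENTA = {"N7": (-1.6, -1.9, 0.0), "C8": (-2.5, -1.3, 0.0), "N9": (-2.2, -0.4, 0.0)}
_BACKBONE_TEMPLATE = {
    "P": (4.5, -1.0, 1.2), "O5'": (4.0, -1.4, 0.6), "C5'": (3.6, -1.8, 0.2),
    "C4'": (3.2, -2.2, -0.2), "O4'": (2.8, -1.6, -0.5), "C3'": (3.0, -2.8, -0.6),
    "O3'": (2.6, -3.2, -1.0), "C2'": (2.4, -2.6, -0.1), "C1'": (2.2, -1.9, 0.1),
}
_EXOCYCLIC = {
    "A": {"N6": (2.1, 1.2, 0.0)},
    "G": {"O6": (2.1, 1.2, 0.0), "N2": (-1.0, 2.6, 0.0)},
    "C": {"O2": (1.4, -2.4, 0.0), "N4": (-1.0, 2.6, 0.0)},
    "T": {"O2": (1.4, -2.4, 0.0), "O4": (-1.0, 2.6, 0.0), "C7": (-2.1, -1.2, 0.0)},
}
_RES_NAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}

DUPLEX_RISE = 3.4  # Angstrom
DUPLEX_TWIST = 36.0  # degrees per bp


def base_template(letter: str) -> dict[str, tuple[float, float, float]]:
    """Atom-name -> local position template for one DNA residue."""
    if letter not in _RES_NAME:
        raise FixtureSpecError(f"sequence letter {letter!r} not in ACGT")
    atoms = dict(_HEX)
    if letter in ("A", "G"):
        atoms.update(_PENTA)
    atoms.update(_EXOCYCLIC[letter])
    atoms.update(_BACKBONE_TEMPLATE)
    return atoms


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def make_toy_duplex_pdb(sequence: str) -> str:
    """Idealized B-form DNA duplex as PDB text.

    Chain A carries ``sequence`` 5'->3' winding up the +z axis; chain B is
    its reverse complement, also listed 5'->3', built by flipping the
    residue template (180 degrees about x) so base planes face each other
    and the two strands are antiparallel.
    """
    seq = sequence.strip().upper()
    if not seq:
        raise FixtureSpecError("empty sequence")
    st = gemmi.Structure()
    st.name = "toy duplex"
    mdl = gemmi.Model("1")

    def add_residue(chain: gemmi.Chain, serial: int, letter: str,
                    rot_z_deg: float, z: float, flip: bool):
        res = gemmi.Residue()
        res.name = _RES_NAME[letter]
        res.seqid = gemmi.SeqId(serial, " ")
        th = math.radians(rot_z_deg)
        c, s = math.cos(th), math.sin(th)
        for name, (x, y, zz) in base_template(letter).items():
            if flip:
                y, zz = -y, -zz
            px, py, pz = c * x - s * y, s * x + c * y, zz + z
            atom = gemmi.Atom()
            atom.name = name
            atom.element = gemmi.Element(_element_of(name))
            atom.pos = gemmi.Position(px, py, pz)
            res.add_atom(atom)
        chain.add_residue(res)

    chain_a = gemmi.Chain("A")
    for i, letter in enumerate(seq):
        add_residue(chain_a, i + 1, letter, i * DUPLEX_TWIST, i * DUPLEX_RISE, False)
    mdl.add_chain(chain_a)

    chain_b = gemmi.Chain("B")
    nres = len(seq)
    for j in range(nres):
        i = nres - 1 - j  # partner index on chain A
        letter = _COMP[seq[i]]
        add_residue(chain_b, j + 1, letter, i * DUPLEX_TWIST + 180.0,
                    i * DUPLEX_RISE, True)
    mdl.add_chain(chain_b)

    st.add_model(mdl)
    st.setup_entities()
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# oxDNA duplexes
# ---------------------------------------------------------------------------

_OX_RISE_SU = 3.4 / 8.518
_OX_TWIST = 35.0  # degrees per bp
_OX_RADIUS = 0.6  # su from axis to nucleotide center of mass


def _fmt(x: float) -> str:
    return f"{x:.8f}"


def make_toy_oxdna(sequence: str, seed: int = 0) -> tuple[str, str]:
    """Ideal-helix oxDNA duplex (classic dialect: topology lists 3'->5').

    Strand 1 is ``sequence``, strand 2 its reverse complement, with
    orthonormal a1/a3 frames and a small seeded positional jitter so
    configurations are not degenerate. Deterministic per (sequence, seed).
    """
    seq = sequence.strip().upper()
    if not seq:
        raise FixtureSpecError("empty sequence")
    if any(b not in _COMP for b in seq):
        raise FixtureSpecError("sequence letters must be in ACGT")
    rng = random.Random(seed)
    nres = len(seq)

    rows = []  # (strand, base, com, a1, a3) in topology order, 3'->5' per strand
    # strand 1: 5'->3' runs up +z; classic topology lists it 3'->5'
    frames1 = []
    for i, b in enumerate(seq):
        th = math.radians(i * _OX_TWIST)
        a1 = np.array([math.cos(th), math.sin(th), 0.0])
        a3 = np.array([0.0, 0.0, 1.0])
        jitter = np.array([rng.uniform(-0.05, 0.05) for _ in range(3)])
        com = -_OX_RADIUS * a1 + np.array([0.0, 0.0, i * _OX_RISE_SU]) + jitter
        frames1.append((b, com, a1, a3))
    for b, com, a1, a3 in reversed(frames1):
        rows.append((1, b, com, a1, a3))
    # strand 2: reverse complement; partner of strand-1 residue i
    frames2 = []
    for j in range(nres):
        i = nres - 1 - j
        th = math.radians(i * _OX_TWIST)
        a1 = -np.array([math.cos(th), math.sin(th), 0.0])
        a3 = np.array([0.0, 0.0, -1.0])
        jitter = np.array([rng.uniform(-0.05, 0.05) for _ in range(3)])
        com = -_OX_RADIUS * a1 + np.array([0.0, 0.0, i * _OX_RISE_SU]) + jitter
        frames2.append((_COMP[seq[i]], com, a1, a3))
    for b, com, a1, a3 in reversed(frames2):
        rows.append((2, b, com, a1, a3))

    n = len(rows)
    top_lines = [f"{n} 2"]
    for k, (snum, base, _, _, _) in enumerate(rows):
        n3 = k - 1 if k > 0 and rows[k - 1][0] == snum else -1
        n5 = k + 1 if k + 1 < n and rows[k + 1][0] == snum else -1
        top_lines.append(f"{snum} {base} {n3} {n5}")
    topology = "\n".join(top_lines) + "\n"

    box = 20.0 + nres * _OX_RISE_SU
    conf_lines = ["t = 0", f"b = {_fmt(box)} {_fmt(box)} {_fmt(box)}", "E = 0 0 0"]
    for _, _, com, a1, a3 in rows:
        vals = list(com) + list(a1) + list(a3) + [0.0] * 6
        conf_lines.append(" ".join(_fmt(v) for v in vals))
    configuration = "\n".join(conf_lines) + "\n"
    return topology, configuration
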