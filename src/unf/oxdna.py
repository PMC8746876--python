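"""oxDNA <-> UNF conversion (classic topology/configuration dialect).

oxDNA stores one rigid body per nucleotide: a center of mass ``com`` plus
two orientation vectors, ``a1`` (toward the Watson-Crick face) and ``a3``
(the stacking direction), in simulation units (1 su = 8.518 A). UNF splits
the nucleotide into separate backbone and base centers; this bridge maps
between the two using the oxDNA1 interaction-site offsets of +/-0.4 su
along a1:

    nucleobaseCenter = (com + 0.4 a1) * 8.518 A
    backboneCenter   = (com - 0.4 a1) * 8.518 A

The classic topology dialect lists nucleotides 3'->5' per strand
(``strand base n3 n5`` per line, header ``N Ns``); UNF strands run 5'->3',
so ordering is reversed on both conversions. The newer 5'->3' topology
dialect is rejected with a clear error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import model
from .errors import OxDnaError
from .geometry import DEFAULT_PARAMS, GeometryParams, resolve_nucleotide_position
from .model import UnfDocument

log = logging.getLogger(__name__)

SU_TO_ANGSTROM = 8.518
BASE_SITE_OFFSET = 0.4      # su along +a1 to the base site
BACKBONE_SITE_OFFSET = -0.4  # su along a1 to the backbone site
BOX_PADDING_SU = 20.0


def su_to_angstrom(x):
    """Simulation units -> Angstrom (elementwise)."""
    return np.asarray(x, float) * SU_TO_ANGSTROM


def angstrom_to_su(x):
    """Angstrom -> simulation units, the exact inverse of
    :func:`su_to_angstrom`.

    Multiplication by 8.518 (> 1) is injective on doubles, so an exact
    inverse exists; plain division mis-rounds it by one ulp for a small
    fraction of inputs. A one-ulp correction restores bit-exact round
    trips for all finite coordinates of practical magnitude.
    """
    x = np.asarray(x, float)
    y = x / SU_TO_ANGSTROM
    for cand in (np.nextafter(y, -np.inf), np.nextafter(y, np.inf)):
        fix = (y * SU_TO_ANGSTROM != x) & (cand * SU_TO_ANGSTROM == x)
        y = np.where(fix, cand, y)
    return y


@dataclass
class OxNucleotide:
    strandId: int
    base: str
    n3: int
    n5: int
    com: np.ndarray
    a1: np.ndarray
    a3: np.ndarray
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))
    angularVelocity: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class OxSystem:
    nNucleotides: int
    nStrands: int
    box: np.ndarray
    time: float = 0.0
    energies: tuple[float, float, float] = (0.0, 0.0, 0.0)
    perNucleotide: list[OxNucleotide] = field(default_factory=list)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_oxdna(topology_text: str, configuration_text: str) -> OxSystem:
    """Parse a classic oxDNA topology + configuration pair.

    Velocities are zero-filled when the configuration rows carry only
    position and orientation columns. Orientation vectors off unit length
    by more than 1e-3 are renormalized with a warning.
    """
    top_lines = [ln for ln in topology_text.splitlines() if ln.strip()]
    if not top_lines:
        raise OxDnaError("empty topology file")
    header = top_lines[0].split()
    if len(header) < 2:
        raise OxDnaError(f"malformed topology header {top_lines[0]!r}")
    if "5->3" in top_lines[0] or (len(header) > 2 and header[2] == "5->3"):
        raise OxDnaError("new-style 5'->3' topology dialect is not supported; "
                         "supply a classic 3'->5' topology")
    n_nt, n_strands = int(header[0]), int(header[1])
    rows = top_lines[1:]
    if len(rows) != n_nt:
        raise OxDnaError(f"topology declares {n_nt} nucleotides but has {len(rows)} rows")

    conf_lines = [ln for ln in configuration_text.splitlines() if ln.strip()]
    if len(conf_lines) < 3:
        raise OxDnaError("configuration file lacks t/b/E header lines")
    meta, conf_rows = conf_lines[:3], conf_lines[3:]
    if len(conf_rows) != n_nt:
        raise OxDnaError(
            f"topology has {n_nt} nucleotides but configuration has {len(conf_rows)} rows")

    def _vals(line: str, prefix: str) -> list[float]:
        body = line.split("=", 1)[1] if "=" in line else line[len(prefix):]
        return [float(x) for x in body.split()]

    time = _vals(meta[0], "t")[0]
    box = np.array(_vals(meta[1], "b")[:3])
    energies = tuple((_vals(meta[2], "E") + [0.0, 0.0, 0.0])[:3])

    sys = OxSystem(nNucleotides=n_nt, nStrands=n_strands, box=box,
                   time=time, energies=energies)
    warned = False
    for k in range(n_nt):
        ts = rows[k].split()
        if len(ts) != 4:
            raise OxDnaError(f"topology row {k} is not 'strand base n3 n5': {rows[k]!r}")
        cs = [float(x) for x in conf_rows[k].split()]
        if len(cs) < 9:
            raise OxDnaError(f"configuration row {k} has {len(cs)} columns, expected >= 9")
        com, a1, a3 = np.array(cs[0:3]), np.array(cs[3:6]), np.array(cs[6:9])
        for name, v in (("a1", a1), ("a3", a3)):
            norm = np.linalg.norm(v)
            if abs(norm - 1.0) > 1e-3:
                if not warned:
                    log.warning("non-unit %s vector (|v|=%.4f) renormalized", name, norm)
                    warned = True
                v /= norm
        vel = np.array(cs[9:12]) if len(cs) >= 15 else np.zeros(3)
        ang = np.array(cs[12:15]) if len(cs) >= 15 else np.zeros(3)
        sys.perNucleotide.append(OxNucleotide(
            strandId=int(ts[0]), base=ts[1], n3=int(ts[2]), n5=int(ts[3]),
            com=com, a1=a1, a3=a3, velocity=vel, angularVelocity=ang))
    return sys


# ---------------------------------------------------------------------------
# oxDNA -> UNF
# ---------------------------------------------------------------------------

def oxdna_to_unf(sys: OxSystem, doc: UnfDocument | None = None,
                 rna: bool = False) -> UnfDocument:
    """Convert an oxDNA system to a UNF structure with explicit frames.

    Strands are rebuilt from the n3/n5 links and stored 5'->3'; the single
    oxDNA center of mass expands to the split backbone/base representation
    via the +/-0.4 su site offsets; the simulation box converts to Angstrom.
    """
    if doc is None:
        doc = model.new_document("oxDNA import", "")
    st = model.Structure(id=doc.allocate_id(), name="oxDNA import")
    doc.simulationBox = tuple(np.asarray(sys.box, float) * SU_TO_ANGSTROM)

    n = sys.nNucleotides
    # group row indices by strand, preserving file order
    strand_rows: dict[int, list[int]] = {}
    for k, nt in enumerate(sys.perNucleotide):
        strand_rows.setdefault(nt.strandId, []).append(k)

    for sid, rows in strand_rows.items():
        members = set(rows)
        # the 5' terminus has n5 == -1; following n3 pointers from it
        # yields the strand in UNF's 5'->3' order
        five_ends = [k for k in rows if sys.perNucleotide[k].n5 == -1]
        if len(five_ends) != 1:
            raise OxDnaError(
                f"strand {sid}: expected exactly one 5' end, found {len(five_ends)} "
                "(circular or broken n3/n5 chain)")
        order_5to3 = []
        k = five_ends[0]
        seen = set()
        while True:
            if k in seen:
                raise OxDnaError(f"strand {sid}: n3 chain revisits row {k}")
            if k not in members:
                raise OxDnaError(f"strand {sid}: n3 chain leaves the strand at row {k}")
            seen.add(k)
            order_5to3.append(k)
            k3 = sys.perNucleotide[k].n3
            if k3 == -1:
                break
            if not 0 <= k3 < n:
                raise OxDnaError(f"strand {sid}: n3 index {k3} out of range")
            k = k3
        if len(order_5to3) != len(rows):
            raise OxDnaError(f"strand {sid}: n3/n5 chain does not cover the strand")

        strand = model.NaStrand(id=doc.allocate_id(),
                                naType="RNA" if rna else "DNA",
                                name=f"strand {sid}")
        prev_nt: model.Nucleotide | None = None
        for k in order_5to3:
            ox = sys.perNucleotide[k]
            frame = model.NucleotideFrame(
                backboneCenter=tuple((ox.com + BACKBONE_SITE_OFFSET * ox.a1) * SU_TO_ANGSTROM),
                nucleobaseCenter=tuple((ox.com + BASE_SITE_OFFSET * ox.a1) * SU_TO_ANGSTROM),
                baseNormal=tuple(ox.a3),
                hydrogenFaceDir=tuple(ox.a1))
            nt = model.Nucleotide(id=doc.allocate_id(), base=ox.base.upper(),
                                  altPositions=[frame])
            if prev_nt is not None:
                prev_nt.next = nt.id
                nt.prev = prev_nt.id
            strand.nucleotides.append(nt)
            prev_nt = nt
        strand.fivePrimeId = strand.nucleotides[0].id
        strand.threePrimeId = strand.nucleotides[-1].id
        st.naStrands.append(strand)
    doc.structures.append(st)
    return doc


# ---------------------------------------------------------------------------
# UNF -> oxDNA
# ---------------------------------------------------------------------------

def _fmt(x: float) -> str:
    return f"{x:.8f}"


def unf_to_oxdna(doc: UnfDocument, params: GeometryParams = DEFAULT_PARAMS
                 ) -> tuple[str, str]:
    """Export every nucleic strand of a document to classic oxDNA text.

    Each nucleotide is placed via the precedence rule (explicit frame if
    present, implicit lattice frame otherwise); the center of mass is the
    exact inverse of the import map, ``nucleobaseCenter/8.518 - 0.4 a1``.
    Base code "N" has no oxDNA letter and is emitted as "T" with a warning;
    protein chains have no record in the classic format and are skipped.
    """
    strands = [s for st in doc.structures for s in st.naStrands if s.nucleotides]
    if any(st.aaChains for st in doc.structures):
        log.warning("protein chains are not representable in classic oxDNA "
                    "files and were skipped")
    rows = []  # (strand_number, base, com, a1, a3) in topology order (3'->5')
    emitted_n = False
    n_bb_deviations = 0
    for snum, strand in enumerate(strands, start=1):
        order = model.walk_strand(strand)
        for nt in reversed(order):  # classic dialect lists 3'->5'
            frame = resolve_nucleotide_position(doc, nt.id, params)
            a1 = np.asarray(frame.hydrogenFaceDir, float)
            a3 = np.asarray(frame.baseNormal, float)
            nb = np.asarray(frame.nucleobaseCenter, float)
            com = angstrom_to_su(nb) - BASE_SITE_OFFSET * a1
            implied_bb = (com + BACKBONE_SITE_OFFSET * a1) * SU_TO_ANGSTROM
            if np.linalg.norm(implied_bb - np.asarray(frame.backboneCenter)) > 0.5:
                n_bb_deviations += 1
            base = nt.base
            if base == "N":
                base = "T"
                if not emitted_n:
                    log.warning('base "N" has no oxDNA letter; emitting "T"')
                    emitted_n = True
            rows.append((snum, base, com, a1, a3))

    if n_bb_deviations:
        log.warning("%d nucleotides store a backbone center deviating >0.5 A "
                    "from the oxDNA site; the base-center relation wins on "
                    "export", n_bb_deviations)
    n = len(rows)
    top_lines = [f"{n} {len(strands)}"]
    for k, (snum, base, _, _, _) in enumerate(rows):
        n3 = k - 1 if k > 0 and rows[k - 1][0] == snum else -1
        n5 = k + 1 if k + 1 < n and rows[k + 1][0] == snum else -1
        top_lines.append(f"{snum} {base} {n3} {n5}")
    topology = "\n".join(top_lines) + "\n"

    if doc.simulationBox is not None:
        box = np.asarray(doc.simulationBox, float) / SU_TO_ANGSTROM
    elif rows:
        pts = np.array([com for _, _, com, _, _ in rows])
        box = pts.max(axis=0) - pts.min(axis=0) + BOX_PADDING_SU
    else:
        box = np.full(3, BOX_PADDING_SU)
    conf_lines = ["t = 0",
                  f"b = {_fmt(box[0])} {_fmt(box[1])} {_fmt(box[2])}",
                  "E = 0 0 0"]
    for _, _, com, a1, a3 in rows:
        vals = list(com) + list(a1) + list(a3) + [0.0] * 6
        conf_lines.append(" ".join(_fmt(v) for v in vals))
    configuration = "\n".join(conf_lines) + "\n"
    return topology, configuration
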