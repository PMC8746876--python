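"""Ideal B-form helix geometry for lattice-referenced nucleotides.

Multilayer origami designs store most nucleotides only as references from
lattice cells; their 3D coordinates are implied by the lattice arrangement
(square or honeycomb), the cell index along the helix, and canonical B-form
duplex geometry (~3.4 A rise, ~34 deg twist per base pair). This module
computes those implicit coarse-grained frames and implements the precedence
rule: an explicit ``altPositions`` record on a nucleotide always wins over
the lattice-derived frame.

Conventions: helices run along +z in lattice-local coordinates, cell index
increasing with z. The lattice is placed in the world by intrinsic X-Y-Z
Euler rotations (degrees) followed by a translation. Lengths are Angstrom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import (
    AmbiguousPlacementError,
    GeometryError,
    UnplaceableNucleotideError,
)
from .model import (
    Cell,
    Lattice,
    NucleotideFrame,
    UnfDocument,
    VirtualHelix,
)

FIVE_TO_THREE = "fiveToThree"
THREE_TO_FIVE = "threeToFive"

#: Twist per base pair chosen so crossover periodicity matches Cadnano:
#: 32 bp = 3 full turns on the square lattice, 21 bp = 2 turns on honeycomb.
SQUARE_TWIST_DEG = 33.75
HONEYCOMB_TWIST_DEG = 360.0 * 2.0 / 21.0


@dataclass(frozen=True)
class GeometryParams:
    """Tunable B-form geometry (Angstrom / degrees).

    interhelix_spacing
        Center-to-center distance between neighboring lattice helices
        (2 nm helix diameter plus a 0.5 nm gap).
    rise_per_bp
        Axial rise per base pair.
    twist_per_bp
        Helical twist per base pair; ``None`` selects the lattice-matched
        default (33.75 deg square, 360*2/21 deg honeycomb).
    initial_angle
        Global phase offset added to every helix.
    backbone_radius / base_radius
        Radial distance of backbone and nucleobase centers from the axis.
    groove_offset
        Extra angular offset of the complementary strand; 0 places paired
        backbones diametrically opposite (no minor-groove asymmetry).
    """

    interhelix_spacing: float = 25.0
    rise_per_bp: float = 3.4
    twist_per_bp: float | None = None
    initial_angle: float = 0.0
    backbone_radius: float = 6.0
    base_radius: float = 1.7
    groove_offset: float = 0.0

    def __post_init__(self):
        for name in ("interhelix_spacing", "rise_per_bp", "backbone_radius", "base_radius"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"GeometryParams.{name} must be positive")

    def twist_for(self, lattice_type: str) -> float:
        if self.twist_per_bp is not None:
            return self.twist_per_bp
        if lattice_type == "square":
            return SQUARE_TWIST_DEG
        if lattice_type == "honeycomb":
            return HONEYCOMB_TWIST_DEG
        raise GeometryError(f"unknown lattice type {lattice_type!r}")


DEFAULT_PARAMS = GeometryParams()


def lattice_point(lattice_type: str, row: int, col: int,
                  params: GeometryParams = DEFAULT_PARAMS) -> tuple[float, float]:
    """In-plane (x, y) position of a virtual helix axis, in Angstrom.

    Rows extend downward on screen in Cadnano, so y decreases with row in
    this right-handed frame. On the honeycomb lattice the (row+col) parity
    term produces the staggered two-site motif.
    """
    d = params.interhelix_spacing
    if lattice_type == "square":
        return (col * d, -row * d)
    if lattice_type == "honeycomb":
        r = d / 2.0
        x = math.sqrt(3.0) * r * col
        y = -r * (3.0 * row + ((row + col) % 2))
        return (x, y)
    raise GeometryError(f"unknown lattice type {lattice_type!r}")


def lattice_rotation(lattice: Lattice) -> Rotation:
    """World rotation of a lattice (intrinsic X-Y-Z Euler, degrees)."""
    return Rotation.from_euler("XYZ", lattice.orientation, degrees=True)


def helix_axis_position(lattice: Lattice, helix: VirtualHelix, cell_index: int,
                        params: GeometryParams = DEFAULT_PARAMS) -> np.ndarray:
    """World-space point on the helix axis at a given cell index."""
    x, y = lattice_point(lattice.type, helix.row, helix.col, params)
    local = np.array([x, y, cell_index * params.rise_per_bp])
    return lattice_rotation(lattice).apply(local) + np.asarray(lattice.position, float)


def implicit_frame(lattice: Lattice, helix: VirtualHelix, cell_index: int,
                   direction: str, sub_index: int = 0, sub_count: int = 1,
                   params: GeometryParams = DEFAULT_PARAMS) -> NucleotideFrame:
    """Coarse-grained frame of a lattice-implied nucleotide.

    ``direction`` names the strand the nucleotide belongs to
    (:data:`FIVE_TO_THREE` runs 5'->3' with increasing cell index).
    Insertion cells hold ``sub_count`` > 1 nucleotides per strand;
    ``sub_index`` interpolates them within the cell's axial slot, advancing
    twist fractionally so inserted bases wind smoothly.
    """
    if not 0 <= sub_index < sub_count:
        raise GeometryError(f"sub_index {sub_index} outside 0..{sub_count - 1}")
    if direction not in (FIVE_TO_THREE, THREE_TO_FIVE):
        raise GeometryError(f"unknown strand direction {direction!r}")
    twist = params.twist_for(lattice.type)
    t = cell_index + sub_index / sub_count
    theta = helix.initialAngle + params.initial_angle + t * twist
    if direction == THREE_TO_FIVE:
        theta += 180.0 + params.groove_offset
    th = math.radians(theta)
    a1_local = np.array([math.cos(th), math.sin(th), 0.0])
    # base stacking normal points 3'->5' along the axis for each strand
    a3_local = np.array([0.0, 0.0, -1.0 if direction == FIVE_TO_THREE else 1.0])
    x, y = lattice_point(lattice.type, helix.row, helix.col, params)
    axis_local = np.array([x, y, t * params.rise_per_bp])
    rot = lattice_rotation(lattice)
    t_world = np.asarray(lattice.position, float)
    axis = rot.apply(axis_local) + t_world
    a1 = rot.apply(a1_local)
    a3 = rot.apply(a3_local)
    return NucleotideFrame(
        backboneCenter=tuple(axis - params.backbone_radius * a1),
        nucleobaseCenter=tuple(axis - params.base_radius * a1),
        baseNormal=tuple(a3),
        hydrogenFaceDir=tuple(a1),
    )


def find_referencing_cell(doc: UnfDocument, nucleotide_id: int
                          ) -> list[tuple[Lattice, VirtualHelix, Cell, str, int, int]]:
    """All lattice cells referencing a nucleotide, with its slot within the
    cell as ``(direction, sub_index, sub_count)``.

    Cell arrays list nucleotides in their own strand's 5'->3' order; for the
    three-to-five strand that order runs against increasing z, so the axial
    sub-index is reversed.
    """
    hits = []
    for lat in doc.lattices:
        for vh in lat.virtualHelices:
            for cell in vh.cells:
                if nucleotide_id in cell.fiveToThreeNts:
                    k = cell.fiveToThreeNts.index(nucleotide_id)
                    hits.append((lat, vh, cell, FIVE_TO_THREE, k,
                                 len(cell.fiveToThreeNts)))
                if nucleotide_id in cell.threeToFiveNts:
                    m = len(cell.threeToFiveNts)
                    k = cell.threeToFiveNts.index(nucleotide_id)
                    hits.append((lat, vh, cell, THREE_TO_FIVE, m - 1 - k, m))
    return hits


def resolve_nucleotide_position(doc: UnfDocument, nucleotide_id: int,
                                params: GeometryParams = DEFAULT_PARAMS
                                ) -> NucleotideFrame:
    """Spatial frame of a nucleotide under the precedence rule.

    An explicit position record (``altPositions[0]``) always takes
    precedence over the lattice-based representation; only nucleotides
    without explicit records fall back to the implicit B-form frame of the
    unique cell referencing them.
    """
    nt = None
    for st in doc.structures:
        for strand in st.naStrands:
            for cand in strand.nucleotides:
                if cand.id == nucleotide_id:
                    nt = cand
                    break
    if nt is None:
        raise UnplaceableNucleotideError(f"no nucleotide with id {nucleotide_id}")
    if nt.altPositions:
        return nt.altPositions[0]
    hits = find_referencing_cell(doc, nucleotide_id)
    if not hits:
        raise UnplaceableNucleotideError(
            f"nucleotide {nucleotide_id} has neither explicit positions nor a lattice cell")
    if len(hits) > 1:
        raise AmbiguousPlacementError(
            f"nucleotide {nucleotide_id} referenced by {len(hits)} cells")
    lat, vh, cell, direction, sub_index, sub_count = hits[0]
    return implicit_frame(lat, vh, cell.index, direction, sub_index, sub_count, params)


def with_twist(params: GeometryParams, twist: float) -> GeometryParams:
    """Convenience copy-with-override used by the CLI."""
    return replace(params, twist_per_bp=twist)
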