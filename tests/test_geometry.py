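"""Lattice geometry: B-form frames, rigid-motion equivariance, precedence."""

import math

import numpy as np
import pytest

from unf import geometry, model
from unf.errors import (
    AmbiguousPlacementError,
    GeometryError,
    UnplaceableNucleotideError,
)
from unf.geometry import (
    FIVE_TO_THREE,
    THREE_TO_FIVE,
    GeometryParams,
    implicit_frame,
    helix_axis_position,
    lattice_point,
    resolve_nucleotide_position,
)

from conftest import make_strand_doc

P = GeometryParams()


def _lattice(lt="square", position=(0, 0, 0), orientation=(0, 0, 0)):
    lat = model.Lattice(id=1000, type=lt, position=position, orientation=orientation)
    vh = model.VirtualHelix(id=1001, row=0, col=0)
    lat.virtualHelices.append(vh)
    return lat, vh


class TestLatticePoint:
    def test_square_origin(self):
        assert lattice_point("square", 0, 0, P) == (0.0, 0.0)

    def test_square_formula(self):
        assert lattice_point("square", 1, 2, P) == (50.0, -25.0)

    def test_honeycomb_formula(self):
        x, y = lattice_point("honeycomb", 0, 1, P)
        assert x == pytest.approx(math.sqrt(3) * 12.5)
        assert y == pytest.approx(-12.5)

    def test_unknown_lattice(self):
        with pytest.raises(GeometryError):
            lattice_point("hexagonal", 0, 0, P)


class TestHelixAxis:
    def test_identity_lattice_index_zero(self):
        lat, vh = _lattice()
        assert np.allclose(helix_axis_position(lat, vh, 0, P), [0, 0, 0])

    def test_consecutive_indices_separated_by_rise(self):
        lat, vh = _lattice(orientation=(20, -35, 110), position=(5, 6, 7))
        for i in range(4):
            d = np.linalg.norm(helix_axis_position(lat, vh, i + 1, P)
                               - helix_axis_position(lat, vh, i, P))
            assert d == pytest.approx(P.rise_per_bp, abs=1e-12)

    def test_translation_equivariance(self):
        lat, vh = _lattice()
        lat2, vh2 = _lattice(position=(10, -20, 30))
        for i in (0, 3, 7):
            shift = helix_axis_position(lat2, vh2, i, P) - helix_axis_position(lat, vh, i, P)
            assert np.allclose(shift, [10, -20, 30], atol=1e-12)


class TestImplicitFrame:
    def test_reference_direction_at_origin(self):
        lat, vh = _lattice()
        fr = implicit_frame(lat, vh, 0, FIVE_TO_THREE, params=P)
        assert np.allclose(fr.hydrogenFaceDir, [1, 0, 0], atol=1e-12)
        assert np.dot(fr.hydrogenFaceDir, fr.baseNormal) == pytest.approx(0, abs=1e-12)

    def test_paired_frames_antiparallel(self):
        lat, vh = _lattice()
        f = implicit_frame(lat, vh, 5, FIVE_TO_THREE, params=P)
        t = implicit_frame(lat, vh, 5, THREE_TO_FIVE, params=P)
        assert np.dot(f.hydrogenFaceDir, t.hydrogenFaceDir) == pytest.approx(-1)
        assert np.dot(f.baseNormal, t.baseNormal) == pytest.approx(-1)

    def test_successive_cells_rotated_by_twist(self):
        lat, vh = _lattice()
        a = implicit_frame(lat, vh, 3, FIVE_TO_THREE, params=P).hydrogenFaceDir
        b = implicit_frame(lat, vh, 4, FIVE_TO_THREE, params=P).hydrogenFaceDir
        ang = math.degrees(math.acos(np.clip(np.dot(a, b), -1, 1)))
        assert ang == pytest.approx(P.twist_for("square"), abs=1e-9)

    def test_honeycomb_twist_matches_21bp_periodicity(self):
        assert 21 * P.twist_for("honeycomb") == pytest.approx(720.0)

    def test_frames_orthonormal_under_rotation(self):
        lat, vh = _lattice(orientation=(31, 47, -12))
        for i in range(6):
            for d in (FIVE_TO_THREE, THREE_TO_FIVE):
                fr = implicit_frame(lat, vh, i, d, params=P)
                a1, a3 = np.array(fr.hydrogenFaceDir), np.array(fr.baseNormal)
                assert abs(np.linalg.norm(a1) - 1) < 1e-9
                assert abs(np.linalg.norm(a3) - 1) < 1e-9
                assert abs(np.dot(a1, a3)) < 1e-9

    def test_rigid_motion_equivariance(self):
        from scipy.spatial.transform import Rotation
        lat, vh = _lattice()
        lat2, vh2 = _lattice(position=(4, 5, 6), orientation=(10, 20, 30))
        R = Rotation.from_euler("XYZ", (10, 20, 30), degrees=True)
        base = implicit_frame(lat, vh, 2, FIVE_TO_THREE, params=P)
        moved = implicit_frame(lat2, vh2, 2, FIVE_TO_THREE, params=P)
        assert np.allclose(R.apply(base.backboneCenter) + [4, 5, 6],
                           moved.backboneCenter, atol=1e-9)
        assert np.allclose(R.apply(base.baseNormal), moved.baseNormal, atol=1e-9)

    def test_insertion_subframes_increase_in_z(self):
        lat, vh = _lattice()
        zs = [implicit_frame(lat, vh, 4, FIVE_TO_THREE, k, 3, P).nucleobaseCenter[2]
              for k in range(3)]
        assert zs == sorted(zs) and len(set(zs)) == 3
        lo = 4 * P.rise_per_bp
        hi = 5 * P.rise_per_bp
        assert all(lo <= z < hi for z in zs)

    def test_bad_subindex_rejected(self):
        lat, vh = _lattice()
        with pytest.raises(GeometryError):
            implicit_frame(lat, vh, 0, FIVE_TO_THREE, 3, 3, P)


class TestPrecedence:
    def _doc_with_lattice_nt(self, explicit):
        doc, strand = make_strand_doc("A", explicit_frames=explicit)
        nt = strand.nucleotides[0]
        lat = model.Lattice(id=doc.allocate_id(), type="square")
        vh = model.VirtualHelix(id=doc.allocate_id(), row=0, col=0)
        vh.cells.append(model.Cell(id=doc.allocate_id(), index=2,
                                   fiveToThreeNts=[nt.id]))
        lat.virtualHelices.append(vh)
        doc.lattices.append(lat)
        return doc, nt

    def test_explicit_positions_take_precedence(self):
        doc, nt = self._doc_with_lattice_nt(explicit=True)
        fr = resolve_nucleotide_position(doc, nt.id, P)
        assert fr == nt.altPositions[0]

    def test_lattice_fallback_when_no_explicit_frame(self):
        doc, nt = self._doc_with_lattice_nt(explicit=False)
        fr = resolve_nucleotide_position(doc, nt.id, P)
        # implicit frame of cell index 2 on the 5'->3' strand
        lat = doc.lattices[0]
        expected = implicit_frame(lat, lat.virtualHelices[0], 2, FIVE_TO_THREE, params=P)
        assert np.allclose(fr.nucleobaseCenter, expected.nucleobaseCenter)
        assert fr.nucleobaseCenter[2] == pytest.approx(2 * P.rise_per_bp)

    def test_free_floating_nucleotide_unplaceable(self):
        doc, strand = make_strand_doc("A", explicit_frames=False)
        with pytest.raises(UnplaceableNucleotideError):
            resolve_nucleotide_position(doc, strand.nucleotides[0].id, P)

    def test_double_reference_ambiguous(self):
        doc, nt = self._doc_with_lattice_nt(explicit=False)
        vh = doc.lattices[0].virtualHelices[0]
        vh.cells.append(model.Cell(id=doc.allocate_id(), index=3,
                                   threeToFiveNts=[nt.id]))
        with pytest.raises(AmbiguousPlacementError):
            resolve_nucleotide_position(doc, nt.id, P)


def test_invalid_params_rejected():
    with pytest.raises(GeometryError):
        GeometryParams(rise_per_bp=-1.0)
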