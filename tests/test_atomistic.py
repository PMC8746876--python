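"""Atomistic coarse-graining: classification, base frames, ligand bonds."""

import math

import numpy as np
import pytest

from unf import atomistic, model
from unf.atomistic import (
    ResidueAtom,
    ResidueRecord,
    base_normal,
    classify_residue,
    conect_pairs_from_pdb_text,
    hydrogen_face,
    ligand_from_residue,
    nucleotide_frame_from_atoms,
    pdb_to_unf,
    residues_from_pdb_text,
)
from unf.errors import ChainTypingError, GeometryError, IncompleteResidueError
from unf.fixtures import make_toy_duplex_pdb


def _res(name, atoms, chain="A", serial=1, hetero=False):
    return ResidueRecord(chainId=chain, serial=serial, name=name, isHetero=hetero,
                         atoms=[ResidueAtom(n, e, p) for n, e, p in atoms])


def _hexagon_residue(name="DT", ccw=True, z=0.0, extra=()):
    """Synthetic pyrimidine: regular hexagon ring in the xy-plane."""
    atoms = []
    names = ["N1", "C2", "N3", "C4", "C5", "C6"]
    for k, nm in enumerate(names):
        ang = math.radians(60 * k) * (1 if ccw else -1)
        atoms.append((nm, nm[0], (1.4 * math.cos(ang), 1.4 * math.sin(ang), z)))
    atoms.extend(extra)
    return _res(name, atoms)


class TestClassify:
    @pytest.mark.parametrize("name,expected", [
        ("DA", atomistic.DNA_NUCLEOTIDE),
        ("DT", atomistic.DNA_NUCLEOTIDE),
        ("U", atomistic.RNA_NUCLEOTIDE),
        ("HOH", atomistic.WATER),
        ("ALA", atomistic.AMINO_ACID),
        ("MSE", atomistic.AMINO_ACID),
    ])
    def test_standard_names(self, name, expected):
        assert classify_residue(_res(name, [])) == expected

    def test_o2prime_marks_rna(self):
        atoms = [("C1'", "C", (0, 0, 0)), ("C4'", "C", (1, 0, 0)),
                 ("O2'", "O", (2, 0, 0))]
        assert classify_residue(_res("G", atoms)) == atomistic.RNA_NUCLEOTIDE

    def test_sugar_without_o2prime_is_dna(self):
        atoms = [("C1'", "C", (0, 0, 0)), ("C4'", "C", (1, 0, 0)),
                 ("N1", "N", (2, 0, 0)), ("C2", "C", (3, 0, 0)),
                 ("N3", "N", (4, 0, 0))]
        assert classify_residue(_res("XXX", atoms)) == atomistic.DNA_NUCLEOTIDE

    def test_unnamed_hetero_is_ligand(self):
        assert classify_residue(_res("LIG", [("C1", "C", (0, 0, 0))],
                                     hetero=True)) == atomistic.LIGAND


class TestBaseNormal:
    def test_ccw_hexagon_gives_plus_z(self):
        res = _hexagon_residue(ccw=True)
        assert np.allclose(base_normal(res), [0, 0, 1], atol=1e-12)

    def test_reversed_order_flips_sign(self):
        res = _hexagon_residue(ccw=False)
        assert np.allclose(base_normal(res), [0, 0, -1], atol=1e-12)

    def test_collinear_ring_rejected(self):
        atoms = [(n, n[0], (float(k), 0.0, 0.0))
                 for k, n in enumerate(["N1", "C2", "N3", "C4", "C5", "C6"])]
        with pytest.raises(GeometryError):
            base_normal(_res("DT", atoms))

    def test_too_few_ring_atoms_rejected(self):
        with pytest.raises(IncompleteResidueError):
            base_normal(_res("DT", [("N1", "N", (0, 0, 0)), ("C2", "C", (1, 0, 0))]))


class TestHydrogenFace:
    def test_constructed_direction(self):
        # WC-edge atoms N3, C2, C4 displaced toward +x of the remaining ring
        atoms = [("N3", "N", (2, 0, 0)), ("C2", "C", (2, 1, 0)), ("C4", "C", (2, -1, 0)),
                 ("N1", "N", (-2, 1, 0)), ("C5", "C", (-2, -1, 0)), ("C6", "C", (-2, 0, 0))]
        res = _res("DC", atoms)
        a1 = hydrogen_face(res, np.array([0.0, 0.0, 1.0]))
        assert np.allclose(a1, [1, 0, 0], atol=1e-12)

    def test_orthogonality_exact_by_construction(self):
        res = _hexagon_residue(extra=[("O2", "O", (2.5, 0.1, 0.4))])
        a3 = base_normal(res)
        a1 = hydrogen_face(res, a3)
        assert abs(np.dot(a1, a3)) < 1e-12

    def test_guanine_template_a1_near_com_to_n1(self):
        res = [r for r in residues_from_pdb_text(make_toy_duplex_pdb("G"))
               if r.name == "DG"][0]
        a3 = base_normal(res)
        a1 = hydrogen_face(res, a3)
        com = np.array([a.position for a in atomistic._base_atoms(res)]).mean(axis=0)
        d = np.array(res.atom("N1").position) - com
        d -= np.dot(d, a3) * a3
        d /= np.linalg.norm(d)
        assert math.degrees(math.acos(np.clip(np.dot(a1, d), -1, 1))) < 5.0

    def test_missing_edge_atoms_rejected(self):
        res = _res("DC", [("N1", "N", (0, 0, 0))])
        with pytest.raises(IncompleteResidueError):
            hydrogen_face(res, np.array([0.0, 0.0, 1.0]))


class TestNucleotideFrame:
    def test_backbone_center_is_mean(self):
        res = _hexagon_residue(extra=[("P", "P", (0.0, 0.0, 0.0)),
                                      ("C1'", "C", (2.0, 0.0, 0.0))])
        fr = nucleotide_frame_from_atoms(res)
        assert fr.backboneCenter == (1.0, 0.0, 0.0)

    def test_base_center_matches_independent_mean(self):
        res = [r for r in residues_from_pdb_text(make_toy_duplex_pdb("T"))
               if r.chainId == "A"][0]
        fr = nucleotide_frame_from_atoms(res)
        expected = np.array([a.position for a in res.atoms
                             if a.name not in atomistic.BACKBONE_ATOMS]).mean(axis=0)
        assert np.allclose(fr.nucleobaseCenter, expected, atol=1e-12)

    def test_base_only_residue_rejected(self):
        with pytest.raises(IncompleteResidueError):
            nucleotide_frame_from_atoms(_hexagon_residue())


class TestLigands:
    def test_close_carbons_bonded_by_radius_rule(self):
        doc = model.new_document("d", "a")
        res = _res("LIG", [("C1", "C", (0, 0, 0)), ("C2", "C", (1.5, 0, 0))],
                   hetero=True)
        lig = ligand_from_residue(res, doc)
        assert lig.bonds == [(0, 1)]

    def test_distant_atoms_not_bonded(self):
        doc = model.new_document("d", "a")
        res = _res("LIG", [("C1", "C", (0, 0, 0)), ("C2", "C", (5.0, 0, 0))],
                   hetero=True)
        assert ligand_from_residue(res, doc).bonds == []

    def test_conect_overrides_distance(self):
        doc = model.new_document("d", "a")
        res = _res("LIG", [("C1", "C", (0, 0, 0)), ("C2", "C", (5.0, 0, 0))],
                   hetero=True)
        lig = ligand_from_residue(res, doc, conect=[(10, 11)],
                                  atom_serials={"C1": 10, "C2": 11})
        assert lig.bonds == [(0, 1)]

    def test_conect_parsing(self):
        text = "CONECT   10   11   12\nCONECT   11   10\n"
        assert conect_pairs_from_pdb_text(text) == [(10, 11), (10, 12)]


class TestPdbToUnf:
    def test_duplex_converts_to_two_valid_strands(self):
        residues = residues_from_pdb_text(make_toy_duplex_pdb("ACGT"))
        doc = pdb_to_unf(residues)
        strands = doc.structures[0].naStrands
        assert [len(s.nucleotides) for s in strands] == [4, 4]
        assert [model.strand_sequence(s, doc) for s in strands] == ["ACGT", "ACGT"[::-1].translate(str.maketrans("ACGT", "TGCA"))]
        assert [f for f in model.validate(doc) if f.severity == "error"] == []

    def test_amino_positions_are_exact_ca_coordinates(self):
        cas = [(1.25, -2.5, 3.125), (4.0, 5.5, -6.75), (7.0, 8.0, 9.0)]
        residues = [_res("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", p),
                                 ("C", "C", (1, 1, 1))], chain="P", serial=k + 1)
                    for k, p in enumerate(cas)]
        doc = pdb_to_unf(residues)
        chain = doc.structures[0].aaChains[0]
        assert [aa.position for aa in chain.aminoAcids] == cas
        assert model.walk_chain(chain)[0].id == chain.nTermId

    def test_mixed_content_file(self):
        residues = residues_from_pdb_text(make_toy_duplex_pdb("AC"))
        residues += [
            _res("GLY", [("N", "N", (0, 0, 50)), ("CA", "C", (1, 0, 50)),
                         ("C", "C", (2, 0, 50))], chain="P"),
            _res("HOH", [("O", "O", (9, 9, 9))], chain="W", hetero=True),
        ]
        doc = pdb_to_unf(residues)
        st = doc.structures[0]
        assert len(st.aaChains) == 1
        assert len(st.naStrands) >= 1
        total = (sum(len(s.nucleotides) for s in st.naStrands)
                 + sum(len(c.aminoAcids) for c in st.aaChains)
                 + len(doc.molecules.ligands))
        assert total == len(residues) - 1  # only the water dropped

    def test_mixed_chain_rejected(self):
        residues = [
            _res("ALA", [("N", "N", (0, 0, 0)), ("CA", "C", (1, 0, 0)),
                         ("C", "C", (2, 0, 0))], chain="X", serial=1),
            residues_from_pdb_text(make_toy_duplex_pdb("A"))[0],
        ]
        residues[1].chainId = "X"
        with pytest.raises(ChainTypingError):
            pdb_to_unf(residues)

    def test_rna_strand_labeled_rna(self):
        residues = residues_from_pdb_text(make_toy_duplex_pdb("AC"))
        chain_a = [r for r in residues if r.chainId == "A"]
        for r in chain_a:
            r.name = {"DA": "A", "DC": "C"}[r.name]
            r.atoms.append(ResidueAtom("O2'", "O", (2.5, -2.0, 0.0)))
        doc = pdb_to_unf(chain_a)
        assert doc.structures[0].naStrands[0].naType == "RNA"
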