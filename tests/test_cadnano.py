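"""Cadnano bridge: routing reconstruction, cuts, multiplicities, round trips."""

import random

import pytest

from unf import model
from unf.cadnano import (
    CadnanoDesign,
    CadnanoInput,
    RoutedPath,
    SCAFFOLD,
    STAPLE,
    VStrand,
    apply_loops_skips,
    cadnano_to_unf,
    color_hex_to_int,
    color_int_to_hex,
    cut_circular,
    design_to_json,
    parse_cadnano,
    trace_strands,
    unf_to_cadnano,
)
from unf.errors import CadnanoError, DegeneratePathError
from unf.fixtures import FixtureSpec, make_toy_cadnano, random_fixture_spec


def _empty_vstrand(num, n=8):
    return VStrand(num=num, row=num, col=0,
                   scaf=[[-1, -1, -1, -1] for _ in range(n)],
                   stap=[[-1, -1, -1, -1] for _ in range(n)],
                   skip=[0] * n, loop=[0] * n)


def _design_single_helix_staple():
    """One helix, 4 contiguous staple tuples at indices 2..5 (5'->3')."""
    vs = _empty_vstrand(0)
    cells = [(0, i) for i in range(2, 6)]
    for k, (h, i) in enumerate(cells):
        t = vs.stap[i]
        if k > 0:
            t[0], t[1] = cells[k - 1]
        if k < len(cells) - 1:
            t[2], t[3] = cells[k + 1]
    return CadnanoDesign(name="one-helix", vstrands=[vs])


def _design_two_helix_crossover():
    """8-cell staple: helix 0 indices 0..3, crossover, helix 1 indices 3..0."""
    v0, v1 = _empty_vstrand(0), _empty_vstrand(1)
    cells = [(0, 0), (0, 1), (0, 2), (0, 3), (1, 3), (1, 2), (1, 1), (1, 0)]
    for k, (h, i) in enumerate(cells):
        t = (v0 if h == 0 else v1).stap[i]
        if k > 0:
            t[0], t[1] = cells[k - 1]
        if k < len(cells) - 1:
            t[2], t[3] = cells[k + 1]
    return CadnanoDesign(name="two-helix", vstrands=[v0, v1]), cells


class TestTraceStrands:
    def test_single_helix_staple_run(self):
        paths = trace_strands(_design_single_helix_staple(), STAPLE)
        assert len(paths) == 1
        assert paths[0].cells == [(0, i) for i in range(2, 6)]
        assert not paths[0].isCircular

    def test_two_helix_crossover_followed_in_tuple_order(self):
        design, cells = _design_two_helix_crossover()
        paths = trace_strands(design, STAPLE)
        assert len(paths) == 1
        # pointer-walk oracle: follow the 3' tuple entries by hand
        pos = (0, 0)
        oracle = [pos]
        while True:
            t = design.helix(pos[0]).stap[pos[1]]
            if t[2] == -1 and t[3] == -1:
                break
            pos = (t[2], t[3])
            oracle.append(pos)
        assert paths[0].cells == oracle == cells

    def test_circular_scaffold_flagged(self):
        vs = _empty_vstrand(0, n=4)
        cells = [(0, 0), (0, 1), (0, 2), (0, 3)]
        for k, (h, i) in enumerate(cells):
            vs.scaf[i][0], vs.scaf[i][1] = cells[(k - 1) % 4]
            vs.scaf[i][2], vs.scaf[i][3] = cells[(k + 1) % 4]
        paths = trace_strands(CadnanoDesign(vstrands=[vs]), SCAFFOLD)
        assert len(paths) == 1 and paths[0].isCircular

    def test_dangling_pointer_raises(self):
        vs = _empty_vstrand(0)
        vs.stap[0] = [-1, -1, 0, 7]  # index 7 is empty
        with pytest.raises(CadnanoError, match="empty cell"):
            trace_strands(CadnanoDesign(vstrands=[vs]), STAPLE)


class TestCutCircular:
    def test_cut_at_min_lex_cell(self):
        path = RoutedPath(SCAFFOLD, [(0, 3), (0, 2), (0, 1), (0, 0)], isCircular=True)
        cut = cut_circular(path)
        assert cut.cells[0] == (0, 0)
        assert cut.cells == [(0, 0), (0, 3), (0, 2), (0, 1)]
        assert not cut.isCircular

    def test_linear_path_rejected(self):
        with pytest.raises(DegeneratePathError):
            cut_circular(RoutedPath(SCAFFOLD, [(0, 0), (0, 1)], isCircular=False))

    def test_degenerate_length_rejected(self):
        with pytest.raises(DegeneratePathError):
            cut_circular(RoutedPath(SCAFFOLD, [(0, 0)], isCircular=True))

    def test_cut_deterministic_over_rotations(self):
        cells = [(1, 5), (0, 9), (0, 2), (1, 1)]
        cuts = {tuple(cut_circular(RoutedPath(SCAFFOLD, cells[k:] + cells[:k],
                                              isCircular=True)).cells)
                for k in range(4)}
        assert len(cuts) == 1


class TestLoopsSkips:
    def _design(self):
        design = _design_single_helix_staple()
        return design

    @pytest.mark.parametrize("skip,loop,mult", [
        (0, 0, 1), (-1, 0, 0), (0, 2, 3), (0, 1, 2),
    ])
    def test_multiplicity(self, skip, loop, mult):
        design = self._design()
        design.vstrands[0].skip[3] = skip
        design.vstrands[0].loop[3] = loop
        out = apply_loops_skips(trace_strands(design, STAPLE)[0], design)
        assert dict(out)[(0, 3)] == mult

    def test_conflicting_skip_and_loop(self):
        design = self._design()
        design.vstrands[0].skip[3] = -1
        design.vstrands[0].loop[3] = 1
        with pytest.raises(CadnanoError, match="both skip and loop"):
            apply_loops_skips(trace_strands(design, STAPLE)[0], design)


class TestColors:
    def test_decimal_to_hex(self):
        assert color_int_to_hex(13369344) == "#CC0000"

    def test_hex_to_decimal_inverse(self):
        for v in (0, 13369344, 0xFFFFFF, 0x00CC66):
            assert color_hex_to_int(color_int_to_hex(v)) == v


class TestCadnanoToUnf:
    def test_n_inputs_n_lattices_n_structures(self):
        inputs = [CadnanoInput(design=make_toy_cadnano(FixtureSpec(seed=k)))
                  for k in range(2)]
        doc = cadnano_to_unf(inputs)
        assert len(doc.lattices) == 2
        assert len(doc.structures) == 2

    def test_staple_color_transferred(self):
        spec = FixtureSpec(colors=[13369344], seed=1)
        doc = cadnano_to_unf([CadnanoInput(design=make_toy_cadnano(spec))])
        staples = [s for st in doc.structures for s in st.naStrands
                   if not s.isScaffold]
        assert staples and all(s.color == "#CC0000" for s in staples)

    def test_loop_and_skip_change_nucleotide_count(self):
        base_spec = FixtureSpec(nHelices=2, cellsPerHelix=32, staples="straight")
        mod_spec = FixtureSpec(nHelices=2, cellsPerHelix=32, staples="straight",
                               loops=[(0, 10, 1)], skips=[(0, 20)])
        count = lambda doc: sum(len(s.nucleotides)
                                for st in doc.structures for s in st.naStrands)
        n_base = count(cadnano_to_unf([CadnanoInput(design=make_toy_cadnano(base_spec))]))
        n_mod = count(cadnano_to_unf([CadnanoInput(design=make_toy_cadnano(mod_spec))]))
        # both modifier cells carry scaffold + staple: +2 for the loop, -2 for the skip
        assert n_mod == n_base + 2 - 2
        # and the multiplicity ledger balances exactly per strand kind
        design = make_toy_cadnano(mod_spec)
        doc = cadnano_to_unf([CadnanoInput(design=design)])
        for kind in (SCAFFOLD, STAPLE):
            expected = 0
            for path in trace_strands(design, kind):
                from unf.cadnano import cut_circular as cc
                if path.isCircular:
                    path = cc(path)
                expected += sum(m for _, m in apply_loops_skips(path, design))
            got = sum(len(s.nucleotides) for st in doc.structures
                      for s in st.naStrands if s.isScaffold == (kind == SCAFFOLD))
            assert got == expected

    def test_insertion_cells_reference_n_plus_one(self, toy_doc):
        cells = [c for lat in toy_doc.lattices for vh in lat.virtualHelices
                 for c in vh.cells]
        insertions = [c for c in cells if c.type == "insertion"]
        deletions = [c for c in cells if c.type == "deletion"]
        assert insertions and deletions
        for c in insertions:  # fixture loop has n = 1
            assert len(c.fiveToThreeNts) == 2
            assert len(c.threeToFiveNts) == 2
        for c in deletions:
            assert c.fiveToThreeNts == [] and c.threeToFiveNts == []

    def test_conversion_output_validates(self, toy_doc):
        assert [f for f in model.validate(toy_doc) if f.severity == "error"] == []

    def test_scaffold_sequence_assignment(self):
        spec = FixtureSpec(nHelices=2, cellsPerHelix=32, staples="straight")
        seq = "ACGT" * 16  # 64 nt scaffold
        doc = cadnano_to_unf([CadnanoInput(design=make_toy_cadnano(spec),
                                           scaffoldSequence=seq)])
        scaffold = [s for st in doc.structures for s in st.naStrands if s.isScaffold][0]
        assert model.strand_sequence(scaffold, doc) == seq
        assert len(model.strand_sequence(scaffold, doc)) == 64
        # paired staple bases are complementary
        nts = {nt.id: nt for st in doc.structures for s in st.naStrands
               for nt in s.nucleotides}
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        for nt in scaffold.nucleotides:
            if nt.pair != -1:
                assert nts[nt.pair].base == comp[nt.base]


class TestUnfToCadnano:
    def test_round_trip_identity(self, rng):
        for _ in range(25):
            spec = random_fixture_spec(rng)
            design = make_toy_cadnano(spec)
            doc = cadnano_to_unf([CadnanoInput(design=design,
                                               latticeType=spec.latticeType)])
            back = unf_to_cadnano(doc)
            assert len(back) == 1
            for vs1, vs2 in zip(design.vstrands, back[0].vstrands):
                assert vs1.scaf == vs2.scaf
                assert vs1.stap == vs2.stap
                assert vs1.skip == vs2.skip
                assert vs1.loop == vs2.loop
                assert vs1.stap_colors == vs2.stap_colors

    def test_free_form_structure_ignored(self, caplog):
        from conftest import make_strand_doc
        doc, _ = make_strand_doc("ACGT", explicit_frames=True)
        import logging
        with caplog.at_level(logging.WARNING, logger="unf.cadnano"):
            designs = unf_to_cadnano(doc)
        assert designs == []
        assert any("not representable" in r.message for r in caplog.records)

    def test_empty_lattice_gives_zero_vstrands(self):
        doc = model.new_document("d", "a")
        doc.lattices.append(model.Lattice(id=doc.allocate_id(), type="square"))
        designs = unf_to_cadnano(doc)
        assert len(designs) == 1 and designs[0].vstrands == []

    def test_same_circular_design_converts_identically(self):
        spec = FixtureSpec(circularScaffold=True, seed=5)
        docs = [cadnano_to_unf([CadnanoInput(design=make_toy_cadnano(spec))])
                for _ in range(2)]
        from unf.io import doc_to_dict
        d0, d1 = (doc_to_dict(d) for d in docs)
        d0["creationDate"] = d1["creationDate"] = ""
        assert d0 == d1


class TestJsonDialect:
    def test_parse_writes_back_identically(self, toy_design):
        text = design_to_json(toy_design)
        design2 = parse_cadnano(text)
        assert design_to_json(design2) == text
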