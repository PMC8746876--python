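"""Shared builders for the test suite. All fixtures are generated in memory."""

from __future__ import annotations

import random

import pytest

from unf import model
from unf.cadnano import CadnanoInput, cadnano_to_unf
from unf.fixtures import FixtureSpec, make_toy_cadnano


def make_strand_doc(bases: str = "ACG", explicit_frames: bool = False
                    ) -> tuple[model.UnfDocument, model.NaStrand]:
    """Document with one linear strand spelling ``bases`` 5'->3'."""
    doc = model.new_document("test", "suite")
    st = model.Structure(id=doc.allocate_id(), name="s")
    strand = model.NaStrand(id=doc.allocate_id(), name="strand")
    prev = None
    for k, b in enumerate(bases):
        nt = model.Nucleotide(id=doc.allocate_id(), base=b)
        if explicit_frames:
            nt.altPositions = [model.NucleotideFrame(
                backboneCenter=(6.0, 0.0, k * 3.4),
                nucleobaseCenter=(1.7, 0.0, k * 3.4),
                baseNormal=(0.0, 0.0, 1.0),
                hydrogenFaceDir=(1.0, 0.0, 0.0))]
        if prev is not None:
            prev.next = nt.id
            nt.prev = prev.id
        strand.nucleotides.append(nt)
        prev = nt
    strand.fivePrimeId = strand.nucleotides[0].id
    strand.threePrimeId = strand.nucleotides[-1].id
    st.naStrands.append(strand)
    doc.structures.append(st)
    return doc, strand


@pytest.fixture
def strand_doc():
    return make_strand_doc("ACG")


@pytest.fixture
def toy_design():
    """Deterministic 2-helix toy origami with one skip and one loop."""
    return make_toy_cadnano(FixtureSpec(
        nHelices=2, cellsPerHelix=32, skips=[(0, 6)], loops=[(1, 12, 1)],
        staples="straight", seed=7))


@pytest.fixture
def toy_doc(toy_design):
    return cadnano_to_unf([CadnanoInput(design=toy_design)])


@pytest.fixture
def rng():
    return random.Random(20260101)
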