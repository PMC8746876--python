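# unf — Unified Nanotechnology Format toolkit

A Python library and `unf` command-line tool implementing the Unified
Nanotechnology Format (UNF) v1.0: a coarse-grained, JSON-based file format
for DNA, RNA and protein nanostructures that stores design data (multilayer
origami lattices) and structural data (free-form strands, alpha-carbon
protein chains, ligands) in a single document, together with bidirectional
converters to and from Cadnano and oxDNA and a coarse-grainer for atomistic
PDB/mmCIF structures.

## Who this is for

DNA/RNA nanotechnology groups move designs between tools that do not share
a format: Cadnano for lattice-based origami design, oxDNA/oxView for
coarse-grained simulation and free-form editing, PDB/mmCIF for atomistic
structures. UNF is the interchange hub: one document can hold several
origami lattices with their world placement, free-form coarse-grained
strands, protein chains, small-molecule ligands, and embedded copies of the
original atomistic files, MD5-checked.

## The model

Each nucleotide is a rigid body described by **four vectors**: the backbone
center of mass, the nucleobase center of mass, the base-plane normal
**a3** (stacking direction) and the hydrogen-face direction **a1**
(toward the Watson–Crick edge), with |a1| = |a3| = 1 and a1 ⊥ a3. This
extends the oxDNA convention — which stores a single center of mass — by
splitting backbone and base sites; the two are related through the oxDNA1
site offsets (1 simulation unit = 8.518 Å):

```
nucleobaseCenter = (com + 0.4 a1) · 8.518 Å
backboneCenter   = (com − 0.4 a1) · 8.518 Å
```

Amino acids are single beads at their alpha-carbon position. Lattice-based
designs store nucleotides as references from virtual-helix **cells**
(normal / insertion / deletion — Cadnano's loops and skips; an insertion of
length n references n+1 nucleotides per crossing strand). Nucleotides
without explicit coordinates get an implicit frame from ideal B-form
geometry (3.4 Å rise; 33.75°/bp twist on the square lattice, 360·2/21° on
honeycomb, matching Cadnano crossover periodicity); explicit position
records always take precedence over the lattice.

A UNF file is a JSON body (layout documented in
`src/unf/schema/unf-1.0.json`) optionally followed by appended payloads,
each introduced by a `#INCLUDED_FILE <id>;<filename>` marker line and
integrity-checked against the MD5 hash recorded in the body.

## Worked example

Generate a toy 4-helix origami, convert it to UNF, inspect it, and export
it for oxDNA simulation:

```
$ unf fixtures cadnano --out design.json --helices 4 --cells 32
wrote design.json
$ unf cadnano2unf design.json:square -o design.unf
wrote design.unf: 1 lattices, 1 structures
$ unf info design.unf
UNF 1.0  name='cadnano import'  author=''
lattices: 1  structures: 1
nucleotides: 240  amino acids: 0  ligands: 0
external files: 0 (0 embedded)
$ unf validate design.unf
design.unf: OK (0 warnings)
$ unf unf2oxdna design.unf -o design
WARNING unf.oxdna: base "N" has no oxDNA letter; emitting "T"
wrote design.top and design.dat
$ head -3 design.top
240 5
1 T -1 1
1 T 0 2
```

The 4×32 serpentine carries a 128-nt circular scaffold (cut at a
deterministic location on conversion) plus four 28-nt staples: 240
nucleotides in 5 strands. The oxDNA topology lists them 3'→5' in the
classic dialect; bases are "N" (no sequence was assigned — pass
`--scaffold-seq` to set one), emitted as "T" with a warning. The same
document converts back with `unf unf2cadnano design.unf -o outdir/`,
reproducing the original routing, skip/loop and color arrays exactly.

Library use mirrors the CLI:

```python
from unf import load, validate, strand_sequence
doc, attachments = load("design.unf")
print([f"{s.name}: {len(s.nucleotides)} nt"
       for st in doc.structures for s in st.naStrands])
```

## Scope

The web-based UNF Viewer GUI, converters for other design tools
(scadnano, Tiamat, vHelix, Adenita, MagicDNA), UNF→all-atom
reconstruction, trajectory handling and oxView scene files are out of
scope. See `docs/methods.md` for the geometric conventions, parameter
defaults and known limitations.
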