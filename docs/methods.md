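# Methods and design notes

This note records the conventions, numeric choices and limitations behind
the toolkit, in the order data flows through it.

## Document model and validation

All objects carry document-wide unique non-negative integer IDs; `-1` is
the "none" sentinel. The version field is stored as text (`"1.0"`), never
a number, so lexical comparisons like `"1.10"` vs `"1.9"` cannot be
mis-ordered; the reader accepts any `1.x` body. Default units are Ångström
and degrees, and every internal computation uses them. Orientations are
intrinsic X-then-Y-then-Z Euler rotations in degrees (the format only
requires that *some* convention be recorded; this one matches
`scipy.spatial.transform.Rotation.from_euler("XYZ", ..., degrees=True)`).
Timestamps are ISO-8601 UTC; colors are uppercase `#RRGGBB`.

The validator (`unf.model.validate`) reports findings instead of raising:
duplicate IDs, dangling references, asymmetric base pairing, inconsistent
prev/next links, 5'→3' walks that do not cover a strand, cell-array
violations (deletion cells referencing nucleotides, normal cells with more
than one per direction, insertions with fewer than two), duplicated
(row, col) helix positions, and non-orthonormal frames (tolerance 1e-6).
Modification codes are free text — the standard vocabulary for nucleic and
amino acid modifications is not pinned down by the format, so nothing is
rejected. Comments attach to exactly one object ID.

The JSON field layout is documented in `src/unf/schema/unf-1.0.json`
(JSON Schema 2020-12). It describes shapes only; cross-reference and
topology invariants live in the validator, which can see the whole
document.

## Container format

A container is the JSON body plus, per embedded file, a marker line
`#INCLUDED_FILE <fileId>;<filename>`, the raw payload bytes, and one
terminating newline (which doubles as the separator before the next
marker). The marker dialect is this implementation's own and is isolated
behind a single constant so it can be swapped if another implementation
settles on different text. Two parsing decisions make the container
binary-safe:

* the JSON boundary is found by string- and escape-aware brace balancing,
  never by scanning for the marker, so string values may contain the
  marker text verbatim;
* payload boundaries are ambiguous if a payload itself contains a
  marker-like line, so the reader backtracks over all candidate splits and
  keeps the one maximizing MD5 matches against the recorded hashes
  (deterministically the earliest split on ties). With realistic payloads
  the first candidate wins immediately.

Hashes are MD5 over the exact embedded bytes — no newline normalization —
so `write ∘ read ∘ write = write` byte-for-byte.

## Lattice geometry

Implicit nucleotide frames use ideal B-form geometry. Defaults
(`GeometryParams`): interhelix spacing d = 25 Å (2 nm helix diameter plus
a 0.5 nm gap), rise 3.4 Å/bp, twist 33.75°/bp on the square lattice
(32 bp = 3 turns) and 360·2/21 ≈ 34.286°/bp on honeycomb (21 bp = 2
turns), matching Cadnano's crossover periodicity; backbone radius 6.0 Å
and base radius 1.7 Å from the helix axis; groove offset γ = 0, i.e.
paired backbones diametrically opposed — a deliberate simplification
(real B-DNA has ~±60° minor-groove asymmetry); all values are
configurable. Square lattice: (x, y) = (col·d, −row·d); honeycomb with
r = d/2: x = √3·r·col, y = −r·(3·row + (row+col mod 2)). Rows extend
downward on Cadnano's screen, hence the negated y in this right-handed
frame.

For cell index i and sub-index k of an insertion holding m nucleotides,
the phase is θ = θ₀ + (i + k/m)·Δθ and the axial offset (i + k/m)·rise, so
inserted bases wind and rise smoothly inside their cell's slot. The a1
vector is (cos θ, sin θ, 0) for the strand running 5'→3' with increasing
index and is rotated by 180° + γ for the complement; a3 points 3'→5'
along the helix axis for each strand (antiparallel between partners).
Deletion cells consume a cell index — they keep lattice registration —
but emit no frames. Cell arrays list nucleotides in their own strand's
5'→3' order, so for the three-to-five array the axial sub-index is the
reverse of the list position.

Precedence: `resolve_nucleotide_position` returns `altPositions[0]` when
present, otherwise the implicit frame of the unique referencing cell;
no frame and no cell is an error, as is reference by more than one cell.

## Cadnano bridge

Cadnano stores per-cell 4-tuples `[h5, i5, h3, i3]`; strand routing is
reconstructed by walking 3' pointers from each 5' end (`h5 = i5 = -1`),
with remaining occupied tuples collected as circular paths. Circular
strands are cut so the 5' end lands on the lexicographically smallest
(helixNum, baseIndex) cell — deterministic and independent of traversal
order. Cut strands are recorded under `misc["cadnanoCircularStrands"]`
so the reverse conversion can close the routing again; `misc` is the
format's sanctioned spot for application data that must not break other
readers.

Cell direction (which of the two per-cell arrays a nucleotide joins) is
derived from the actual traversal — the neighboring path cell on the same
helix — falling back to Cadnano's even/odd helix parity only for
single-cell fragments. Pairing joins scaffold and staple nucleotides
sharing a cell, matched by axial slot. Colors: Cadnano's decimal integers
convert to `#RRGGBB`; a color attaches to the staple whose 5' end sits at
the recorded base index and is re-emitted on the 5'-end helix, sorted by
index. Bases default to `N`; an optional scaffold sequence is assigned
5'→3' with paired staples complemented (Cadnano keeps sequences in a
separate CSV, outside the design file).

On export, one Cadnano design is written per lattice (arrays padded to
the lattice block size, 32 for square and 21 for honeycomb); helix
numbers reuse the stored `designNumber`, else are assigned by checkerboard
parity of (row, col). Deletion cells are re-inserted into each strand's
routing wherever its nucleotide path jumps more than one index on a
helix. Consequence: a deletion at a strand terminus or immediately across
a crossover is not reconstructible (the cell model stores no routing for
it), so the fixture generator only places skips and loops on interior
straight runs — the same constraint a designer faces when UNF is the
interchange medium. Free-form structures and molecules are ignored with a
warning; Cadnano cannot express them.

## Atomistic coarse-graining

Classification: standard residue names first (amino acids incl. MSE/SEC,
DA/DC/DG/DT, A/C/G/U, HOH/WAT as water); nonstandard residues with sugar
atoms (C1', C4') and at least part of a base ring are typed by the ribose
O2' atom — present means RNA. Chains mixing nucleic and amino residues
are rejected; strand type (DNA/RNA) is the majority classification.
Residues are assumed listed 5'→3' / N→C; only the first model is read and
only blank/"A" altlocs; `O5*`-style names are normalized to primes.

Frame recipe (the format defers the exact atom recipe to implementations;
this one is isolated in module constants for substitution):

* a3 = normalize(Σᵢ vᵢ × vᵢ₊₁) over the cyclically ordered ring atoms
  (purines N1,C2,N3,C4,C5,C6,N7,C8,N9; pyrimidines N1..C6), vᵢ relative
  to the base center; the listed order fixes the sign, and the sum is
  translation-invariant (it equals twice the polygon's vector area).
* a1 = the direction from the base center to the centroid of the
  Watson–Crick edge atoms (purines {N1,C2,C6}, pyrimidines {N3,C2,C4}),
  projected perpendicular to a3 — orthogonal by construction.
* Backbone center = unweighted mean of the present sugar-phosphate atoms
  (P, OP1/2, O5', C5', C4', O4', C3', O3', C2', C1', O2'); base center =
  unweighted mean of everything else heavy (ring plus exocyclic).
  Unweighted rather than mass-weighted: the difference is well under the
  coarse-graining length scale and the convention is simpler to state.

Amino acids copy the alpha-carbon coordinate bit-exactly. Non-water
hetero residues become ligands with explicit atoms and bonds: CONECT
records when present, else a covalent-radius heuristic (bonded iff
distance ≤ rA + rB + 0.4 Å). Waters and unclassifiable residues are
dropped with a logged count. PDB/mmCIF parsing is delegated to gemmi.

## oxDNA bridge

Classic dialect only: topology header `N Ns`, one `strand base n3 n5`
line per nucleotide listed 3'→5' per strand; the newer 5'→3' dialect is
rejected with a pointed error. Configurations accept 9 or 15+ columns
(velocities zero-filled); orientation vectors off unit length by more
than 1e-3 are renormalized with a warning. Import splits the single
center of mass into the two UNF centers via the ±0.4 su site offsets;
export inverts through the base-center relation,
com = nucleobaseCenter/8.518 − 0.4·a1, and warns (once, with a count)
when stored backbone centers deviate more than 0.5 Å from the implied
site — lattice-implied frames do, by ~2.5 Å, because UNF's backbone
radius is a design choice independent of oxDNA's site geometry. Base `N`
is emitted as `T` with a warning; protein chains have no record in the
classic format and are skipped.

Unit conversion: ×8.518 to Ångström. Multiplication by 8.518 is not
injective on IEEE doubles (~4% of values share a rounded product with a
neighbor), so a bit-exact inverse cannot exist for all inputs; the
Å→su direction applies a one-ulp correction that restores exactness
wherever the forward map is injective and is within one ulp otherwise —
the information-theoretic optimum. Pipeline round trips recover com/a1/a3
far inside the 1e-6 su tolerance.

## Synthetic fixtures

`unf.fixtures` generates every test input in memory:

* **Cadnano designs** — serpentine scaffolds over an even number of
  helices (circular or linear), two staple patterns (per-helix straight
  runs, or paired-helix staples with one crossover each), seeded staple
  colors, and skips/loops restricted to interior straight runs (see the
  Cadnano section for why). These emulate multilayer square/honeycomb
  origami at toy scale (2–8 helices, ≤ 64 cells).
* **Atomistic duplexes** — idealized B-form duplexes built from planar
  base templates (hexagon ring of radius 1.4 Å; purine pentagon placed so
  the cyclic ring traversal keeps positive signed area, giving all bases
  a consistent +z template normal) with a compact off-plane backbone
  cluster, wound at 36°/3.4 Å and written through gemmi as PDB text.
  They are geometrically exact for what the coarse-grainer measures
  (planarity, means, orthogonality) and chemically idealized in every
  other respect — bond lengths, sugar pucker and groove geometry are not
  realistic, so passing tests certify the coarse-graining math, not
  fidelity to crystal structures.
* **oxDNA duplexes** — ideal antiparallel helices (35°/bp, 0.4 su rise,
  0.6 su radius) with seeded positional jitter, printed at 8 decimals in
  the classic dialect.

All generators are deterministic functions of their spec and seed.

## Problem sizes and limitations

The test suite and acceptance script run toy sizes throughout: 100
randomized designs of 2–8 helices for the round-trip property, ≤ 10 bp
duplexes, 12 container trials with payloads under 150 bytes — each chosen
as the smallest size that exercises every code path (crossovers, circular
cuts, both lattice types, insertions and deletions co-occurring, 0–3
attachments). The format itself has no size limit, but this
implementation holds documents in memory and does not stream
multi-gigabyte containers.

Known limitations: no oxDNA2 a2-dependent backbone sites, no trajectory
(multi-frame) handling, no sequence CSV emission for Cadnano, no
cadnano2.5/scadnano dialects, no UNF→all-atom reconstruction, no
side-chain orientations for proteins (single-bead chains only), and the
minor-groove offset defaults to the symmetric simplification noted above.
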