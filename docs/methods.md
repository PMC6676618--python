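# Methods

## Model

A molecule's conformational flexibility lives almost entirely in its
rotatable bonds: acyclic single bonds between two non-terminal heavy
atoms. Cutting all of them partitions the heavy atoms into *rigid
fragments* — ring systems, conjugated cores, functional groups — whose
internal geometry is essentially transferable between molecules. The
package therefore treats 3D structure generation as a lookup-and-stitch
problem: store one experimental geometry per distinct rigid fragment,
and assemble a query molecule from those stored geometries plus simple
valence rules for whatever is left.

Amide C(=O)–N bonds are treated as rigid by default (their partial
double-bond character keeps amides planar), with an `amide_rotatable`
switch for sensitivity analysis. The rotatable-bond definition itself is
a convention, not a law; the one above is the common cheminformatics
default.

### Fragment keys

A fragment is keyed by the canonical SMILES of its induced subgraph with
every severed bond replaced by an implicit hydrogen — no attachment-point
dummy atoms, so the key is the plain canonical string of the standalone
molecule the fragment depicts. One canonicalization engine (RDKit) is
used for both library build and query, because canonical SMILES is
engine-specific and keys must never cross dialects. Two details matter:

- The canonical atom order is recorded alongside the key. Stored
  coordinates are serialized in that order, which is what lets a
  template's rows be transferred onto the atoms of any query fragment
  with the same key.
- When a cut removes a reference atom of a double bond's cis/trans
  descriptor, that descriptor is dropped before canonicalization: the
  hydrogen cap carries no stereo label, and keeping a dangling
  descriptor would make build-side and query-side keys disagree.

### Library

A fragment with ≥ `min_atoms` (default 5, heavy atoms) enters the
library once its key has occurred ≥ `min_count` (default 3) times in the
corpus, every occurrence counting (including several within one
molecule; `count_per_molecule` switches to the per-molecule variant).
The stored geometry is always the first occurrence in corpus stream
order — a deliberately simple policy that makes the stored record
independent of later corpus content; consensus/averaged geometries are
an explicit non-goal. Geometries with any interatomic distance below
0.5 Å are rejected as collapsed.

On disk: text records (`<key> <n_atoms> <count>` header, one
`<element> <x> <y> <z>` line per atom at 4 decimal places, blank-line
separated) plus an index of `<key>\t<byte_offset>` lines. Four decimals
(1e-4 Å) sit far below any geometric tolerance used anywhere in the
package. Loading without the index falls back to one linear scan;
lookups afterwards are byte-offset seeks either way, and the two paths
are contractually identical (tested exhaustively on fixture libraries).

The generic-ring tier is a small built-in list of SMARTS patterns with
idealized coordinates: planar aromatic 5/6-rings (bond 1.39 Å), planar
3/4-rings, an envelope cyclopentane, a chair cyclohexane (internal
angles 111°), and 7–18-membered regular polygons with alternating
±0.25 Å pucker. Templates are tried in list order; a match must cover
all ring atoms of the fragment *and* realize every ring bond as a
template bond (so a fused bicyclic cannot pass itself off as its
perimeter macrocycle). Matched atoms take template coordinates with the
query's own elements; unmatched exocyclic atoms go to the rule builder.
Tier order is fixed at exact-then-generic. An external template file can
be loaded in place of the built-ins.

### Stitching

The query is traversed depth-first from atom 0, neighbors in ascending
input index — a pure convention whose only job is determinism. Placement
of a fragment with template geometry is one rigid motion fixed by three
choices:

1. the new bond's length is the sum of single-bond covalent radii
   (C 0.76, N 0.71, O 0.66, H 0.31, S 1.05 Å, …) scaled by bond order
   (single 1.00, aromatic 0.915, double 0.87, triple 0.78 — factors that
   reproduce benzene ≈ 1.39 Å, ethene ≈ 1.32 Å, ethyne ≈ 1.19 Å from
   the carbon radius);
2. its direction is the first open valence direction of the anchor atom,
   from idealized hybridization shells: sp linear (180°), sp² trigonal
   planar (120°), sp³ tetrahedral (109.47°), with hybridization
   perceived from the graph alone (triple bond or two doubles → sp;
   aromatic or one double → sp²; otherwise sp³ for common organic
   elements);
3. the remaining spin about the bond axis is set to an anti (180°)
   torsion against the already-built chain. The anti convention is a
   design choice: some explicit deterministic rule is needed, extended
   chains are the generic low-energy shape, and it makes outputs
   bit-reproducible. It is also the main known source of torsion error —
   real inter-fragment dihedrals are frequently not anti.

Rule-placed single atoms follow the same length/direction/torsion rules.
The first atom of a molecule sits at the origin, and fresh valence
shells are oriented with their first direction along +z, fixing the
global frame. Fragment rigidity is exact up to floating-point rotation
error (intra-fragment distances preserved to ~1e-12 relative; the
contract tested is 1e-6).

Bonds never traversed during placement are ring closures; each is
measured and flagged when longer than 1.5× ideal. Flagging is
deliberate: a macrocycle stitched from small-ring templates placed one
by one cannot close properly, and the package reports that honestly
rather than hiding it behind a local fix. Repair belongs to a
downstream optimizer.

Hydrogens are placed last, on the remaining open valence directions at
ideal H–X lengths; sp³ shells always offer four directions, so e.g.
water gets its two hydrogens at the tetrahedral 109.47°.

### Stereochemistry enforcement

The build path ignores stereo declarations entirely; a final pass
compares the geometry's perceived descriptors with the declared ones on
an identically-ordered molecule (equivalent to comparing signed volumes,
but robust to neighbor-order conventions) and repairs mismatches:

- Tetrahedral centers: the two substituent branches with the fewest
  downstream atoms (preferring branches free of other declared centers)
  are swapped by reflection through the local bisector plane — an
  isometry, so bond lengths survive. When the center is ring-locked and
  branches overlap, the two cheapest substituent *atoms* swap positions
  instead; parity flips at the cost of local distortion, which is
  logged.
- Double bonds: the smaller side rotates 180° about the bond axis; a
  ring double bond falls back to swapping one end's substituents.

Corrections are counted in the build report so regressions are visible;
genuinely uncorrectable centers are logged, not silently accepted.

## Evaluation metrics

- **Heavy-atom RMSD**: minimum over optimal rigid superposition (SVD
  least squares, proper rotations only) and over graph isomorphisms
  (capped at 10⁴, identity fallback with a warning), so symmetric rings
  and differing atom orders are not over-penalized. An identity-mapping
  mode exists for comparison; symmetry-aware ≤ identity always.
- **Internal coordinates**: mean |Δ| over all bonds, all bonded triples,
  and all bonded heavy-atom quadruples, torsions compared circularly
  into [0, 180°]. Averaging over *all* quadruples (not just rotatable
  bonds) is a declared choice; it makes the number a property of the
  whole geometry rather than of a rotor list.
- **TFD**: the standard torsion fingerprint deviation (hydrogen-free,
  distance-weighted, symmetry-minimized, in [0, 1]); molecules with no
  scorable torsion are defined as 0 with a logged note.
- **Stereo success**: InChIKey of the input SMILES vs. InChIKey of the
  generated structure with stereo re-perceived from 3D. Batch means are
  computed over stereo-successful molecules only (a flag includes
  failures for sensitivity analysis), with the success rate reported
  separately.

## Synthetic data

The fixture module supplies ten molecules with hard-coded analytic
coordinates (regular hexagon benzene at 1.39 Å, ideal chair cyclohexane,
planar all-anti butane, a 12-membered planar carbocycle, an ideal
tetrahedral CHFClBr, …) rather than toolkit-embedded conformers, so
ground truth is independent of any generation engine. The corpus
builder replicates them with seeded Gaussian jitter applied only to
copies after the first, making the first-conformer policy directly
observable. The stereo suite is 34 SMILES covering single and multiple
R/S centers, cis/trans and conjugated double bonds, ring and ring-fused
centers and a stereogenic macrocycle; ring entries carry exocyclic
substituents where possible so parity corrections stay local.

What passing on these fixtures shows: the bookkeeping (keys, ordering,
serialization, tier logic, stereo enforcement) and the geometric
contracts are exact. What it does not show: accuracy on real, flexible,
drug-like molecules — fixture fragments are mined from the very
geometries being regenerated, so RMSD-level results on external corpora
are a separate empirical question requiring real crystallographic data.

## Numerical choices and degenerate inputs

- Coordinates are float64 throughout; stored records round to 1e-4 Å.
- Rotation alignment handles the antiparallel case by a 180° rotation
  about a deterministic perpendicular; near-linear neighbor pairs in
  valence completion fall back to a deterministic auxiliary frame
  (global +x, or +y when nearly parallel to x).
- Ties everywhere (DFS neighbor order, anchor choice, torsion reference
  atoms, template order) break by atom index or list order; there is no
  randomness anywhere in the build path, and repeated runs are
  byte-identical.
- Multi-component SMILES are rejected at parse time; unparsable batch
  entries yield per-molecule error records, never a batch abort; corpus
  molecules without coordinates are skipped with a warning; an empty
  library serializes and loads as valid empty files.

## Problem sizes

The shipped tests and the acceptance script run on the fixture corpus
(10 molecules × 3 copies), the 34-entry stereo suite, 50 randomized
negative lookup probes and 100 randomized rigid transforms — sizes
chosen so the whole suite completes in seconds while still exercising
every code path; all thresholds above are independent of these counts.

## Known limitations

- Inter-fragment torsions are always anti; no torsion-preference model.
- One conformer per fragment key (first seen), one output conformer per
  query; no ensemble generation.
- Macrocycles assembled from small rings get flagged long closures by
  construction; no distance-geometry or optimizer fallback is built in.
- Ring-locked stereocenters may be repaired by a distorting atom swap or
  remain uncorrectable (logged).
- Hypervalent and organometallic centers fall outside the sp/sp²/sp³
  direction model and get tetrahedral-fallback geometry.
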