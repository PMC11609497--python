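# Methods

This note records the model behind molkit's design, the numerical choices,
what the synthetic data does and does not emulate, and the known limits.

## Data model and access-kind contracts

All trajectory analysis here is organized around three entities: a
**Topology** (time-independent atom identities: names, residues, chains,
masses, optional bonds), a **State** (one frame: N x 3 coordinates in nm,
an optional triclinic box, time in ps) and a **Selection** (a sorted index
set viewing a subset of atoms through a shared Topology + State pair).
Selections hold no atom data; reads and writes go through the shared
storage, so a change made through one selection is immediately visible to
every overlapping one.

Shared mutable views are safe only under discipline, and that discipline is
made explicit as an **access kind** chosen when a `System` is created.  The
kind fixes three properties of every selection derived from the system:

| kind              | access     | may overlap | validity check |
|-------------------|------------|-------------|----------------|
| MutableSerial     | read/write | yes         | none           |
| BuilderSerial     | read/write | yes         | per access     |
| ImmutableParallel | read only  | yes         | none           |
| MutableParallel   | read/write | **no**      | none           |

- Serial kinds are pinned to the worker that created them (the parallel
  driver refuses tasks declaring them when more than one worker is
  requested).
- `BuilderSerial` is the only kind whose system accepts structural edits
  (`add_atoms` / `delete_atoms`).  Validity is tracked with a generation
  counter rather than per-index bounds checks: after a deletion the
  remaining atoms are re-indexed, so a surviving bound check could silently
  address the *wrong* atom — staleness of every pre-existing selection is
  the only safe contract.  Appends do not bump the generation because they
  cannot invalidate an existing index.
- `MutableParallel` selections are kept pairwise disjoint by a per-system
  **used-index registry**: creation claims the index set atomically with
  the disjointness test under one lock, destruction releases it.  The cost
  is paid only at creation/destruction; using a live selection does no
  registry work.

Python cannot enforce the "exclusive control" hand-off of Topology/State
into a System; it is a documented contract, and writing through retained
outside references is undefined behavior of the library.

### Sub-selections

Narrowing an existing selection comes in three forms with different
lifetime rules: `subselect` (one child, parent kept alive),
`split_fragments` (a partition keyed by a user function, parent kept
alive) and `into_fragments` (the same partition, parent consumed before
any fragment is handed out).  Only fragmentation is available on
`MutableParallel` selections: a live parent coexisting with its children
would violate disjointness.  For that kind the registry swaps the parent's
claim for the fragments' claims in one indivisible step, so no concurrent
claimant can grab those indices in between.

## Geometry

- **Periodic box**: a 3 x 3 row-vector matrix in the Gromacs
  lower-triangular convention (a along +x, b in xy); arbitrary input boxes
  are rotated into this form on ingestion, giving a unique representation.
  Minimum image is exact per-axis rounding for orthorhombic boxes; for
  triclinic boxes the rounded image is refined over the 27 neighbor
  lattice translations, which is exact for any box whose tilt obeys the
  usual simulation conventions.
- **Kabsch superposition**: weighted covariance SVD with determinant
  correction (the sign of the smallest singular direction is flipped when
  the optimal orthogonal map is a reflection), so the returned rotation is
  always proper.  Fewer than 3 atoms is an error; collinear inputs have a
  non-unique rotation but still return a valid minimizer.
- **PBC-aware center of mass**: per-axis circular mean in fractional
  coordinates (map to angles, average mass-weighted unit vectors, map the
  mean angle back).  Chosen over unwrap-then-average because it needs no
  bond information; it is meaningful only for clusters smaller than about
  half the box, which covers the within-cutoff use case it serves.
- **unwrap**: chain rule along selection index order — each atom is moved
  to the image nearest its predecessor, starting from an anchor atom.
  Branched molecules whose index order jumps spatially may not be made
  whole; bond-graph unwrapping is out of scope.
- **Neighbor search**: a cell list with cell edge >= cutoff (measured as
  perpendicular heights for triclinic cells), scanning the 27 cells around
  each query cell; distances are evaluated with the exact minimum image,
  and ties at the cutoff are included (`<=`).  When the cutoff exceeds
  half the smallest box height the grid assumption fails and the search
  falls back to a brute-force minimum-image scan with a logged warning.
  Triclinic grids are built in fractional space; optimizing them further
  was deliberately not attempted.
- **SASA**: Shrake–Rupley quadrature with a golden-spiral point set
  (default 960 points) on each atom's probe-expanded sphere (Bondi vdW
  radii, probe 0.14 nm ~ water).  A numeric quadrature was chosen over an
  analytic power-diagram method; its error is controlled by the point
  count (~0.4% worst case against the two-sphere closed form at 960
  points) and acceptance is against closed-form spheres.  Periodic images
  are ignored; compute SASA on whole molecules.  Unknown elements raise
  rather than defaulting silently.

## File formats

Lengths are nm and times ps internally (Gromacs convention); PDB/XYZ/DCD
store Angstrom and are converted at the boundary.  PDB is fixed-column
v3.3 (ATOM/HETATM/CRYST1/MODEL), 1e-3 A precision; serials are renumbered
on write, resids preserved verbatim; masses are assigned from an element
table because PDB has no mass field (unknown elements get 12.0 amu with a
warning).  DCD is the CHARMM dialect (optional unit-cell record of six
float64, float32 coordinates, auto-detected endianness); every frame has
the same byte length, so `read_frame(i)` is a constant-time seek — the
random-access reader contract that also makes frame-parallel work
practical.  Multi-model PDB and multi-frame XYZ satisfy the same contract.
An adapter hook (`register_reader`) accepts external backends (e.g. XTC);
no compression codec is bundled.  TPR/GRO/mmCIF are out of scope.

## Frame-parallel execution

`analyze_trajectory` specifies a contract, not a concurrency primitive:
every worker owns a private reader, a private State buffer and a private
System replica (Topology shared read-only), frames are dealt round-robin,
and partial results are returned densely indexed by frame.  Determinism
follows: any reduction the caller performs over the ordered result list is
independent of the worker count, which the acceptance checks assert to
byte equality on CSV output.  `process_fragments` covers the orthogonal
axis — within-frame parallelism over disjoint MutableParallel fragments of
one selection writing a single shared State, sound because of registry
disjointness.

## Synthetic data

The generator builds self-avoiding-ish random-walk polymer chains (0.15 nm
steps, 0.08 nm clash tolerance against recent atoms) with realistic field
values — backbone names N/CA/C/O plus side-chain dummies, cycling residue
names, per-chain letters, element-derived masses — inside a cubic box.
Geometric realism (secondary structure, packing, solvent) is deliberately
absent: every operation tested (superposition, distance queries, centers,
I/O, parallel scheduling) depends on particle density and bookkeeping, not
on protein-like geometry.  Consequently passing tests demonstrate
correctness of the algorithms and contracts, not fidelity on real force
fields or exotic PDB dialects.

Trajectories carry exact ground truth: rigid mode writes per-frame
rotation + translation transforms to a JSON manifest (frame 0 equals the
input), brownian mode accumulates Gaussian steps of width sigma, mixed
adds noise to the rigid motion.  Fixed seeds reproduce files bit-for-bit.
The standard test sizes are a 21-atom unit fixture and a 4,320-atom x
100-frame system (4 chains x 135 residues x 8 atoms), the package's
down-scaled analog of a small production trajectory; both were chosen so
the full suite exercises every code path at molecular-like density while
staying quick to regenerate.

## Defaults worth knowing

| parameter | default | why |
|---|---|---|
| probe radius | 0.14 nm | water-sized probe, the field's convention |
| SASA points | 960 | ~0.4% two-sphere error; linear cost in points |
| `within` tie rule | `<=` | inclusive cutoff, documented and tested |
| within-self | included | `within r of (E)` keeps E's atoms |
| fit weighting | mass-weighted | matches common RMSD-tool behavior |
| trajectory dt | 1 ps | synthetic frames are evenly spaced |

## Known limitations

- Selection keywords are the minimal set above; no chemistry macros
  (`protein`, `backbone`), no bond-connectivity splitting.
- The circular-mean COM degrades for clusters comparable to the box size.
- SASA ignores periodicity and has quadrature error ~O(1/n_points).
- DCD velocities, fixed-atom blocks and 64-bit marker variants are not
  supported; XTC needs an external adapter.
- Thread-based workers share the GIL: the parallel driver's purpose is the
  safety/determinism contract (and I/O overlap), not linear speedups on
  pure-Python inner loops.
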