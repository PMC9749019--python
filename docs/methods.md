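# Methods

This note documents the models, numerical choices, and limitations of
lrdock, and what the synthetic-data generators do and do not emulate.

## Units and constants

Lengths in Å, energies in kJ/mol, charges in elementary units, temperature
in Kelvin; `k_B = 0.0083144621 kJ mol⁻¹ K⁻¹` and the Coulomb constant
`k_e = 1389.35458 kJ mol⁻¹ Å e⁻²` (GROMACS-compatible energy units with
crystallographic lengths). Lennard-Jones parameters are stored in the
GROMOS-native C6/C12 form; σ/ε table entries are converted via
`C6 = 4εσ⁶`, `C12 = 4εσ¹²`.

## Nonbonded model

Receptor–ligand pairs within a strict (`<`) 8 Å cutoff contribute

* vdW repulsion `C12/r¹²` and attraction `−C6/r⁶`, with per-pair
  coefficients from geometric combination `√(C6ᵢC6ⱼ)`, `√(C12ᵢC12ⱼ)`
  (GROMOS convention; Lorentz–Berthelot on σ/ε is available for
  Amber-style tables);
* a screened Coulomb term. The default dielectric is distance-dependent,
  `ε_r(r) = D·r` with `D = 4 Å⁻¹`, giving `E = k_e q_i q_j /(D r²)`; this
  is the most common implicit-water screening choice in docking, and the
  slope is configurable, as is a constant-ε alternative. The forces are the
  exact analytic derivatives of the implemented energies.

There is no switching or shifting at the cutoff: the potential is truncated
and therefore discontinuous at 8 Å. This is a deliberate fidelity-over-
smoothness choice; the energy–force consistency tests keep probe pairs away
from the boundary. Pair distances are clamped at 1e-6 Å so degenerate
synthetic inputs cannot overflow the kernel. Summation is deterministic
(ascending ligand index per receptor atom), so repeated evaluations are
bit-identical and replays reproduce energies exactly.

The three components (vdW repulsive, vdW attractive, electrostatic) can be
masked individually; the full report is the exact sum of the three
single-component reports.

### Neighbor search

A regular cell grid (cell size defaulting to the cutoff, so a query scans
at most 27 cells) is built once over the ligand in its local frame.
Receptor atoms are transformed into that frame for queries; rigid ligand
moves therefore never rebuild the grid. The strict `<` cutoff convention is
shared between the grid path and the brute-force definition, so both agree
on the exact pair set — this is property-tested against O(N·M) loops.

## Collision detection

* **Force mode** (required for flexible receptors): collision iff
  `|ΣF| > threshold`, strictly. No canonical threshold exists for this
  scheme in the literature it derives from; the default of
  1000 kJ mol⁻¹ Å⁻¹ was chosen once as roughly an order of magnitude above
  thermal force scales and below hard-clash forces for small ligands. It is
  always configurable and recorded in session traces.
* **Overlap mode** (rigid docking): maximum interatomic penetration
  `max(R_i + R_j − d_ij)` over in-cutoff pairs, floored at zero, compared
  strictly against a tolerance (default 0 — any vdW overlap collides).
  Ties break toward the lowest (receptor, ligand) index pair.

## Linear response

The deformation of the receptor under ligand forces is
`Δr = β V_M Λ_M V_Mᵗ f(r_o + Δr)` with `β = 1/(k_B T)`. The product is
evaluated as three matrix–vector products; the 3N×3N response matrix is
never materialized.

**Relaxation.** The fixed point is found by damped iteration
`Δr ← (1−α)Δr + α·βVΛVᵗf(r_o + Δr)` from zero, stopping when the max-norm
change drops below tolerance. Defaults: α = 0.2, tolerance 1e-4 Å, 500
iterations — α = 0.2 damps the stiff short-range force gradients near
contact while converging in tens of iterations for typical scenes.
Non-convergence is flagged on the result (with the full per-iteration
trace), not raised. The procedure is deterministic: repeated relaxations of
the same pose are bit-identical, in contrast with steering a live MD
simulation.

**Model building.** The covariance of atomic fluctuations is plain
Cartesian (not mass-weighted) with 1/F normalization, computed after Kabsch
superposition of every frame onto the first (default on — otherwise
rigid-body motion dominates the spectrum). For F − 1 < 3N the eigenpairs
come from the F×F Gram matrix `XXᵗ/F`, avoiding the dense 3N×3N problem;
both routes are cross-checked in tests. `r_o` is the frame with minimal
RMSD to the ensemble mean (ties to the lowest index), and the model stores
the captured-fluctuation fraction `Σλ_{1..M}/tr(C)`. Degenerate eigenvalues
make individual eigenvectors solver-dependent, so tests compare subspace
projectors, not raw vectors.

**Frames.** Forces are computed in the world frame and rotated into the
receptor model frame by the inverse receptor rotation before entering the
response formula; the deformation lives in the model frame and is applied
before the receptor transform.

## Hydrogen bonds

A bond is a (donor, hydrogen, acceptor) triple with `d(H,A) < 2.5 Å` and
D–H···A angle `> 90°`, both strict; the angle is measured at the hydrogen
between the H→D and H→A directions with 180° = linear (the convention of
the underlying crystallographic survey — a naive reading that puts 0° at
linear would invert the criterion, so the convention is pinned by tests).
Donor/acceptor roles come from the parameter table plus an editable JSON
residue→atom→role map covering standard amino acids, nucleotides, water
and common sugar atoms; a hydrogen belongs to the nearest heavy atom within
1.25 Å (covalent X–H bonds are 0.95–1.1 Å), with CONECT records taking
precedence. Structures without hydrogens can dock rigidly but H-bond
detection raises an informative error — hydrogen placement is out of scope.

## Solvent-excluded surface

The SES is the probe-erosion of the solvent-accessible volume. The field
construction:

1. exact SAS signed distance `d_SAS(x) = min_i(|x−c_i| − R_i − p)` sampled
   on a regular grid (box = atom bounds padded by max radius + probe +
   2·spacing);
2. distance from interior nodes to the SAS exterior, estimated as
   `min_y(|x−y| − d_SAS(y))` over near-surface exterior nodes y (KD-tree,
   8 nearest), sharpened by the exact per-sphere lower bound
   `max_i(R_i + p − |x−c_i|)`. The bound is tight for isolated atoms (their
   SES is exactly the vdW sphere); the KD-tree term handles reentrant
   crevices. This subvoxel correction is what keeps the isolated-atom area
   error at ~0.3% at 0.375 Å spacing, versus ~20% for a binary
   distance transform at the same spacing;
3. `field = distance-to-exterior − p`, positive inside the SES.

Marching Cubes (the Lewiner variant, which resolves the ambiguous cases of
the classic 256-case table and yields edge-manifold meshes) triangulates
iso level 0 with linear edge interpolation. Normals are recomputed from the
geometry as area-weighted vertex normals, oriented out of the molecule.
Default spacings are 0.375 Å, falling back to 0.75 Å for large structures
(a node-count limit raises a MemoryError advising coarser spacing); the
default probe is 1.4 Å (water). Fields whose nodes land exactly on the iso
level can produce degenerate triangles; zero-area faces are dropped.

This distance-field construction agrees with offset-surface SES algorithms
at the zero set up to grid resolution but is not guaranteed identical in
deep crevices.

## Session layer

Moves are world-frame rigid increments to either molecule. Each proposal is
evaluated with the configured collision scheme at the candidate pose;
colliding moves are rejected with the prior state returned untouched (the
scripted analogue of an interactive tool freezing the molecules), accepted
flexible moves re-relax the deformation. Every attempt appends a JSON
record (step, molecule, delta rotation/translation, acceptance, component
energies, collision metric, H-bond count, monitored distances); the trace
is JSON-lines, streamable and replayable. Because the engine is
deterministic, a replay reproduces the transform history bit-identically.
A session with a response model refuses overlap collision mode at
construction, and a hot-swapped response model resets the deformation —
Δr is only meaningful in its own model's subspace.

## Synthetic data

The fixture generators are pure functions of their arguments and a seed:

* **Random clouds / toy pairs** place atoms uniformly with a minimum pair
  separation (default 2.0 Å, enforced across the receptor–ligand split
  too) and element-cycled fallback parameters. The separation emulates
  non-clashing heavy-atom packing; real nonbonded contacts are never
  closer. They emulate *geometry and chemistry scales*, not real molecular
  topology — there are no bonds, residues are placeholders, and charges
  are small cycled values.
* **Harmonic ensembles** draw frames `base + Σ √λ_m z_m v_m + noise` with
  planted directions projected orthogonal to the rigid-body subspace
  (the convention for physical internal modes, and necessary for recovery
  to be well-defined after Kabsch superposition). They emulate Gaussian
  equilibrium fluctuations only — no anharmonicity, no solvent, no
  mass-weighting.
* **H-bond geometries** are constructed exactly from (distance, angle).
* **The salt-bridge scene** is a four-atom receptor + one-atom ligand with
  a one-mode response model (λ = 0.3 Å², T = 300 K). The charged probe and
  acceptors keep small LJ parameters because a bare 1/r² Coulomb attraction
  has no stable equilibrium; the LJ core stabilizes contact at ~2.9 Å, a
  physically sensible salt-bridge distance. With electrostatics off a
  residual vdW attraction leaves ~0.03 Å of deformation, which is why the
  "returns to r_o" assertion uses a 0.1 Å tolerance.

Passing tests on these fixtures demonstrates algorithmic correctness
(oracle equivalence, analytic identities, parameter recovery), not accuracy
against real force fields or experimental structures.

## Problem sizes

The test suite and the acceptance script size their problems for a
single-CPU laptop-scale run: force-oracle checks use 30–200-atom fixtures,
ensemble recovery uses 30 atoms × 5000 frames × a few seeds, surfaces use
single atoms and 5 Å analytic spheres at 0.375/0.75 Å spacing, and sessions
run 100 moves on 28-atom scenes. Everything completes in seconds.

## Known limitations

* The bundled parameter table is a synthetic mini force field covering the
  fixture chemistry; real docking needs a user-supplied table derived from
  a published force field.
* The ligand is rigid; intramolecular (bonded) terms, hydrogen placement,
  and MD itself are out of scope.
* The truncated cutoff makes the energy discontinuous at 8 Å.
* The distance-dependent dielectric slope (4 Å⁻¹) and the force-collision
  threshold are documented defaults, not claims of fidelity to any
  particular interactive tool.
* The SES field is an approximation near deep reentrant crevices at coarse
  spacings.
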