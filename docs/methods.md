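# Methods

## The model

A peptide macrocycle is treated as a rigid-geometry torsion chain: bond
lengths (N–Cα 1.458, Cα–C′ 1.524, C′–N 1.329 Å), bond angles (121.7° at N,
111.2° at Cα, 116.2° at C′) and the peptide torsion ω = 180° are frozen at
ideal values, leaving the 2n torsions (φᵢ, ψᵢ) as the only degrees of
freedom. One local frame sits at each of the 3n backbone atoms (x toward
the next atom, y so the atom after next lies in the first xy quadrant);
stepping from one frame to the next costs a translation by the bond
length, an xy-plane rotation by (π − bond angle) and an about-x rotation
by the torsion. Because atom 3n+1 *is* atom 1, closure is the statement
that the accumulated frame transform is the identity, and the cyclic
error

    E_cyc = ‖q + M₁q + ⋯ + M₁⋯M_{n−1}q‖²
          + ‖M₁⋯M_n e₁ − e₁‖² + ‖M₁⋯M_n e₂ − e₂‖²

is a smooth non-negative function of the torsions that vanishes exactly on
closed rings. The origin term carries Å² and the axis terms are
dimensionless; they are summed without re-weighting. The set of closed
conformations is a smooth manifold of dimension 2n − 6 (nine residuals,
three of which are redundant at closure by the orthonormality of the frame
product).

Assumptions worth stating: ω is exactly trans (no cis-proline rings, no ω
relaxation); bond geometry never deviates from ideal (real relaxed
structures deviate by a few percent); carbonyl O and amide H are placed by
ideal planar rules (O: in the Cα–C′–N′ plane opposite N′, 1.231 Å, 120.1°;
H: anti-bisecting the C′–N–Cα angle in the peptide plane, 1.010 Å) and are
used only for H-bonds and RMSD.

## Closure solving

`close_backbone` finds the nearest closed conformation. When asked for a
*nearby* solution (recording, crossover/mutation repair) a first
trust-region least-squares pass augments the nine closure residuals with
weak displacement anchors (weight 0.02–0.05 per degree), which selects the
nearest manifold point of the underdetermined system; a damped Gauss–
Newton iteration with pseudo-inverse steps then drives E_cyc below
10⁻¹² · tolerance (quadratic tail, essentially free). A plain trust-region
solve is the fallback if Gauss–Newton stalls. Window-restricted solves
(`free_mask`) leave all torsions outside a chosen window untouched, which
is what makes crossover exchanges honest: the receiving parent's torsions
outside the window are bit-identical in the offspring.

## Energy model

The sampler is energy-agnostic; the packaged backbone energy is a
deliberately simple surrogate with every constant in one configurable
block (`EnergyParams`):

- pair terms act on heavy-atom pairs ≥ 4 covalent bonds apart on the
  *cyclic* bond graph (C′ of residue n bonds N of residue 1);
- repulsion/attraction: 12-6 Lennard-Jones split at its minimum
  (ε = 0.15 kcal/mol, radii N 1.55, C 1.70, O 1.52 Å, 6 Å cutoff);
- electrostatics: Coulomb with partial charges (N −0.47, H +0.31, C′
  +0.51, O −0.51, Cα +0.16 e) and distance-dependent dielectric ε_r = 10d;
- solvation: a Gaussian-overlap desolvation penalty for polar atom pairs;
- H-bonds: geometric detection (H⋯O < 2.5 Å, N–H⋯O > 120°) with energy
  ramping linearly to −1.5 kcal/mol at 2.2 Å / 150°; "strong" means
  ≤ −0.5 kcal/mol. The ramp plateaus were chosen so that
  ordinary helical-turn geometry (≈2.3 Å, ≈155°) counts as strong;
- Ramachandran term: bilinear lookup in a per-residue map (below);
- weighted total: E_total = 0.45·E_rama + E_rep + E_hbond + E_other.

This surrogate preserves the *algorithmic* behavior the pipeline needs
(cheap-first evaluation, monotone repulsion, chirality and rigid-motion
invariance); it is not a calibrated force field, and absolute energies are
not comparable to any published scale.

## Ramachandran maps and bins

Backbone sampling uses a permissive, symmetrized glycine map so that both
L- and D-residues are reachable. The packaged grids (10° nodes, plain
text, user-replaceable) are analytic approximations: a mixture of Gaussian
basins on the torus, −log-transformed, flattened (×0.25) and cut off; the
glycine basins sit at the six bin centers, making the map exactly
symmetric under (φ,ψ) → (−φ,−ψ). Two grid cells outside the allowed core
form a finite, penalized "soft margin" so that the small torsion drift
introduced by closure refinement and relaxation does not strand a residue
on an infinite-energy node; the genuinely forbidden interior stays
infinite. Per-residue maps obey the mirror rule (D map = point reflection
of the L map); proline's allowed area < generic < glycine.

The six bins are centered at (−61,−41), (61,41), (−135,135), (135,−135),
(−61,141), (61,−141) — a point-symmetric set with mirror partners
1↔2, 3↔4, 5↔6 — and membership is nearest-center under the toroidal
metric (disallowed queries fall back to nearest center, flagged). Bin
strings are compared modulo cyclic rotation; the canonical form is the
lexicographically smallest rotation (Booth's algorithm). The number of
rotation-unique assignments of 6 labels to an n-ring is
(1/n)·Σᵢ 6^gcd(i,n) — 39,996 for n = 7 — and enumeration yields exactly
one representative per class.

## Layered simulated annealing

Each step displaces every residue independently within a disk of radius
k_t (linear 40° → 0.5° over the run) in (φ,ψ) space; a residue whose
proposal lands outside its allowed map keeps its old torsions. The move
then passes layers in order — Ramachandran, repulsion, cyclic error,
H-bond, (misc for n ≤ 7) — each with the Metropolis rule: pass if the new
layer energy is below the current one or below the layer threshold,
otherwise with probability exp((E_cur − E_new)/T). Rejection at any layer
skips the rest. Defaults (per-layer threshold; T₀ → T_f, geometric):
rama 2n; 5 → 0.5 · rep 1n; 20 → 1 · cyclic 0.1; 10 → 0.005 ·
hbond −2; 2 → 0.3 · misc 0; 2 → 0.3, with 5000 steps and up to three
re-runs of unproductive starts. These numbers are this package's own
defaults, tuned once so that a desk-scale run (a few seconds per
trajectory, one CPU) records good backbones at a useful rate (roughly one
productive trajectory per ten bin-center starts at n = 7); they are
exposed per size class in `data/profiles.yaml`.

This is explicitly not a thermodynamic sampler: layering exists to find
low-energy closed states cheaply, not to draw from a Boltzmann ensemble.

Recording ("good backbone") requires, after refinement: E_cyc ≤ 0.01
(in practice ≪ 10⁻⁹), repulsion ≤ 0.5 kcal/mol/residue, and at least
max(2, ⌈n/5⌉) strong H-bonds. Because the cyclic layer's threshold leaves
no pressure below 0.1, a raw trajectory state meeting the screens is
*refined* before recording: anchored closure to the nearest closed
conformation, a short bounded steric repair (0.45·rama + rep + 10³·E_cyc,
Powell, ≤ 250 evaluations) if that introduced clashes, a free re-close,
and a final re-check of every criterion on the refined state. The
trajectory itself is never modified. At most one candidate per canonical
bin string is kept per run (lowest E_total).

The low-RMSD arm (`low_rmsd_annealing`) is the same loop with exactly two
tests — cyclic error, then Metropolis on backbone-heavy-atom RMSD to a
reference — and records first-seen representatives per bin class,
starting with the reference itself; its recording waives the H-bond and
repulsion demands because its job is low-RMSD landscape coverage, not
candidate quality.

## ClusterGen

For sequences whose landscape cannot be covered by threading, a genetic
algorithm over closed backbones:

- *Initialization*: a low-energy SA arm (the layered sampler for the
  packaged energy; for a custom `EnergyModel` a two-test variant — cyclic
  error, then Metropolis on the model energy, 100 → 0.5 cooling) plus,
  when a native structure exists, the low-RMSD arm. All samples are
  relaxed, energy-sorted, greedily clustered (leader algorithm on the
  ascending-energy order, cyclic-minimum RMSD, with a fixed-labeling
  shortcut when that alone is inside the cutoff), and the 2·N_GA(0) lowest
  centers form the population.
- *Variation*: crossover swaps a random cyclic window (2 … n/2 residues)
  of torsions between parents and is accepted only if a window-restricted
  closure solve succeeds (the exchange-feasibility gate); mutation
  disk-perturbs a random window (redrawing prohibited proposals up to 10
  times) and re-closes the window the same way.
- *Relaxation*: children are refined by manifold descent — up to 10
  rounds of bounded Powell minimization (±25°) of the model energy inside
  the tangent null space of the closure Jacobian, re-closing exactly
  after each round. Coordinate descent with a closure penalty cannot move
  on this manifold (any single-torsion change breaks closure); null-space
  steps can.
- *Selection*: parents and children merge, are re-clustered, and the
  N_GA(i) lowest-energy centers survive — elitist, so the best energy is
  non-increasing. Published population schedules are wired in as profiles
  (15-mer: 500; 20-mer: 750 − 5i; 24-mer: 1000 − 10i; 50 generations).
- *Recording*: every selected center with energy below the ceiling
  (default 0 kcal/mol, configurable since surrogate energy scales differ)
  enters the landscape with its cyclic-minimum RMSD to the native; in
  prediction mode (no native) RMSDs are computed at the end against the
  lowest-energy record. Structure prediction clusters the 50 lowest-energy
  records at 1.5 Å and returns the ≤ 5 lowest centers.

## Stability statistics

PNear is computed in log space (log-sum-exp), making it invariant to
constant energy shifts and safe for energies spanning thousands of
kcal/mol. λ defaults to 0.5 Å (n ≤ 9), 1.5 Å (n ≤ 17), 2.0 Å (larger);
kT = 0.62 kcal/mol (37 °C). For backbone pools the RMSD is minimized over
all n cyclic relabelings (the ring has no first residue); for GA
landscapes of a single labeled sequence the fixed labeling is used.
Landscape reshaping re-anchors the native at the argmin-energy record and
recomputes all RMSDs (energies untouched).

The free-energy surface is F = −RT ln P on a 50×50 histogram of
(RMSD, R_g) samples spanning their observed ranges; empty cells are
masked, so Σ exp(−F/RT) = 1 over occupied cells and the minimum sits in
the modal cell. Samples are taken in whatever length unit they arrive in
(Å here); a unit change shifts F by a constant only. R_g is unweighted by
default (mass weights optional, undocumented conventions differ).

## Synthetic test systems

No external data is used anywhere. The fixture generator provides:

- *closed_backbone*: bin-center starts, jittered ±15°, locally closed;
  only fully map-allowed rings are returned.
- *helical_turn*: a hand-built (synthetic, non-physical) 4-residue
  structure with exactly one planted H-bond at 2.0 Å / 160°, the
  detection oracle.
- *two_funnel_landscape*: analytic records from two linear-walled funnels
  (native at RMSD 0, decoy at 3 Å), PNear hand-computable.
- *planted_minimum_system*: a 6-residue toy whose energy is
  k·Σ d_torus((φᵢ,ψᵢ),(φ*ᵢ,ψ*ᵢ))² − depth (k = 0.002 kcal/deg²,
  depth = 5), with the unique global minimum at a planted closed target —
  deliberately multimodal under the closure constraint, so recovering the
  planted state exercises the GA's global search, not just the local
  relaxer.
- *bivariate_samples*: seeded Gaussian clouds for the FES tests.

What passing these tests shows — and does not. The toy systems verify the
machinery (exact closure, layered acceptance, clustering invariants,
funnel statistics, planted-minimum recovery at 15 generations / N_GA = 50)
at sizes and energy models chosen to run in seconds-to-minutes on one
CPU. They do not demonstrate force-field accuracy, real-sequence
designability, or the sampling completeness that full-scale runs
(100,000 initial configurations, N_GA in the hundreds, external Cartesian
relaxation) would provide; the full-scale schedules are wired into the
"15"/"20"/"24" profiles but are not exercised by the test suite.

## Numerical choices and degenerate inputs

- Angles are stored in radians internally, exposed in degrees, wrapped to
  (−180°, 180°]; ±180° are the same torsion and canonicalized to +180°.
- Dihedrals of collinear triples raise a typed degenerate-geometry error
  instead of returning NaN.
- Kabsch superposition uses proper rotations only (no reflection);
  structure pairs of unequal size are a type error, and the SVD route is
  cross-checked in the tests against an Euler-grid + refine oracle.
- Greedy energy clustering breaks ties by ascending-energy order, which
  is deterministic for a fixed input; equal-energy bin-string
  representatives keep the first seen.
- All stochastic components take explicit seeds; per-run streams are
  spawned from a root `SeedSequence`, so candidate lists are bit-stable.

## Known limitations

- The closure solve assumes ideal geometry; structures read from PDB
  files with real (non-ideal) geometry will not round-trip through
  forward kinematics exactly.
- The surrogate energy cannot rank real designs; the export hooks
  (PDB out / score tables in) exist so an external full-energy relax can
  stand in where the internal one is used.
- The 6-bin partition and the analytic map basins are approximations;
  swapping in measured grid files changes bin membership near boundaries.
- Prediction-mode ClusterGen at published scale (10⁵–10⁶ initial points,
  N_GA up to 5000) is configured but far beyond desk-scale runtimes.
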