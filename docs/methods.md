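# Methods

## Coarse-grained representation

Structures are parsed from PDB text (gemmi underneath), collapsed to the
first MODEL, with alternate locations resolved to the highest-occupancy
conformer (ties: first label in file order). Preprocessing keeps the
selected chains, strips heteroatoms and hydrogens, maps selenomethionine
(MSE) to MET, and drops other nonstandard residues and residues without a
Cα, each with a warning. All residues of every selected chain are retained
so inter-chain contacts between selected chains enter the network. The
coarse model places one node per residue at the Cα, ordered by chain and
then author sequence number (insertion codes respected); mutations are
addressed in author numbering throughout.

## Potential

The potential is pairwise Hookean, V = Σ ½ k_ij (d_ij − d⁰_ij)², evaluated
at the equilibrium (input) geometry, so the Hessian has the standard
elastic-network block structure: off-diagonal block
−(k_ij/d⁰²)(r_i−r_j)(r_i−r_j)ᵀ, diagonals fixed by translation invariance.
Spring assignment:

* **ANM**: k_ij = `base_spring` for all pairs with Cα distance ≤
  `anm_cutoff` (default 18 Å, the conventional coarse-grained choice).
* **ENCOM_LIKE** (default): sequence-consecutive residues of a chain get
  `covalent_spring` (default 10, i.e. 10× the base spring — the backbone
  link must dominate generic contacts, but its exact value only rescales
  relative stiffnesses); all other pairs get
  `base_spring`·[d ≤ cutoff] + `contact_scale`·w_ij, zero-stiffness springs
  omitted.

The contact weight between residues a and b is
w_ab = Σ_{p∈a,q∈b} M[class(p), class(q)] · s(d_pq) over heavy-atom pairs,
with s a linear surface-in-contact surrogate:
s(d) = clamp((R_p + R_q + t − d)/t, 0, 1), vdW radii per element and a
water-probe-like tolerance t = 1.4 Å. This monotone ramp stands in for an
exact contact-surface computation: it preserves the model family (bigger,
closer side chains → stiffer springs) while keeping the analytic and
finite-difference Hessians exactly consistent. The atom-type classes
(8 classes by element/polarity/aromaticity) and the interaction matrix M
(default all-ones, i.e. pure surface weighting) are shipped as editable CSVs
in `cgnma/data`; spring units are arbitrary, so all entropies and ΔΔG
contributions are relative — the fitted combination coefficient α absorbs
the scale.

Chain connectivity uses only nearest-neighbour covalent springs; no
angle/dihedral terms. This is a deliberate simplification: it keeps the
energy pairwise so `build_hessian_numeric` (central differences of V,
default step 1e-4 Å) is an exact independent oracle for the analytic
assembly, which the tests exploit (agreement to 1e-5 on helix and dumbbell
fixtures).

## Modes, entropy, b-factors, overlap

The Hessian is diagonalized densely (`scipy.linalg.eigh`). A mode is
trivial when λ < 1e-8 × λ_max (relative threshold, scale-free); connected
non-collinear structures have exactly 6 (a different count warns about
disconnection or collinearity — 6 per rigid component). Vibrational entropy
is S = −½ Σ ln λ over internal modes, dropping all physical prefactors:
only mode-stiffness ratios survive in ΔΔS_vib, which is all the stability
score uses. Predicted b-factors are b_i = Σ_m ‖v_m,i‖²/λ_m in relative
units. Squared overlap between a unit mode and a displacement Δ is
(v·Δ)²/(Δ·Δ). Within degenerate eigenvalue subspaces the eigenvector basis
is solver-dependent; every quantity used downstream (entropy, b-factors,
overlap sums over subspaces) is basis-invariant, and tests only assert such
quantities.

## Mutations

Mutant structures are built by **sequence swap**: backbone and Cα stay
fixed; side-chain heavy atoms are replaced by the canonical atom census of
the target residue placed at 1.5 Å spacing along the Cα→Cβ direction
(Cβ direction from the ideal tetrahedral bisector when no Cβ exists). What
the score needs is the atom-class census entering the contact weights, not
rotamer geometry; model quality directly bounds prediction quality, and a
hook is provided to substitute any external modelling command per mutation
(failures skip that mutation with a warning rather than aborting the scan).
A consequence of the stub geometry is that atoms far out along the stub can
be beyond contact range, so chemically conservative swaps (e.g. F→Y) may
score exactly neutral on small fixtures.

ΔΔS_vib = S(mut) − S(wt) requires equal node counts and trivial-mode counts
(guaranteed by sequence swap). Under the ANM the mutant Hessian is
bit-identical to the wild type, so every mutation scores exactly 0 — kept
as a regression control. The combined prediction is
ΔΔG = α·ΔΔS_vib + β·ΔΔG_B with defaults α = −1.12, β = 0.38, the
best-performing coefficients reported for combining vibrational-entropy
scores with an enthalpic FoldX-style predictor; ΔΔG_B values are consumed
from CSV keyed by mutation string (e.g. `KA13Q`) and never recomputed here.
Negative ΔΔG is stabilizing; the stabilizing/destabilizing split used in
calibration summaries is ±0.5 kcal/mol.

`calibrate` draws bootstrap resamples of a (ΔΔG_A, ΔΔG_B, ΔΔG_exp) table
(default 10 000 samples), fits a no-intercept least-squares regression per
sample, and reports median α, β and median ± std RMSE for all rows and both
subsets. Rank-deficient resamples are redrawn up to 5 times; if the full
table is singular (e.g. a constant-zero column) the minimum-norm solution
is used and counted, so the identifiable coefficient is still recovered.

Flexibility maps report b(mut) − b(wt) per residue (positive = more
flexible = red, negative = rigidified = blue). The job-wide color scale is
S = min(max|δ|, 3·std(|δ|)) over all mutations and residues in the job,
falling back to max|δ| when std degenerates to zero; colors are therefore
comparable only within one job. A heatmap of predicted ΔΔG over positions ×
mutant types is emitted when a scan covers more than two positions and more
than two types, along with a top-25 most-stabilizing summary.

## Ensembles

For selected internal modes (1-based indices ≥ 7) each mode's amplitude
runs over a δ-spaced grid, δ = min_rmsd·√N; by eigenvector orthonormality a
tuple (a_1..a_m) puts the conformer at RMSD sqrt(Σa²/N) from the input, so
the Cartesian product is pruned to the ball Σa² ≤ (max_rmsd·√N)². The
δ-lattice was chosen because its minimum nonzero point distance is exactly
δ, which guarantees the pairwise min-RMSD constraint while sampling
uniformly; a greedy post-filter (keep lexicographically smaller tuples)
additionally enforces the bound for user-supplied tuples, where it is not
automatic. If the surviving grid exceeds the cap (default 350 conformers)
the spacing grows geometrically (factor 1.2 — unspecified by any external
convention; geometric growth guarantees fast termination) until it fits,
and the final spacing is reported as the effective minimum RMSD.

RMSD is computed over Cα nodes in the shared input frame without
superposition: conformers are generated in that frame and rigid-body modes
are never sampled, so superposition would be a no-op up to numerical noise.
Visualization ordering runs greedy nearest-unvisited paths from every start
(ties: lowest index) and keeps the lowest-total path — a heuristic for the
NP-hard exact ordering, exact on small ensembles (verified against brute
force for n ≤ 8). Single-mode trajectories a·sin(2πt/n_frames) are emitted
for the first 20 internal modes by default. Conformers are raw linear
displacements and not stereochemically regularized; the same external-command
hook used for mutant modelling can rebuild them with a full modelling tool.

## Synthetic fixtures

All tests run on generated structures; none download data.

* **helix**: ideal α-helix Cα trace (rise 1.5 Å, 100°/residue, radius
  2.3 Å; consecutive Cα ≈ 3.8 Å) with stub side chains tilted between the
  radial normal and the helix axis (1 : 1.5) so residues i and i±3/i±4 make
  vdW contact — the natural helical contact topology; without the tilt,
  purely radial stubs diverge and the sequence-aware model would see no
  mutation at all.
* **dumbbell**: two compact lobes fused at a small elbow cluster in a bent
  (open-V) arrangement — a minimal hinged two-domain protein. The
  inter-domain separation vector is defined as the hinge-opening field
  (rigid counter-rotation of the lobes about the elbow, zero on the elbow),
  the displacement that opens/closes the cleft. At the canonical geometry
  (default sizes, seed 0) analyzed with an 11 Å cutoff — matched to the
  fixture's ~40 Å extent; the 18 Å protein default would blanket the toy
  with springs — the slowest internal mode carries > 0.5 squared overlap
  with this field. The three softest modes (in-plane opening, out-of-plane
  scissor, twist) are close in stiffness, so under re-jittered geometries
  the opening field can split across them; jointly they always carry most
  of it. A straight extended-linker dumbbell cannot exhibit a
  separation-dominated slowest mode under central-force springs (the
  linker's transverse motions are always softer), which motivated the bent
  design.
* **line / dimer**: a collinear chain (degenerate-geometry tests) and two
  parallel helices in chains A/B with interface contacts (chain-selection
  and inter-chain-spring tests).
* **ΔΔG tables**: ΔΔG_exp = α·ΔΔG_A + β·ΔΔG_B + N(0, σ), with ΔΔG_A
  zero-centred unit-scale (entropy-like) and ΔΔG_B mean +1, sd 1.5
  (enthalpy-like, destabilizing-biased). Calibration recovery is tested at
  n = 300, σ = 0.1, 1 000 bootstrap samples (sizes chosen to finish in
  seconds; estimates are already stable there).

Fixtures are bit-reproducible given (kind, n, seed). What they do not
emulate: real packing heterogeneity, rotamer geometry, backbone relaxation
on mutation, and solvent — so passing tests demonstrate correctness of the
machinery and its invariants, not predictive accuracy on real proteins,
which requires benchmarking against experimental ΔΔG and conformational
data.

## Numerical choices and limitations

* Zero-mode tolerance 1e-8 (relative); Hessian symmetry asserted to 1e-8.
* Finite-difference step 1e-4 Å balances truncation against round-off for
  the oracle's 1e-5 agreement target.
* Ordering ties and altloc ties are broken deterministically (lowest index
  / first in file) so identical inputs give byte-identical outputs.
* The contact ramp is C0 but not C1 at its endpoints; since the Hessian is
  always evaluated at the fixed input geometry this only matters for
  sensitivity of spring constants near the cutoff, not for the dynamics.
* Hard distance cutoffs make spectra discontinuous in coordinates: pairs
  near the cutoff can flip springs on/off under tiny perturbations. For
  small synthetic systems choose cutoffs away from dominant pair-distance
  shells (the dumbbell's 11 Å sits in such a gap).
* Dense diagonalization is O(N³); fine for desk-scale proteins (hundreds of
  residues), not for large complexes.
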