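# Methods

## Scope and units

`nsepot` implements a message-passing interatomic potential whose inputs
are atomic numbers, Cartesian coordinates (Å), the total molecular charge
*Q* (elementary charges) and the spin multiplicity *S*. Outputs are the
molecular energy (kcal/mol), per-atom forces (kcal/mol/Å) and per-atom
α/β spin charges. All internal constants (e.g. the Coulomb constant
332.0637 kcal·Å/mol/e²) live in one place; no other unit system appears
anywhere.

## Spin-channel accounting

With *n*ᵤ = *S* − 1 unpaired electrons and the convention that electrons
carry charge −1 and the α channel hosts the unpaired excess,

    Qᵅ = (Q − nᵤ)/2,   Qᵝ = (Q + nᵤ)/2,

so Qᵅ + Qᵝ = Q and Qᵝ − Qᵅ = nᵤ, with Qᵅ ≤ Qᵝ. For integer *S* the pair
(Q, S) must be parity-consistent with the electron count
N = ΣZ − Q: N − nᵤ even and nonnegative; violations raise at construction
time. Non-integer *S* is admitted purely as a smoothness probe — the
totals interpolate linearly and the parity check is skipped — and file I/O
refuses to write it.

## Architecture

1. **Geometric features.** Gaussian radial shells (16 by default, centres
   on [0.5, 5.0] Å) under a *squared*-cosine cutoff envelope, contracted
   against learned per-element embeddings of each neighbour:
   envᵢ = Σⱼ g(rᵢⱼ) ⊗ e(Zⱼ). Features depend only on interatomic
   distances, so rigid-motion invariance and permutation equivariance are
   exact, not approximate. The squared cosine makes both the envelope and
   its radial derivative vanish at the cutoff (the derivative cubically),
   so neighbour-list rebuilds cannot introduce kinks. Angular information
   is deliberately absent from the descriptors; many-body correlations
   enter through the charge-mediated message passing.

2. **Message passing with NSE.** Three iterations by default. Each pass
   feeds [self-embedding, environment, qᵅ+qᵝ, qᵝ−qᵅ] through a two-layer
   tanh MLP; a head emits candidate charges q̃ˢ and weights fˢ per channel.
   Weights are mapped through softplus plus a 1e-4 floor — the update
   divides by Σf, so strict positivity is a well-posedness requirement,
   not a modelling choice. The NSE layer then applies

       qᵢˢ = q̃ᵢˢ + fᵢˢ/Σⱼfⱼˢ (Qˢ − Σⱼq̃ⱼˢ)

   independently per channel. Conservation of both channel totals is an
   algebraic identity of this update, which is why the test suite checks
   it on *untrained* random parameters. Charges re-enter the next pass as
   the symmetric/antisymmetric pair (qᵅ+qᵝ, qᵝ−qᵅ), which keeps the
   singlet limit well behaved. Initial charges are the channel totals
   spread uniformly over atoms. The closed-shell NQE scheme is implemented
   as NSE with tied channels (one candidate, one weight, half the total
   each), so single-channel behaviour is a special case rather than a
   separate code path.

3. **Readout and long-range terms.** A final MLP maps the converged
   features to per-atom energies; per-element reference shifts (fitted by
   linear regression on training compositions, carrying the arbitrary
   energy zero) are added. Explicit physics terms follow: damped Coulomb
   k qᵢqⱼ/√(r² + w²) on the summed charges (w = 1.5 Å — finite at contact,
   bare 1/r beyond a few Å) and a BJ-style damped dispersion
   −C₆ᵢⱼ/(r⁶ + d⁶) with per-element C₆ and d = 3.0 Å. Summed rather than
   per-channel charges drive the Coulomb term; the per-element C₆ table is
   configuration, not physics — values are plausible in magnitude but not
   fitted to any reference.

4. **Forces.** Exact gradients from a small in-repo reverse-mode autodiff
   over numpy arrays. Its backward pass is built from the same
   differentiable operations, so gradients can be differentiated again —
   which is what lets a force-matching loss (a function of ∂E/∂R) be
   minimised with respect to the parameters. Forces therefore match
   central finite differences to ~1e-8 relative, and net force/torque
   vanish to rounding because the energy depends on distances only.

## Surrogate reference oracle

Training labels come from an analytic stand-in for an electronic-structure
labeler:

- **Energetics**: pairwise Morse curves with separate singlet and triplet
  parameter sets (doublet = their elementwise mean). The triplet sets
  carry a lowered dissociation asymptote, so the default H–H singlet
  (D = 109.5 kcal/mol, a = 1.94 Å⁻¹, r = 0.741 Å) and triplet
  (D = 9, a = 1.2, r = 1.35, asymptote −22) curves cross exactly once, at
  1.7299 Å — verified by dense sampling plus Brent root-finding, and used
  as ground truth for crossing-point recovery. The asymptote offset is
  per-pair, which is a modelling convenience: it is exact for dimers (the
  recovery task) and merely produces a consistent spin-dependent baseline
  for polyatomics.
- **Charges**: classical electronegativity equalisation. The functional
  Σᵢ(χᵢqᵢ + ½ηᵢqᵢ²) + Σᵢ<ⱼ k qᵢqⱼ/√(r²+w²) is minimised under Σq = Q via
  the exact KKT linear system. Because the damped kernel is a positive
  semidefinite function of distance, strict convexity (hence a unique
  minimum) is guaranteed whenever every hardness exceeds the kernel's
  contact value k/w ≈ 221 kcal/mol/e²; the constructor enforces this and
  the shipped defaults (η between 250 and 320, χ between 51 and 79 on a
  Pauling-like ordering) satisfy it.
- **Spin splitting**: the nᵤ unpaired electrons are distributed over atoms
  proportionally to per-element spin-affinity weights, then
  qᵅ = q/2 − u/2, qᵝ = q/2 + u/2 — channel sums hit the totals exactly by
  arithmetic.
- **Forces**: analytic. For the electrostatic part the envelope theorem
  applies (the charges are the constrained minimiser), so only the
  explicit r-dependence of the kernel contributes.

The **dataset generator** perturbs template geometries (H₂, a CH₃⁺-like
4-atom cluster, a 6-atom C/H chain) with Gaussian displacements
(σ = 0.15 Å default) and cycles charge/spin edits — electron
attachment/removal to doublets, electron unpairing to a triplet, hydrogen
removal to a doublet radical — keeping only parity-consistent
combinations. A single integer seed determines everything.

What the surrogate does **not** emulate: chemical realism of label
magnitudes, multi-reference character, charge transfer beyond QEq,
anisotropic bonding, conformational complexity. Passing the recovery test
shows the architecture can represent and learn spin-resolved surfaces
and conserve charges while doing so — not that it reaches any particular
accuracy on real chemistry.

## Training

Loss = w_E·MSE(E/atom) + w_F·MSE(F) + w_q·[MSE(qᵅ) + MSE(qᵝ)] with
defaults (1, 0.5, 1): charge supervision is the distinctive label of this
architecture and is weighted on par with energy; per-atom energy
normalisation balances mixed system sizes. Optimiser: Adam (β = 0.9/0.999,
ε = 1e-8), lr 1e-3 default, halved after a 10-epoch validation plateau,
early stop after 30 epochs without improvement, best-validation parameters
returned. Frames are sorted into fixed batches by one seeded shuffle and
batch order is re-shuffled per epoch from the same generator, so a fixed
seed gives bit-identical runs at fixed thread count. Conservation is
spot-checked every epoch during training. Ensembles train K members
(default 4) that differ only in seed base+k for initialisation and data
shuffling; prediction spread is the population standard deviation.

The PES-recovery task trains on 3000 dimer frames (40-point grid on
[0.6, 4.0] Å, singlet/triplet alternating, 0.01 Å jitter) for 80 epochs at
batch 256, lr 5e-3 — about a minute on one CPU; these sizes were chosen to
leave a wide margin on the 0.15 Å crossing-recovery criterion while
keeping the whole validation battery fast enough to run routinely.

## Reaction analysis

- **Optimisation**: monotone BFGS with Armijo backtracking; converged when
  the largest per-atom force norm drops below 1e-3 kcal/mol/Å. A
  non-finite energy mid-search returns the last good geometry with a note.
- **Scans**: constrained optimisations, not reaction paths. Rigid mode
  displaces atom j along the bond axis; relaxed mode holds the scanned
  distance with a stiff harmonic restraint (k = 1e4 kcal/mol/Å²) and
  relaxes everything else. A fixed-stiffness restraint leaves a residual
  offset of order |dE/dr|/k, so the restraint centre is iteratively
  corrected (umbrella shifting) until the realised distance matches the
  target to 1e-6 Å — this keeps the scheme potential-agnostic while making
  "relaxed scan of a dimer ≡ rigid scan" hold to rounding. Recorded
  energies exclude the restraint term. 2-D scans are the Cartesian product
  of two such constraints. Profile markers: reactant/product at the
  endpoints, TS at the interior maximum — an approximation, clearly not a
  saddle search.
- **Crossings**: on a common grid, the first sign change of the energy gap
  is linearly interpolated; without a sign change the closest-contact
  point is returned and flagged. Exact grid-point degeneracies are
  reported as crossings at the grid point; identical profiles are flagged
  degenerate.
- **RMSD**: Kabsch superposition — SVD of the covariance with the
  determinant correction that excludes reflections. The residual is
  evaluated directly after applying the optimal rotation rather than via
  the trace formula, which loses ~8 digits to cancellation on
  near-identical structures.
- **Statistics**: MD = mean deviation, MAD = mean |deviation|,
  R² = 1 − SS_res/SS_tot on (reference, predicted) pairs, reported as
  undefined when the reference has zero variance. Profile MAD zeroes both
  profiles at their reactant point first, making it invariant to the
  absolute energy offset.

## Design choices that were genuinely open

- **Descriptor form**: radial-only Gaussian basis + element embeddings
  instead of angular symmetry functions — fully specified, testable, and
  sufficient for the tasks here; angular information arrives indirectly
  via iterated charge exchange.
- **Whether S enters directly**: the model sees S only through the channel
  totals (and the initial uniform charges derived from them), never as a
  raw feature — this is what makes linear-in-S interpolation of the totals
  the single knob controlling smoothness in S.
- **f-head sharing**: the α and β heads are separate slices of one output
  layer (distinct parameters, shared trunk).
- **Checkpoint format**: a single JSON file (config + parameter arrays +
  format version). Deterministic, diffable, and free of archive-timestamp
  noise; size is irrelevant at this model scale.
- **CLI**: argparse subcommands over the library, config-hash + seed
  stamped into every output file, logging to stderr only — reruns with the
  same seed are byte-identical.

## Known limitations

- No periodic boundary conditions, no angular descriptors, no
  element-pair-specific long-range parametrisation beyond the C₆ table.
- Scans locate approximate features: the interior-maximum "TS" and the
  grid-interpolated crossing are starting guesses, not stationary points;
  there is no saddle optimisation or minimum-energy-crossing-point search.
- Open-shell singlets (two unpaired electrons coupled to S = 1) are out of
  scope: the channel-total accounting assigns them the same totals as a
  closed-shell singlet.
- The autodiff engine is minimal by design: float64 only, no
  vectorisation across molecules beyond batch concatenation, no GPU. It
  is fast enough for the desk-scale systems this package targets and no
  further.
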