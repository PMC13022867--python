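# Methods

`fockforge` searches for *one-shot* surrogates of self-consistent electronic
structure: short programs of parameter-free matrix operations whose output
matrix **M**, after a single generalized diagonalization, yields molecular
orbitals good enough to reproduce Hartree–Fock (or Kohn–Sham) total energies
without any SCF cycles. This note records the model, the numerical choices,
and what the synthetic study systems do and do not demonstrate.

## The one-shot energy model

For a closed-shell molecule with AO overlap `S`, core Hamiltonian `Hcore`,
two-electron integrals `(μν|λσ)` and `n_occ` electron pairs, a workspace
matrix `M` is scored by

1. solving `M c = S c ε` (ascending eigenvalues, `cᵀS c = I`),
2. doubly occupying the `n_occ` lowest orbitals, `P = 2 C_occ C_occᵀ`,
3. building one exact Fock matrix `F[P] = Hcore + J[P] − ½K[P]`,
4. evaluating `E = ½ Tr[P (Hcore + F[P])] + E_nuc`.

Step 3 is a deliberate design choice: the energy is evaluated at `F[P(M)]`,
not at `M` itself. Any matrix function `f(F)` that is monotone on the
occupied spectrum shares `F`'s generalized eigenvectors but carries
arbitrarily rescaled eigenvalues; only the rebuilt Fock matrix makes step 4
the true Hartree–Fock energy functional of the predicted density. Two exact
consequences — both enforced by tests — follow:

* **identity**: scoring the converged Fock matrix reproduces the SCF energy
  to numerical precision, and so does any monotone spectral transform of it;
* **variational bound**: no symmetric `M` can score below the converged SCF
  energy, because step 4 evaluates the HF functional at an idempotent
  density.

The Kohn–Sham path replaces step 3–4 by a single evaluation of the
restricted KS total energy (Coulomb + exchange–correlation + one-electron +
nuclear) at `P(M)`.

Occupation is strict aufbau; if the frontier gap `ε_{n_occ} − ε_{n_occ−1}`
falls below 1e−10 hartree the occupation is ambiguous and the evaluation is
flagged invalid (sentinel energy +∞) rather than resolved arbitrarily. The
same sentinel mechanism covers non-finite intermediates and workspace
matrices whose Frobenius norm exceeds 1e8.

## Quantum-chemistry engine

All AO-basis quantities are computed in-package:

* **Basis.** STO-3G, generated from the standard construction: universal
  three-Gaussian least-squares expansions of ζ=1 Slater shells (1s, shared
  2s/2p, shared 3s/3p), scaled per element by the published Slater
  exponents. The universal constants were re-derived by re-running the fit
  (the test suite repeats this check); supported elements are H–Ne plus Na
  and Cl.
* **Integrals.** McMurchie–Davidson Hermite expansion with a tabulated Boys
  function (6th-order Taylor interpolation on a 0.05-spaced grid, |error| <
  1e−12; stable upward recursion beyond T = 36). numba-compiled kernels;
  overlap-based primitive screening at 1e−15 and Schwarz-style pair bounds
  in the gradient kernels (≲1e−9 hartree effect on total energies).
* **SCF.** DIIS-accelerated Roothaan iteration (energy convergence 1e−10,
  commutator below 1e−7), with two level-shifted, damped retries (μ = 0.3
  and 1.0 hartree on the virtual manifold) for stretched-bond cases; scans
  along a bond warm-start from the previous density.
* **Gradients.** Analytic RHF nuclear gradients (angular-momentum
  raising/lowering for bra/ket center derivatives; operator-center terms via
  translational invariance; validated against finite differences at ~1e−8
  hartree/bohr). Geometry relaxation is BFGS on these gradients
  (gtol 3e−6 au). Hessians are central finite differences of the gradient
  (step 5e−3 bohr); rows are differentiated only for symmetry-unique atoms,
  with image-atom rows filled exactly through the detected axis-aligned
  mirror/C2/inversion operations (H[πa, πb] = R H[ab] Rᵀ) — for the C2h
  anti conformer of n-butane this saves about two-thirds of the gradient
  evaluations. A one-sided `scheme="forward"` exists but cannot resolve
  soft torsional modes (its O(step) bias is comparable to ω² of a ~100 cm⁻¹
  mode) and is not used by the standard pipelines.
* **Kohn–Sham.** The LDA (Slater exchange + VWN5 correlation) on
  Becke-partitioned atomic grids (Gauss–Chebyshev radial map, 60 points;
  Gauss–Legendre × uniform-azimuth spheres, 14×28 points). Every ingredient
  has an independent closed-form check in the tests (grid electron counts,
  analytic Slater exchange of a Gaussian density, functional-derivative
  consistency of the XC matrix). Hybrid functionals are not implemented;
  the KS pipeline therefore runs with `dft:lda` and the package makes no
  claims about any other functional.
* **Small-matrix eigensolver.** Batched Householder/implicit-QL
  (tred2/tqli) compiled with numba; one call diagonalizes the workspace
  matrices of every geometry of a species, which is what makes 10⁴-iteration
  annealing runs affordable. Falls back to LAPACK above n = 48.

## Function catalogue

6 input, 61 internal and 2 output functions, all parameter-free (the only
embedded constants are the Wolfsberg–Helmholz factor 1.75 and the ±20
clipping bound of exponential maps). Inputs: `Hcore`, `S`, the
extended-Hückel guess, one-Fock-build guesses from the core and
superposition-of-atomic-densities densities, and the symmetrized `S⁻¹Hcore`.
Internal families: combinations (`+`, `−`, symmetrized product, replace)
with eight context matrices (`Hcore`, `S`, `S⁻¹`, `I`, `P(M)`, `F[P(M)]`,
`J`, `K`); S-metric powers; nine elementwise scalar maps and the same nine
as eigenvector-preserving spectral maps; three normalizations; three
Hadamard products; one- and half-step Roothaan updates; identity. Outputs:
the S-metric generalized eigensolve, or a plain eigensolve whose
eigenvectors are mapped back through `S^{−1/2}` (Löwdin-basis
diagonalization — the second convention keeps `Tr(PS)` equal to the
electron count, which a raw identity-metric eigensolve would not).

Every internal function maps symmetric to symmetric (or raises the invalid
flag); the catalogue is content-hashed, and serialized programs refuse to
load under a different hash.

## Search

Programs have `N_f = 15` slots (1 input, 13 internal, 1 output). Annealing
minimizes the mean squared deviation between shifted predictions and shifted
references,

    F_E = (1/N) Σ_ij [ (Ē_ij − D̄_i) − (E_ij − D_i) ]²,

where `D_i` is the independent-atom reference energy of species *i* and
`D̄_i = Σ_el n_el d_el` is a per-element shift model refit in closed form
(minimum-norm linear least squares on the composition design matrix) at
every iteration. `N` is the total geometry count, which reduces to the
`N_m·N_p` normalization when every species has the same number of
geometries. The annealer compares √F_E in hartree; a worse candidate is
accepted with probability `exp(−ΔF/(k_B T))`, `k_B = 3.166811563e−6`
hartree/K, with `T` decreasing linearly from 250,000 K to a 1 K floor over
the run. At that initial temperature `k_B T ≈ 0.79` hartree, so the chain
explores essentially freely for most of the schedule and optimizes greedily
near the end; the returned result is always the best-so-far program. Each
iteration mutates `r ∈ {1,2,3}` uniformly chosen slots with role-matched
draws. Invalid programs never displace a finite incumbent. Ties (ΔF = 0)
are accepted.

**Atomic reference energies.** `D_i` uses a spherically averaged
fractional-occupation *restricted* SCF for open-shell atoms (electrons
spread equally over the degenerate frontier shell). Because residuals only
ever see `D_i` through the same per-element linear structure as the fitted
shifts, any per-element constant offset in `D_i` is absorbed exactly by the
fit; the convention affects no training or testing error and is recorded in
output metadata.

**Shift refit order.** Shifts are refit before the acceptance decision, so
Metropolis always compares shift-optimal fitnesses.

**Model selection for testing.** Training restricts programs to a narrow
energy window, and the claim being selected for — element-level
transferability — cannot be certified from the training molecules alone:
the fitted per-element shifts absorb every per-molecule bias of the
training compositions by construction, so a program can score perfectly on
unseen geometries of the training molecules while carrying a composition
bias that explodes elsewhere. Selection among the best-k training programs
is therefore two-step and never touches the hold-out species:

* where a *composition probe* with the same bonding character as the
  transfer domain exists, candidates are ranked by their frozen-shift error
  on it: for the hydrocarbon study the probe is H2 — a sigma-bonded
  molecule whose composition (0 C, 2 H) lies outside the span a training
  interpolation can hide behind. Homonuclear diatomics were evaluated as
  probes for the ionic heterodiatomic study and rejected: covalent Li2/F2
  bonding is a different regime and their errors do not track ionic
  transfer.
* where no same-character probe exists (the heterodiatomics — the only
  same-regime molecule outside training is the hold-out itself), candidates
  are ranked by worst-case density fidelity over the validation domain (the
  training molecules' wider-energy curves): the maximum relative Frobenius
  error between the predicted one-shot density and the converged SCF
  density, the operational definition of `M ≈ f(F)`; the worst case rather
  than the mean because extrapolation demands a uniformly good surrogate.

Validation energy RMSE breaks ties. Candidates must evaluate validly on at
least 80 % of the validation geometries (the invalid flag is a first-class
outcome; a program failing at a few extreme geometries can still be the
best surrogate elsewhere) and on every hold-out geometry. Reports record
the valid count per molecule; shifts are never refit at test time. Because
the scaled-down searches carry 10–12 restarts instead of 50, which program
is best — and how well it transfers — remains noticeably seed-dependent;
the hold-out errors quoted by the reproduction script should be read with
that spread in mind.

## Study systems (what the generators emulate)

* **Heterodiatomics.** LiCl, NaCl, LiF training curves: a geometric
  bond-length grid (0.55–6 × the covalent-radius sum, 160 points) is scanned
  at the reference level, the curve minimum refined, and 15 points per
  molecule subselected stratified-uniformly in energy over both the inner
  wall and the dissociation branch, within 0.25 hartree of the minimum.
  Testing extends each curve to 0.8 hartree above equilibrium (~50 points)
  and adds NaF, absent from training, predicted with the Na and F shifts
  learned on NaCl and LiF.
* **Alkanes.** Methane and ethane equilibria are relaxed at RHF/STO-3G,
  their four lowest-frequency normal modes define the sampling subspace, and
  configurations are drawn on uniform-energy shells: ε ~ U[0, E_max], unit
  direction u on the mode-subset sphere, `q_k = u_k √(2ε)/ω_k` (quadratic
  energy exactly ε). The unit-sphere draw is what makes the quadratic energy
  equal ε exactly. Sampling runs at 1.15 × the 0.03-hartree threshold and an
  ab initio filter then removes points whose true RHF energy exceeds it, so
  the retained energy distribution stays approximately uniform. Training
  draws 18 + 18 points uniformly from databases of 447 (CH4) and 295 (C2H6)
  filtered configurations. Test sets combine the four training modes
  individually with three seeded random triples of higher-frequency modes;
  transfer sets sample propane and n-butane (never trained on) from their
  four lowest modes.

The generators emulate the *geometry distributions* of the study — thermally
modest distortions near equilibrium plus diatomic curves out to
dissociation. They do not emulate basis-set effects beyond a minimal basis,
open-shell or charged species, non-equilibrium bonding topologies
(transition states), or conformational ensembles; passing tests therefore
demonstrate surrogate quality for near-equilibrium closed-shell energetics
at RHF/STO-3G (or LDA/STO-3G), not chemistry outside that envelope.

## Problem sizes in the acceptance script

The full-scale protocol (50 restarts × 10⁴ iterations per study) is a
multi-hour single-CPU computation. `scripts/acceptance.py` runs the same
pipelines at reduced sizes chosen once for a single-CPU session: 10 restarts
of the full 10^4-iteration-scale schedule (8000 iterations) for the combined
diatomic training, 20 × 1500 for the single-molecule success rate, 10 × 1500
for the alkanes, ≥200 test geometries per alkane molecule and 50 transfer
geometries per larger alkane. Search depth for the hard joint-diatomic task
is kept near the full protocol
deliberately — convergence of the loss happens late in the schedule — while
the restart count carries the scaling; the minimum over fewer restarts is a
noisier (generally slightly worse) estimate of the full protocol's best
program.

## Known limitations

* Closed-shell RHF/RKS only; odd-electron species are rejected at input.
* The catalogue is this package's own documented set of 6 + 61 + 2
  functions; discovered programs are search artifacts of *this* catalogue
  (hash-pinned), and search-performance results, not individual function
  identities, are the reproducible quantity.
* Programs are validated only where they are evaluated; outside the sampled
  energy windows a program may go invalid (by design, loudly) rather than
  extrapolate.
* Energies carry the ~1e−9 hartree noise floor of primitive screening;
  nothing in the package asserts agreement between independently computed
  quantities tighter than 1e−8 hartree.
* No nuclear gradients of *surrogate* energies (only of the reference RHF
  energy), no periodic systems, no basis sets beyond the generated STO-3G
  table.
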