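# Methods

## The model

`rdmlearn` builds *surrogate electronic-structure methods*: instead of
solving the self-consistent-field (SCF) equations for every new
molecular geometry, it learns the AO-basis one-electron reduced density
matrix (1-rdm) γ̂ as a function of the external potential and evaluates
everything else from the prediction.

Two maps are learned, mirroring the bijections of density-functional
and reduced-density-matrix functional theory:

**Map 1 (γ-learning).** Kernel ridge regression from the
electron–nuclear attraction matrix v̂ (the only geometry-dependent
one-electron operator retained as a feature) to γ̂:

    γ̂[v̂] = Σ_i β̂_i K(v̂_i, v̂),   K(v̂_i, v̂_j) = Tr[v̂_i v̂_j]

The dual coefficients β̂_i are AO×AO matrices obtained from the
regularized kernel system β̂_i = Σ_j [(K + λI)⁻¹]_{ij} γ̂_j (solved by
Cholesky factorization of K + λI, never by explicit inversion; the
condition number is logged).  Because the kernel is a trace, no
flattening convention enters the model.

**Map 2 (γ+δ-learning).** Ridge regression from the upper-triangle
features of the map-1 prediction γ^p to: the density residual
Δγ = γ̂ − γ^p (giving the refined density γ^p + Δγ^p), the total
energy, the atomic forces (in the internal frame), and the dipole
vector.  For mean-field theories these targets can also be computed
directly from the predicted density; for full CI map 2 is the only
route to energies and forces, as no 1-rdm energy functional exists.

Three prediction variants follow: observables from γ^p, observables
from γ^p + Δγ^p, and energies/forces read directly off map 2.

**N-representability.** Predicted densities are purified before use:
γ is diagonalized in the Löwdin-orthonormalized metric, the top N/2
natural occupations are set to 2 and the rest to 0, and the matrix is
rebuilt.  The result satisfies (γS)(γS) = 2γS and Tr[γS] = N exactly;
purification is a projection (idempotent).  It is skipped for full-CI
surrogates, whose occupations are genuinely fractional.

**Frames.** Operator matrices of different geometries are comparable
only in a common internal frame.  Every training and query geometry is
superimposed on the equilibrium reference by mass-weighted least
squares (Kabsch); the stationarity conditions of that fit are exactly
the translational and rotational Eckart conditions, so the same
construction fixes the frame for dipole time series before Fourier
transformation.  Vector predictions (forces, dipoles) are rotated back
to the laboratory frame with the stored transform.  Identical-atom
permutations are *not* matched; atom ordering must be consistent — a
documented limitation.

## Training-set generation

Geometries are sampled by normal-mode displacement about a relaxed
equilibrium.  A mass-weighted Hessian is built by central finite
differences of analytic engine forces (step 0.01 Å, configurable),
rigid-body motions are projected out, and each sample displaces *all*
modes simultaneously by independent Gaussian deviates with

    σ_i² = 2 k_B T N_atoms / [Ω_i² N_vib (1 − 2/(9 N_vib))³]

so every mode carries the same energy-scaled variance σ_i²Ω_i².  The
default sample count follows the N_vib³ rule — (c·N_vib)³ per
conformer, c = 1 for N_vib ≤ 12 and c = 0.8 above (the crossover is
exposed as configuration) — i.e. 27 for a bent triatomic, 216 for
N_vib = 6, 13,824 for a 30-mode ring, tripled for molecules sampled
from three conformers.  Linear molecules keep 3N−5 modes.  Sampling is
fully seeded and a resumed (checkpointed) build is identical to an
uninterrupted one.

Conformers of alcohols are intended to be generated by rotating the
hydroxyl hydrogen about the C–O axis and re-relaxing; the training-set
container stores one reference geometry per conformer and samples each
independently.

## The built-in engine

No external quantum-chemistry code is required (or assumed): the
package carries a compact GTO engine of its own behind the same narrow
adapter interface any other engine could implement.

- **Integrals.**  McMurchie–Davidson Hermite-Gaussian expansion for
  overlap, kinetic, electron–nuclear attraction, dipole and two-electron
  repulsion integrals over contracted Cartesian Gaussians (general
  angular momentum; the embedded Pople data tables — STO-3G for H–Ne,
  6-31G for H/C/N/O — use s and p shells).  The Boys function is the
  stable confluent-hypergeometric form.  Analytic nuclear derivatives
  of all integrals come from the exact identity
  d/dA G_i = 2a·G_{i+1} − i·G_{i−1}; the operator-center term of the
  nuclear attraction follows from translational invariance.  Primitive
  loops are batched into cached-path `einsum` contractions; per-geometry
  integral sets (including derivative integrals) live in a small LRU so
  reference, γ-route and refined-route evaluations of one geometry share
  one integral build.
- **Restricted Hartree–Fock** with DIIS, convergence 1e-10 Hartree,
  closed shells only.  The analytic gradient uses the standard
  trace expressions with the energy-weighted density matrix.
- **One-shot functionals from a given γ** (the heart of the surrogate
  routes): `energy_from_rdm` evaluates the HF functional once, with no
  SCF; `forces_from_rdm` builds the Fock matrix from γ, diagonalizes
  once, occupies by Aufbau and evaluates the analytic gradient with
  those orbitals — recovering the exact SCF gradient when γ is
  converged and degrading smoothly otherwise. `fock_and_orbitals` gives
  the orbital spectrum, HOMO–LUMO gap, and cube-file export.
- **Determinant full CI** for few-orbital systems (complete
  Slater–Condon Hamiltonian over all spin-adapted determinant pairs,
  dense diagonalization, spin-summed 1-rdm back-transformed to the AO
  basis; forces by central differences of the CI energy).  A hard cap
  on the determinant count keeps this honest about its scaling.

DFT levels (LDA/B3LYP) would require an exchange-correlation
quadrature; the engine interface accepts a plug-in engine for them, and
the built-in engine refuses them with a clear error.  All benchmarks in
this package therefore run at HF (and full CI for the smallest
systems).

## Dynamics, optimization and IR spectra

Velocity Verlet (NVE) with an optional Langevin O-step (BAOAB, NVT)
drives dynamics on any force provider — the conventional engine or any
surrogate route.  Defaults: 0.5 fs timestep, seeded thermostats, a
5 Hartree/Bohr force cap that aborts blown-up trajectories with the
offending frame index.  Geometry optimization is BFGS on the provider's
energy/gradient with a max-|F| convergence criterion (default 4e-4
Hartree/Bohr ≈ 0.02 eV/Å); if BFGS stalls — which happens when energy
and forces come from independent map-2 regressions, so the gradient is
not exactly ∇E — a force-only FIRE descent refines from the best
geometry seen.

IR spectra: frames and dipoles are Eckart-aligned to the reference,
the dipole derivative is taken by central differences, autocorrelated
(FFT), Hann-windowed, zero-padded to the next power of two and Fourier
transformed; wavenumbers are multiplied by a vibrational scaling factor
(default 0.97).  Window and padding are configurable.  Two production
presets exist: per-mode velocity kicks (each trajectory starts at
equilibrium with velocities along one normal mode at an instantaneous
kinetic temperature, default 50 K, N_dof = 3N convention), and
NVT-then-NVE segment sampling for larger molecules.

## Numerical choices

- λ (map 1) defaults to 1e-10: near-interpolation, matching the goal of
  SCF-level density accuracy.  Exact duplicates among training
  potentials are dropped before factorization.  For training sets whose
  samples lie on a low-dimensional manifold (e.g. a bond scan), the
  linear trace kernel is severely ill-conditioned and near-zero λ makes
  the prediction oscillate between training points; `lam="loo"` then
  selects λ on a logarithmic grid by minimizing the closed-form
  leave-one-out residual of the training densities.  The isoelectronic
  diatomic-scan experiment uses this mode; normal-mode-sampled sets
  (full-dimensional manifolds) keep the fixed default.
- α (map 2) defaults to 1e-8, with an intercept and no feature
  standardization (trace-scale features are homogeneous).
- Purification tie-breaks at a near-degenerate Fermi split are by
  eigenvalue order then index, with a logged warning below a 1e-6 gap.
- Dipole origin is the center of nuclear charge, making neutral-molecule
  dipoles origin-independent (documented caveat for ions).
- Internal units are Hartree atomic units; interfaces use Å, kcal/mol,
  kcal·mol⁻¹·Å⁻¹, Debye, fs and Kelvin.

## What the synthetic benchmark does and does not show

The desk-scale study conditions are: water at HF/6-31G, 27 training
samples at 300 K, 50 independently sampled held-out test geometries
(standing in for frames of a long reference trajectory); diatomic bond
scans (N2+CO trained jointly, isoelectronic transfer) at HF/STO-3G; and
full-CI surrogates for H2.  6-31G is used for the water benchmark
because it reproduces the structural regime of the full-scale study —
many more matrix features (91) than training samples (27) — in which
map 2's refinement is meaningful; in a minimal basis map 1 already
interpolates nearly exactly.

Normal-mode sampling emulates the thermally accessible configuration
space of a near-harmonic molecule.  It does not emulate strong
anharmonicity, conformational transitions during dynamics, bond
breaking (beyond explicitly added dissociation geometries), open-shell
states, or condensed-phase environments — so passing tests certify the
learning machinery and its scaled-down physics, not production accuracy
for floppy molecules, which in the full-scale protocol requires the
larger N_vib³ training sets and conformer-resolved sampling.

Known limitations: closed-shell RHF/full-CI engine only (no DFT
functionals built in); s/p basis data only; no permutational alignment;
full CI restricted to tiny determinant spaces; forces for full-CI
surrogates only via map 2.
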