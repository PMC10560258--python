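# rdmlearn

Surrogate electronic-structure methods built on machine-learned
one-electron reduced density matrices (1-rdms).

## The problem

Every property a mean-field electronic-structure method can deliver —
energies, atomic forces, dipoles, orbital gaps — is a functional of the
1-rdm γ̂, and γ̂ itself is fixed by the external (electron–nuclear)
potential v̂ of the nuclear configuration.  `rdmlearn` exploits these
maps to *bypass the self-consistent field entirely*: it learns γ̂ as a
function of v̂ on a small set of reference calculations and then
predicts the density — and everything computed from it — for new
geometries at a tiny fraction of the cost.  That is enough to run
energy-conserving molecular dynamics, relax geometries, compute
HOMO–LUMO gaps and orbitals, and obtain anharmonic, temperature-
dependent infrared spectra without a single SCF iteration at
prediction time.

The package is aimed at method developers and computational chemists
who want an SCF-free surrogate for small gas-phase molecules, with the
whole pipeline — reference engine included — in plain Python.

## The two learned maps

**Map 1 (γ-learning)** — kernel ridge regression with the trace kernel
on operator matrices:

    γ̂[v̂] = Σᵢ β̂ᵢ K(v̂ᵢ, v̂),    K(v̂ᵢ, v̂ⱼ) = Tr[v̂ᵢ v̂ⱼ],
    β̂ᵢ = Σⱼ [(K + λI)⁻¹]ᵢⱼ γ̂ⱼ

Both features and targets are matrices over a Gaussian-type-orbital
basis, expressed in a common internal (Eckart/Kabsch) frame.

**Map 2 (γ+δ-learning)** — regularized linear (ridge) regression from
the predicted γ̂ᵖ to a density refinement Δγ̂ᵖ, the energy E, the
forces F and the dipole μ.  Predicted densities are Aufbau-purified
(natural occupations projected to 2/0) so they are non-interacting
N-representable, which is what keeps long trajectories stable.

Training geometries come from normal-mode sampling: Gaussian
displacements along all vibrational modes with variance
σᵢ² = 2k_BT·N_atoms/[Ωᵢ²·N_vib·(1 − 2/(9N_vib))³] and the N_vib³
sample-count rule (27 samples for water).

A compact GTO engine ships inside the package (McMurchie–Davidson
integrals with analytic nuclear gradients, restricted Hartree–Fock,
determinant full CI for tiny systems) behind a narrow adapter
interface, so no external quantum-chemistry code is needed.

## Worked example

Train a Hartree–Fock/6-31G surrogate for water and use it:

```python
from rdmlearn import Geometry, MethodSpec, DensitySurrogate
from rdmlearn.sampler import SamplePlan, normal_mode_analysis
from rdmlearn.store import build_training_set
from rdmlearn.surrogate import engine_force_provider
from rdmlearn.md import optimize_geometry

spec = MethodSpec("HF", "6-31g")
water = Geometry(("O", "H", "H"),
                 [[0.0, 0.0, 0.1173],
                  [0.0, 0.7572, -0.4692],
                  [0.0, -0.7572, -0.4692]])

eq, _ = optimize_geometry(water, engine_force_provider(spec), fmax=1e-5)
modes = normal_mode_analysis(eq, spec)          # 3 modes for water
ts = build_training_set(eq, spec,
                        SamplePlan(temperature=300.0, n_samples="auto",
                                   seed=11),
                        modes_list=[modes])      # 27 reference SCFs
surr = DensitySurrogate(lam=1e-10, alpha=1e-8).fit(ts)

print(f"{surr.energy(eq, route='refined'):.6f} Ha")
print(f"gap {surr.homo_lumo_gap(eq) * 27.2114:.3f} eV")
```

prints (numbers from this exact script):

```
-75.985359 Ha
gap 19.192 eV
```

i.e. the surrogate reproduces the engine's converged total energy at
the relaxed geometry (−75.9853592 Ha) to better than 1e-6 Hartree and
its HOMO–LUMO gap (19.192 eV) without any SCF iterations.  Evaluated on 50 held-out
normal-mode samples, the same model reaches an energy RMSD of
~1.3×10⁻⁵ kcal·mol⁻¹ and a force-magnitude RMSD of ~2.7×10⁻³
kcal·mol⁻¹·Å⁻¹ against the engine.

A command-line interface wraps the same pipeline:

```bash
rdmlearn build water.xyz --basis 6-31g -T 300 --seed 11 -o train.h5
rdmlearn train train.h5 -o model.h5
rdmlearn md model.h5 water.xyz --steps 2000 -o traj.xyz
rdmlearn ir model.h5 traj.xyz -o spectrum.csv
```

## Layout

| module | contents |
|---|---|
| `rdmlearn.engine` | engine adapter: AO matrices, SCF references, one-shot E/F/orbitals from a given γ |
| `rdmlearn.integrals`, `rdmlearn.basis`, `rdmlearn.fci` | the built-in GTO engine |
| `rdmlearn.frames` | Kabsch alignment, Eckart frame |
| `rdmlearn.sampler` | normal-mode analysis and training-set sampling |
| `rdmlearn.models` | `GammaKRR` (map 1) and `DeltaRefiner` (map 2), sklearn-style |
| `rdmlearn.surrogate` | `DensitySurrogate` — the composite method |
| `rdmlearn.rdm` | purification, occupations, 1-rdm observables |
| `rdmlearn.md`, `rdmlearn.ir` | dynamics, optimization, IR spectra |
| `rdmlearn.store`, `rdmlearn.cli` | HDF5 training-set/model store, `rdmlearn` CLI |

See `docs/methods.md` for the model assumptions, numerical choices and
limitations.
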