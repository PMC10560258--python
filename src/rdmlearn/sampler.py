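"""Training-set geometry generation by normal-mode sampling.

Geometries are drawn by displacing the equilibrium structure along all
vibrational normal modes simultaneously, each mode by an independent
Gaussian deviate whose variance scales the mode's thermal amplitude:

    σ_i² = 2 k_B T N_atoms / [Ω_i² N_vib (1 − 2/(9 N_vib))³]

so that every mode carries the same energy-scaled variance σ_i²Ω_i².
The default sample count follows the N_vib³ rule: (c·N_vib)³ per
conformer with c = 1 up to N_vib = 12 and c = 0.8 above (27 samples for
a bent triatomic, 13,824 for a 30-mode ring), times the number of
conformers for floppy molecules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import MethodSpec, run_reference
from .geometry import Geometry
from .units import ANG_TO_BOHR, BOHR_TO_ANG, KB_HARTREE

__all__ = [
    "NormalModes", "SamplePlan", "normal_mode_analysis",
    "normal_modes_from_hessian", "mode_sigma", "default_sample_count",
    "generate_samples", "hessian_finite_difference",
]

#: crossover of the sample-count prefactor, exposed for configuration
SAMPLE_COUNT_CROSSOVER = 12
SAMPLE_COUNT_PREFACTORS = (1.0, 0.8)
#: finite-difference step for the Hessian, Å
HESSIAN_STEP_ANG = 0.01


@dataclass
class NormalModes:
    """Vibrational analysis result at an equilibrium geometry.

    frequencies : (N_vib,) angular frequencies Ω_i, atomic units, ascending
    modes : (N_vib, N_atoms, 3) mass-weighted displacement vectors
        (orthonormal in the mass-weighted metric)
    equilibrium : the reference Geometry
    """

    frequencies: np.ndarray
    modes: np.ndarray
    equilibrium: Geometry
    masses_au: np.ndarray

    @property
    def n_vib(self) -> int:
        return len(self.frequencies)

    def wavenumbers(self) -> np.ndarray:
        from .units import HARTREE_TO_WAVENUMBER

        return self.frequencies * HARTREE_TO_WAVENUMBER


@dataclass
class SamplePlan:
    """How to sample a training set."""

    temperature: float = 300.0            # K
    n_samples: int | str = "auto"
    seed: int = 0
    conformers: list = field(default_factory=list)

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.n_samples != "auto" and int(self.n_samples) < 1:
            raise ValueError("n_samples must be >= 1 or 'auto'")

    def to_dict(self) -> dict:
        return {
            "temperature": self.temperature,
            "n_samples": self.n_samples,
            "seed": self.seed,
        }


def is_linear(geom: Geometry, tol: float = 1e-6) -> bool:
    """True when all atoms are collinear (moments-of-inertia test)."""
    if geom.n_atoms < 3:
        return True
    r = geom.coords - geom.center_of_mass()
    m = geom.masses_amu()
    inertia = np.einsum("a,aij->ij",
                        m,
                        np.einsum("ak,al->akl", r, r) * -1
                        + np.einsum("a,ij->aij",
                                    np.einsum("ak,ak->a", r, r), np.eye(3)))
    w = np.linalg.eigvalsh(inertia)
    return w[0] < tol * max(w[-1], 1.0)


def n_vibrational(geom: Geometry) -> int:
    return 3 * geom.n_atoms - (5 if is_linear(geom) else 6)


def hessian_finite_difference(force_fn, geom: Geometry,
                              step_ang: float = HESSIAN_STEP_ANG) -> np.ndarray:
    """Cartesian Hessian (Hartree/Bohr², (3N, 3N)) by central differences
    of a force function geom -> (N, 3) Hartree/Bohr."""
    n = geom.n_atoms
    H = np.zeros((3 * n, 3 * n))
    step_bohr = step_ang * ANG_TO_BOHR
    for a in range(n):
        for x in range(3):
            cp = geom.coords.copy()
            cp[a, x] += step_ang
            fp = np.asarray(force_fn(geom.with_coords(cp))).ravel()
            cm = geom.coords.copy()
            cm[a, x] -= step_ang
            fm = np.asarray(force_fn(geom.with_coords(cm))).ravel()
            H[3 * a + x] = -(fp - fm) / (2.0 * step_bohr)
    return 0.5 * (H + H.T)


def _trans_rot_basis(geom: Geometry, masses_au: np.ndarray) -> np.ndarray:
    """Orthonormal mass-weighted translation/rotation vectors, (k, 3N)."""
    n = geom.n_atoms
    sqm = np.sqrt(masses_au)
    r = (geom.coords - geom.center_of_mass()) * ANG_TO_BOHR
    vecs = []
    for x in range(3):
        t = np.zeros((n, 3))
        t[:, x] = sqm
        vecs.append(t.ravel())
    axes = np.eye(3)
    for ax in axes:
        rot = np.cross(r, ax) * sqm[:, None]
        vecs.append(rot.ravel())
    B = np.array(vecs)
    # orthonormalize, dropping null rotations (linear molecules)
    q, rr = np.linalg.qr(B.T)
    keep = np.abs(np.diag(rr)) > 1e-8
    return q.T[keep]


def normal_modes_from_hessian(hess: np.ndarray, geom: Geometry,
                              imaginary_tol: float = 1e-5) -> NormalModes:
    """Mass-weight, project out rigid motions, diagonalize.

    Raises if a retained mode has an imaginary frequency beyond
    ``imaginary_tol`` (in a.u. of Ω²) — the geometry is then not a
    minimum of the chosen method.
    """
    masses = geom.masses_au()
    sqm = np.sqrt(np.repeat(masses, 3))
    Hmw = hess / np.outer(sqm, sqm)
    B = _trans_rot_basis(geom, masses)
    P = np.eye(len(sqm)) - B.T @ B
    Hp = P @ Hmw @ P
    Hp = 0.5 * (Hp + Hp.T)
    w, V = np.linalg.eigh(Hp)
    n_vib = n_vibrational(geom)
    order = np.argsort(np.abs(w))
    vib_idx = sorted(order[len(w) - n_vib:], key=lambda i: w[i])
    lam = w[vib_idx]
    if lam[0] < -imaginary_tol:
        k = int(np.argmin(lam))
        raise ValueError(
            f"imaginary frequency on vibrational mode {k} "
            f"(Ω² = {lam[k]:.3e} a.u.); geometry is not a minimum"
        )
    lam = np.clip(lam, 0.0, None)
    freqs = np.sqrt(lam)
    modes = V[:, vib_idx].T.reshape(n_vib, geom.n_atoms, 3)
    return NormalModes(
        frequencies=freqs, modes=modes, equilibrium=geom, masses_au=masses,
    )


def normal_mode_analysis(geom: Geometry, spec: MethodSpec,
                         step_ang: float = HESSIAN_STEP_ANG) -> NormalModes:
    """Vibrational normal modes from engine forces at a relaxed geometry."""
    hess = hessian_finite_difference(
        lambda g: run_reference(g, spec).forces, geom, step_ang,
    )
    return normal_modes_from_hessian(hess, geom)


def mode_sigma(omega: float | np.ndarray, temperature: float,
               n_atoms: int, n_vib: int):
    """Gaussian width σ_i of the displacement along one mode (m.w. a.u.)."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega <= 0):
        raise ValueError("mode frequency must be positive")
    if n_vib < 1:
        raise ValueError("n_vib must be >= 1")
    var = (
        2.0 * KB_HARTREE * temperature * n_atoms
        / (omega ** 2 * n_vib * (1.0 - 2.0 / (9.0 * n_vib)) ** 3)
    )
    return np.sqrt(var)


def default_sample_count(n_vib: int, n_conformers: int = 1,
                         crossover: int = SAMPLE_COUNT_CROSSOVER,
                         prefactors=SAMPLE_COUNT_PREFACTORS) -> int:
    """Training-set size from the N_vib³ rule (total over conformers)."""
    if n_vib < 1:
        raise ValueError("n_vib must be >= 1")
    c = prefactors[0] if n_vib <= crossover else prefactors[1]
    per_conformer = int(round((c * n_vib) ** 3))
    return per_conformer * n_conformers


def generate_samples(modes: NormalModes, plan: SamplePlan) -> list:
    """Randomly displaced geometries for one conformer.

    Each sample displaces *all* modes simultaneously by independent
    normal deviates q_i ~ N(0, σ_i) in mass-weighted coordinates, then
    converts back to Cartesian Å.  Reproducible for a fixed seed.
    """
    geom = modes.equilibrium
    n_vib = modes.n_vib
    n = plan.n_samples
    if n == "auto":
        n = default_sample_count(n_vib)
    sigma = mode_sigma(modes.frequencies, plan.temperature,
                       geom.n_atoms, n_vib)
    rng = np.random.default_rng(plan.seed)
    inv_sqm = 1.0 / np.sqrt(modes.masses_au)
    out = []
    for k in range(int(n)):
        q = rng.normal(0.0, sigma, size=n_vib)
        disp_mw = np.einsum("i,iax->ax", q, modes.modes)
        disp_bohr = disp_mw * inv_sqm[:, None]
        out.append(geom.with_coords(
            geom.coords + disp_bohr * BOHR_TO_ANG,
            comment=f"sample={k} T={plan.temperature}",
        ))
    return out


def hydroxyl_rotation_conformers(geom: Geometry, c_index: int, o_index: int,
                                 h_index: int, n_conformers: int = 3) -> list:
    """Candidate alcohol conformers by rotating the hydroxyl H about C–O.

    Returns ``n_conformers`` copies of the geometry with the hydroxyl
    hydrogen rotated in equal steps (360°/n) about the C–O axis,
    starting from the input orientation.  Each candidate should be
    relaxed with the engine before it is used as a sampling reference.
    """
    from scipy.spatial.transform import Rotation

    axis = geom.coords[o_index] - geom.coords[c_index]
    axis = axis / np.linalg.norm(axis)
    out = []
    for k in range(n_conformers):
        angle = 2.0 * np.pi * k / n_conformers
        R = Rotation.from_rotvec(angle * axis).as_matrix()
        coords = geom.coords.copy()
        coords[h_index] = (
            geom.coords[o_index]
            + (geom.coords[h_index] - geom.coords[o_index]) @ R.T
        )
        out.append(geom.with_coords(coords, comment=f"conformer={k}"))
    return out


def project_on_modes(modes: NormalModes, geom: Geometry) -> np.ndarray:
    """Mass-weighted normal-coordinate displacements of one geometry."""
    d = (geom.coords - modes.equilibrium.coords) * ANG_TO_BOHR
    d_mw = d * np.sqrt(modes.masses_au)[:, None]
    return np.einsum("iax,ax->i", modes.modes, d_mw)
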