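"""The electronic-structure engine and its narrow adapter interface.

Every quantum-chemical quantity the learning pipeline consumes comes
through the functions here: AO operator matrices for a geometry
(:func:`compute_ao_matrices`), converged reference solutions
(:func:`run_reference`), and non-self-consistent evaluation of the
energy, forces, Fock spectrum and orbitals from a *given* 1-rdm.  The
built-in engine implements restricted Hartree–Fock (DIIS-accelerated,
with analytic nuclear gradients) and determinant full CI for systems
with few orbitals; any other GTO-capable engine could be substituted
behind the same call signatures.

Sign conventions: forces are -dE/dR (Hartree/Bohr internally); the
external-potential feature v is the electron–nuclear attraction matrix
only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh

from . import integrals as ints
from .basis import build_shells, n_ao as _count_ao
from .geometry import Geometry
from .units import AU_TO_DEBYE

log = logging.getLogger(__name__)

SUPPORTED_THEORIES = ("HF", "FullCI")


class EngineError(RuntimeError):
    """SCF non-convergence or an invalid engine request."""


@dataclass(frozen=True)
class MethodSpec:
    """Electronic-structure method specification.

    theory : "HF" or "FullCI" (the built-in engine's levels; DFT
        functionals would require an engine with an XC quadrature).
    basis : embedded basis-set name ("sto-3g", "6-31g").
    """

    theory: str = "HF"
    basis: str = "sto-3g"
    scf_tol: float = 1e-10
    max_cycles: int = 200

    def __post_init__(self):
        canon = {t.lower(): t for t in SUPPORTED_THEORIES}
        low = self.theory.lower().replace("-", "")
        if low in ("fci", "fullci"):
            low = "fullci"
        if low not in canon:
            raise EngineError(
                f"theory {self.theory!r} is not provided by the built-in "
                f"engine (available: {SUPPORTED_THEORIES}); DFT levels need "
                "a grid-capable engine plugged in behind this interface"
            )
        object.__setattr__(self, "theory", canon[low])

    def to_dict(self) -> dict:
        return {"theory": self.theory, "basis": self.basis}

    @classmethod
    def from_dict(cls, d: dict) -> "MethodSpec":
        return cls(theory=d.get("theory", "HF"), basis=d.get("basis", "sto-3g"))


@dataclass
class AOMatrices:
    """Operator matrices over the AO basis of one geometry."""

    S: np.ndarray
    t: np.ndarray
    v: np.ndarray          # electron-nuclear attraction (the map-1 feature)
    D: np.ndarray          # (3, n, n) position-operator matrices
    n_ao: int
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))


@dataclass
class ReferenceResult:
    """A converged engine solution for one geometry."""

    gamma: np.ndarray      # spin-summed AO 1-rdm
    energy: float          # Hartree (total, incl. nuclear repulsion)
    forces: np.ndarray     # (N, 3), Hartree/Bohr
    dipole: np.ndarray     # Debye 3-vector
    mo_energies: np.ndarray | None = None
    mo_coeff: np.ndarray | None = None
    converged: bool = True


def charge_center(geom: Geometry) -> np.ndarray:
    """Center of nuclear charge, Bohr (dipole origin)."""
    z = geom.numbers.astype(float)
    return z @ geom.coords_bohr() / z.sum()


class _IntegralCache:
    """Small LRU of per-(geometry, basis) integral sets."""

    def __init__(self, maxsize=12):
        from collections import OrderedDict

        self.data = OrderedDict()
        self.maxsize = maxsize

    @staticmethod
    def key(geom, basis):
        return (geom.symbols, geom.coords.tobytes(), geom.charge, basis.lower())

    def get(self, geom, basis, want_eri=False, want_grad=False):
        k = self.key(geom, basis)
        entry = self.data.get(k)
        stale = (
            entry is None
            or (want_eri and entry[2] is None)
            or (want_grad and entry[3] is None)
        )
        if stale:
            shells = entry[0] if entry else build_shells(geom, basis)
            coords = geom.coords_bohr()
            charges = geom.numbers.astype(float)
            if entry is None:
                origin = charge_center(geom)
                ao = AOMatrices(
                    S=ints.overlap(shells),
                    t=ints.kinetic(shells),
                    v=ints.nuclear_attraction(shells, coords, charges),
                    D=ints.dipole_matrices(shells, origin),
                    n_ao=_count_ao(shells),
                    origin=origin,
                )
            else:
                ao = entry[1]
            V2 = entry[2] if entry else None
            if want_eri and V2 is None:
                V2 = ints.eri(shells)
            grads = entry[3] if entry else None
            if want_grad and grads is None:
                natm = geom.n_atoms
                grads = {
                    "dS": ints.grad_overlap(shells, natm),
                    "dT": ints.grad_kinetic(shells, natm),
                    "dV": ints.grad_nuclear_attraction(
                        shells, coords, charges, natm),
                    "dERI": ints.grad_eri(shells, natm),
                }
            entry = (shells, ao, V2, grads)
            self.data[k] = entry
            if len(self.data) > self.maxsize:
                self.data.popitem(last=False)
        else:
            self.data.move_to_end(k)
        return entry


_cache = _IntegralCache()


def compute_ao_matrices(geom: Geometry, spec: MethodSpec) -> AOMatrices:
    """Overlap, kinetic, external-potential and dipole matrices."""
    return _cache.get(geom, spec.basis)[1]


# ---------------------------------------------------------------------------
# restricted Hartree-Fock

def _fock(P, hcore, V2):
    J = np.einsum("pqrs,rs->pq", V2, P)
    K = np.einsum("prqs,rs->pq", V2, P)
    return hcore + J - 0.5 * K


def _hf_electronic_energy(P, hcore, F):
    return 0.5 * np.einsum("pq,pq->", P, hcore + F)


class _DIIS:
    def __init__(self, max_vec=8):
        self.errs, self.focks, self.max_vec = [], [], max_vec

    def update(self, F, P, S):
        err = F @ P @ S - S @ P @ F
        self.errs.append(err.ravel())
        self.focks.append(F.copy())
        if len(self.errs) > self.max_vec:
            self.errs.pop(0)
            self.focks.pop(0)
        m = len(self.errs)
        if m < 2:
            return F
        B = -np.ones((m + 1, m + 1))
        B[-1, -1] = 0.0
        for i in range(m):
            for j in range(m):
                B[i, j] = self.errs[i] @ self.errs[j]
        rhs = np.zeros(m + 1)
        rhs[-1] = -1.0
        try:
            c = np.linalg.solve(B, rhs)[:m]
        except np.linalg.LinAlgError:
            return F
        return sum(ci * Fi for ci, Fi in zip(c, self.focks))


def _scf(geom: Geometry, spec: MethodSpec):
    """Converge RHF; returns (E_total, P, C, eps, ao, V2, shells)."""
    if geom.multiplicity != 1 or geom.n_electrons % 2:
        raise EngineError("built-in engine is closed-shell (RHF) only")
    shells, ao, V2, _ = _cache.get(geom, spec.basis, want_eri=True)
    hcore = ao.t + ao.v
    nocc = geom.n_electrons // 2
    if nocc > ao.n_ao:
        raise EngineError("more occupied orbitals than basis functions")
    eps, C = eigh(hcore, ao.S)
    P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    diis = _DIIS()
    e_nuc = geom.nuclear_repulsion()
    e_old = None
    for cycle in range(spec.max_cycles):
        F = _fock(P, hcore, V2)
        e_elec = _hf_electronic_energy(P, hcore, F)
        F_eff = diis.update(F, P, ao.S)
        eps, C = eigh(F_eff, ao.S)
        P_new = 2.0 * C[:, :nocc] @ C[:, :nocc].T
        dP = np.abs(P_new - P).max()
        P = P_new
        if e_old is not None and abs(e_elec - e_old) < spec.scf_tol and dP < 1e-8:
            F = _fock(P, hcore, V2)
            eps, C = eigh(F, ao.S)
            P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
            e_elec = _hf_electronic_energy(P, hcore, F)
            return e_elec + e_nuc, P, C, eps, ao, V2, shells
        e_old = e_elec
    raise EngineError(f"SCF did not converge in {spec.max_cycles} cycles")


def _dipole_from_gamma(gamma, ao: AOMatrices, geom: Geometry) -> np.ndarray:
    """Total dipole (Debye), origin at the center of nuclear charge."""
    el = -np.einsum("kpq,pq->k", ao.D, gamma)
    z = geom.numbers.astype(float)
    nuc = z @ (geom.coords_bohr() - ao.origin)
    return (el + nuc) * AU_TO_DEBYE


def _rhf_gradient(geom, spec, P, W):
    """Analytic RHF gradient for a density P and energy-weighted W."""
    natm = geom.n_atoms
    coords = geom.coords_bohr()
    charges = geom.numbers.astype(float)
    g = _cache.get(geom, spec.basis, want_grad=True)[3]
    dS, dT, dV, dERI = g["dS"], g["dT"], g["dV"], g["dERI"]
    grad = np.einsum("axpq,pq->ax", dT + dV, P)
    grad += 0.5 * np.einsum("axpqrs,pq,rs->ax", dERI, P, P)
    grad -= 0.25 * np.einsum("axprqs,pq,rs->ax", dERI, P, P)
    grad -= np.einsum("axpq,pq->ax", dS, W)
    # nuclear-nuclear repulsion
    for i in range(natm):
        for j in range(natm):
            if i == j:
                continue
            rij = coords[i] - coords[j]
            grad[i] += -charges[i] * charges[j] * rij / np.linalg.norm(rij) ** 3
    return grad


def run_reference(geom: Geometry, spec: MethodSpec) -> ReferenceResult:
    """Converged SCF (or full CI) solution: γ, E, forces, dipole."""
    if spec.theory == "FullCI":
        from .fci import run_fci
        return run_fci(geom, spec)
    e_tot, P, C, eps, ao, V2, shells = _scf(geom, spec)
    nocc = geom.n_electrons // 2
    W = 2.0 * (C[:, :nocc] * eps[:nocc]) @ C[:, :nocc].T
    forces = -_rhf_gradient(geom, spec, P, W)
    return ReferenceResult(
        gamma=P, energy=e_tot, forces=forces,
        dipole=_dipole_from_gamma(P, ao, geom),
        mo_energies=eps, mo_coeff=C,
    )


def energy_from_rdm(gamma: np.ndarray, geom: Geometry, spec: MethodSpec) -> float:
    """Evaluate the HF energy functional once at γ (no SCF iterations)."""
    if spec.theory == "FullCI":
        raise EngineError(
            "full CI has no 1-rdm energy functional; use the learned map 2"
        )
    shells, ao, V2, _ = _cache.get(geom, spec.basis, want_eri=True)
    if gamma.shape != (ao.n_ao, ao.n_ao):
        raise ValueError(
            f"gamma shape {gamma.shape} does not match n_ao={ao.n_ao}"
        )
    hcore = ao.t + ao.v
    F = _fock(gamma, hcore, V2)
    return _hf_electronic_energy(gamma, hcore, F) + geom.nuclear_repulsion()


def _one_step_orbitals(gamma, geom, spec):
    shells, ao, V2, _ = _cache.get(geom, spec.basis, want_eri=True)
    if gamma.shape != (ao.n_ao, ao.n_ao):
        raise ValueError(
            f"gamma shape {gamma.shape} does not match n_ao={ao.n_ao}"
        )
    hcore = ao.t + ao.v
    F = _fock(gamma, hcore, V2)
    eps, C = eigh(F, ao.S)
    return eps, C, ao, V2, shells, hcore


def forces_from_rdm(gamma: np.ndarray, geom: Geometry, spec: MethodSpec) -> np.ndarray:
    """Forces from a (predicted) γ via the non-self-consistent route.

    Build the Fock matrix from γ, diagonalize once, occupy by Aufbau and
    evaluate the standard analytic gradient with those orbitals.  When γ
    is the converged SCF density this recovers the exact SCF gradient.
    Returns -dE/dR in Hartree/Bohr.
    """
    if spec.theory == "FullCI":
        raise EngineError("forces from a full-CI 1-rdm must come from map 2")
    eps, C, ao, V2, shells, hcore = _one_step_orbitals(gamma, geom, spec)
    nocc = geom.n_electrons // 2
    if nocc < ao.n_ao and abs(eps[nocc] - eps[nocc - 1]) < 1e-10:
        raise EngineError(
            "degenerate frontier orbitals at the Fermi level; inspect the "
            "purification of the predicted 1-rdm"
        )
    P = 2.0 * C[:, :nocc] @ C[:, :nocc].T
    W = 2.0 * (C[:, :nocc] * eps[:nocc]) @ C[:, :nocc].T
    return -_rhf_gradient(geom, spec, P, W)


def fock_and_orbitals(gamma: np.ndarray, geom: Geometry, spec: MethodSpec):
    """One Fock build from γ + one generalized eigensolve.

    Returns (orbital energies, MO coefficient matrix, HOMO-LUMO gap in
    Hartree).
    """
    if spec.theory == "FullCI":
        raise EngineError("orbital spectra require a mean-field theory")
    eps, C, ao, *_ = _one_step_orbitals(gamma, geom, spec)
    nocc = geom.n_electrons // 2
    gap = float(eps[nocc] - eps[nocc - 1]) if nocc < ao.n_ao else np.nan
    return eps, C, gap


def homo_lumo_gap(gamma, geom, spec) -> float:
    return fock_and_orbitals(gamma, geom, spec)[2]


# ---------------------------------------------------------------------------
# orbitals on a real-space grid (Gaussian cube export)

def _ao_values(shells, points):
    """AO amplitudes on (M, 3) Bohr points; shape (M, n_ao)."""
    from .basis import cartesian_components

    cols = []
    for sh in shells:
        d = points - sh.center
        r2 = np.einsum("md,md->m", d, d)
        radial = np.zeros(len(points))
        for c, a in zip(sh.coefs, sh.exps):
            radial += c * np.exp(-a * r2)
        for lx, ly, lz in cartesian_components(sh.l):
            cols.append(d[:, 0] ** lx * d[:, 1] ** ly * d[:, 2] ** lz * radial)
    return np.array(cols).T


def write_cube(path, geom: Geometry, spec: MethodSpec, coeffs: np.ndarray,
               npts: int = 40, margin: float = 4.0) -> None:
    """Write one molecular orbital as a Gaussian cube file."""
    shells = build_shells(geom, spec.basis)
    lo = geom.coords_bohr().min(axis=0) - margin
    hi = geom.coords_bohr().max(axis=0) + margin
    steps = (hi - lo) / (npts - 1)
    axes = [np.linspace(lo[d], hi[d], npts) for d in range(3)]
    with open(path, "w") as fh:
        fh.write("molecular orbital\ngenerated by rdmlearn\n")
        fh.write(f"{geom.n_atoms:5d} {lo[0]:12.6f} {lo[1]:12.6f} {lo[2]:12.6f}\n")
        for d in range(3):
            vec = np.zeros(3)
            vec[d] = steps[d]
            fh.write(f"{npts:5d} {vec[0]:12.6f} {vec[1]:12.6f} {vec[2]:12.6f}\n")
        for z, r in zip(geom.numbers, geom.coords_bohr()):
            fh.write(f"{z:5d} {float(z):12.6f} {r[0]:12.6f} {r[1]:12.6f} {r[2]:12.6f}\n")
        for x in axes[0]:
            for y in axes[1]:
                pts = np.column_stack([
                    np.full(npts, x), np.full(npts, y), axes[2]
                ])
                vals = _ao_values(shells, pts) @ coeffs
                for start in range(0, npts, 6):
                    chunk = vals[start:start + 6]
                    fh.write(" ".join(f"{v:13.5E}" for v in chunk) + "\n")
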