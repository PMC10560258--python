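"""Molecular dynamics and geometry optimization on surrogate forces.

A force provider is any callable ``geom -> (energy_Ha, forces_Ha_per_Bohr)``;
the conventional engine, and every surrogate route, satisfy this
protocol.  Integration is velocity Verlet (NVE) with an optional
Langevin thermostat (BAOAB splitting) for NVT.  Internal dynamics are
in Hartree atomic units; the stored trajectory uses fs / Å / kcal·mol⁻¹
/ Debye.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import Geometry
from .units import (
    ANG_TO_BOHR,
    BOHR_TO_ANG,
    FS_TO_AU,
    HARTREE_TO_KCALMOL,
    KB_HARTREE,
)

log = logging.getLogger(__name__)

#: abort threshold on any force component, Hartree/Bohr
FORCE_CAP = 5.0


class ForceBlowupError(RuntimeError):
    pass


@dataclass
class Trajectory:
    """A propagated trajectory (uniform timestep)."""

    times: np.ndarray                # fs
    coords: np.ndarray               # (n_frames, N, 3) Å
    velocities: np.ndarray           # (n_frames, N, 3) Bohr / a.u. time
    potential_energies: np.ndarray   # kcal/mol
    total_energies: np.ndarray       # kcal/mol
    dipoles: np.ndarray | None = None  # (n_frames, 3) Debye
    geom0: Geometry | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.times)
        for name in ("coords", "velocities", "potential_energies",
                     "total_energies"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"inconsistent trajectory array {name!r}")
        if len(self.times) > 2:
            dt = np.diff(self.times)
            if not np.allclose(dt, dt[0], rtol=1e-8):
                raise ValueError("non-uniform timestep")

    @property
    def dt_fs(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    def frames(self):
        for c in self.coords:
            yield self.geom0.with_coords(c)


def kinetic_energy_au(velocities, masses_au) -> float:
    return 0.5 * float(np.einsum("a,ax,ax->", masses_au, velocities, velocities))


def instantaneous_temperature(velocities, masses_au) -> float:
    """2 E_kin / (N_dof k_B) with N_dof = 3 N_atoms."""
    ndof = velocities.size
    return 2.0 * kinetic_energy_au(velocities, masses_au) / (ndof * KB_HARTREE)


def maxwell_boltzmann_velocities(geom: Geometry, temperature: float,
                                 seed: int = 0) -> np.ndarray:
    """Random velocities rescaled to the exact instantaneous temperature."""
    rng = np.random.default_rng(seed)
    m = geom.masses_au()
    v = rng.normal(size=(geom.n_atoms, 3)) / np.sqrt(m)[:, None]
    v -= (m @ v) / m.sum()          # remove center-of-mass drift
    t_now = instantaneous_temperature(v, m)
    if t_now > 0 and temperature > 0:
        v *= np.sqrt(temperature / t_now)
    elif temperature == 0:
        v[:] = 0.0
    return v


def mode_kick_velocities(modes, mode_index: int, t_kick: float) -> np.ndarray:
    """Velocities along one normal mode at a given kinetic temperature.

    The Cartesian velocity is proportional to the mass-unweighted mode
    vector; the kick strength is fixed so the instantaneous kinetic
    temperature (N_dof = 3 N_atoms) equals ``t_kick`` exactly.
    """
    if not 0 <= mode_index < modes.n_vib:
        raise IndexError(f"mode index {mode_index} out of range")
    if t_kick < 0:
        raise ValueError("kick temperature must be >= 0")
    m = modes.masses_au
    v = modes.modes[mode_index] / np.sqrt(m)[:, None]
    if t_kick == 0:
        return np.zeros_like(v)
    ekin_target = 0.5 * v.size * KB_HARTREE * t_kick
    ekin_now = kinetic_energy_au(v, m)
    return v * np.sqrt(ekin_target / ekin_now)


def run_md(geom: Geometry, velocities: np.ndarray, force_provider,
           dt_fs: float = 0.5, n_steps: int = 1000,
           ensemble: str = "nve", temperature: float = 300.0,
           friction_per_fs: float = 0.01, seed: int = 0,
           dipole_provider=None, record_every: int = 1) -> Trajectory:
    """Propagate with velocity Verlet (+ Langevin O-step for NVT).

    ``dipole_provider`` (geom -> Debye 3-vector), when given, records the
    dipole at every stored frame.
    """
    if ensemble not in ("nve", "nvt"):
        raise ValueError("ensemble must be 'nve' or 'nvt'")
    m = geom.masses_au()
    dt = dt_fs * FS_TO_AU
    gamma_fric = friction_per_fs / FS_TO_AU
    rng = np.random.default_rng(seed)

    x = geom.coords_bohr().copy()
    v = np.array(velocities, dtype=float)
    e_pot, f = force_provider(geom.with_coords(x * BOHR_TO_ANG))
    _check_forces(f, 0)

    times, xs, vs, epots, etots, dips = [], [], [], [], [], []

    def record(step, e_pot, x, v):
        times.append(step * dt_fs)
        xs.append(x * BOHR_TO_ANG)
        vs.append(v.copy())
        ekin = kinetic_energy_au(v, m)
        epots.append(e_pot * HARTREE_TO_KCALMOL)
        etots.append((e_pot + ekin) * HARTREE_TO_KCALMOL)
        if dipole_provider is not None:
            dips.append(dipole_provider(geom.with_coords(x * BOHR_TO_ANG)))

    record(0, e_pot, x, v)
    for step in range(1, n_steps + 1):
        v_half = v + 0.5 * dt * f / m[:, None]
        if ensemble == "nvt":
            # BAOAB: stochastic O-step between the half kicks
            c1 = np.exp(-gamma_fric * dt)
            c2 = np.sqrt((1.0 - c1 * c1) * KB_HARTREE * temperature / m)
            x = x + 0.5 * dt * v_half
            v_half = c1 * v_half + c2[:, None] * rng.normal(size=v.shape)
            x = x + 0.5 * dt * v_half
        else:
            x = x + dt * v_half
        e_pot, f = force_provider(geom.with_coords(x * BOHR_TO_ANG))
        _check_forces(f, step)
        v = v_half + 0.5 * dt * f / m[:, None]
        if step % record_every == 0:
            record(step, e_pot, x, v)

    return Trajectory(
        times=np.array(times), coords=np.array(xs), velocities=np.array(vs),
        potential_energies=np.array(epots), total_energies=np.array(etots),
        dipoles=np.array(dips) if dips else None,
        geom0=geom,
        meta={
            "dt_fs": dt_fs, "ensemble": ensemble, "seed": seed,
            "temperature": temperature,
            "provider": getattr(force_provider, "label", "unknown"),
        },
    )


def _check_forces(f, step):
    if not np.all(np.isfinite(f)) or np.abs(f).max() > FORCE_CAP:
        raise ForceBlowupError(
            f"force exceeded {FORCE_CAP} Hartree/Bohr at step {step}"
        )


# ---------------------------------------------------------------------------
# geometry optimization

class OptimizationError(RuntimeError):
    def __init__(self, msg, last_geometry=None):
        super().__init__(msg)
        self.last_geometry = last_geometry


def optimize_geometry(geom: Geometry, force_provider,
                      fmax: float = 4e-4, max_steps: int = 200):
    """Relax until max |F| < fmax (Hartree/Bohr).

    BFGS on the provider's energy/gradient first; if that stalls — which
    happens when energies and forces come from *independent* regressions
    and the gradient is therefore not exactly ∇E — a force-only FIRE
    descent refines from the best geometry seen.  Returns
    (relaxed_geometry, path).
    """
    from scipy.optimize import minimize

    path = []

    def fun(x):
        g = geom.with_coords(x.reshape(-1, 3))
        e, f = force_provider(g)
        path.append((g, float(np.abs(f).max())))
        # dE/dR_Å = -F[Ha/Bohr] * (Bohr per Å)
        return e, (-f * ANG_TO_BOHR).ravel()

    class _Converged(Exception):
        pass

    def cb(x):
        if path and path[-1][1] < fmax:
            raise _Converged

    e0, f0 = force_provider(geom)
    if np.abs(f0).max() < fmax:
        return geom, [(geom, float(np.abs(f0).max()))]
    try:
        minimize(fun, geom.coords.ravel(), jac=True, method="BFGS",
                 callback=cb, options={"maxiter": max_steps, "gtol": 1e-12})
    except _Converged:
        pass
    converged = [g for g, fm in path if fm < fmax]
    if converged:
        return converged[0], [g for g, _ in path]
    # FIRE refinement from the best geometry visited
    best = min(path, key=lambda t: t[1])[0] if path else geom
    g_fire, fire_path = _fire(best, force_provider, fmax, max_steps)
    path.extend((g, np.nan) for g in fire_path)
    if g_fire is None:
        raise OptimizationError(
            f"geometry optimization did not reach max|F| < {fmax} in "
            f"{max_steps} steps",
            last_geometry=path[-1][0] if path else geom,
        )
    return g_fire, [g for g, _ in path]


def _fire(geom, force_provider, fmax, max_steps,
          dt0=0.4, dt_max=2.0, max_disp=0.05):
    """Force-only FIRE minimization (unit masses, Å / Hartree/Bohr)."""
    x = geom.coords.copy()
    v = np.zeros_like(x)
    dt, alpha, n_up = dt0, 0.1, 0
    path = []
    for _ in range(max_steps):
        _, f = force_provider(geom.with_coords(x))
        path.append(geom.with_coords(x.copy()))
        if np.abs(f).max() < fmax:
            return geom.with_coords(x), path
        p = float(np.sum(f * v))
        if p > 0:
            n_up += 1
            if n_up > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            v[:] = 0.0
            dt = max(dt * 0.5, 1e-3)
            alpha, n_up = 0.1, 0
        v = v + dt * f
        fn = np.linalg.norm(f)
        if fn > 0:
            v = (1 - alpha) * v + alpha * np.linalg.norm(v) * f / fn
        step = dt * v
        norm = np.abs(step).max()
        if norm > max_disp:
            step *= max_disp / norm
        x = x + step
    return None, path
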