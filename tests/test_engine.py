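"""Engine checks: SCF, one-shot functionals, orbitals, full CI.

The independent oracles are closed-form minimal-basis solutions and
finite differences of the converged energy.
"""

import numpy as np
import pytest
from scipy.linalg import eigh

from rdmlearn import integrals as ints
from rdmlearn.basis import build_shells
from rdmlearn.engine import (
    EngineError,
    MethodSpec,
    compute_ao_matrices,
    energy_from_rdm,
    fock_and_orbitals,
    forces_from_rdm,
    homo_lumo_gap,
    run_reference,
)
from rdmlearn.geometry import Geometry
from rdmlearn.rdm import purify_aufbau
from rdmlearn.units import BOHR_TO_ANG

SPEC = MethodSpec("HF", "sto-3g")


def test_methodspec_rejects_unavailable_theories():
    with pytest.raises(EngineError, match="engine"):
        MethodSpec("LDA", "sto-3g")
    with pytest.raises(EngineError):
        MethodSpec("B3LYP", "sto-3g")


def test_h2_hf_matches_closed_form_two_level_solution(h2_eq_min):
    """Minimal-basis H2 RHF has an analytic 2×2 solution.

    By symmetry the occupied MO is (φ1+φ2)/√(2+2S12); the oracle builds
    the energy directly from that orbital and the raw integrals, with
    no SCF iterations.
    """
    geom = h2_eq_min
    sh = build_shells(geom, "sto-3g")
    S = ints.overlap(sh)
    h = ints.kinetic(sh) + ints.nuclear_attraction(
        sh, geom.coords_bohr(), geom.numbers.astype(float))
    V2 = ints.eri(sh)
    c = 1.0 / np.sqrt(2.0 + 2.0 * S[0, 1])
    mo = np.array([c, c])
    e1 = 2.0 * mo @ h @ mo
    e2 = np.einsum("p,q,r,s,pqrs->", mo, mo, mo, mo, V2)
    oracle = e1 + e2 + geom.nuclear_repulsion()
    res = run_reference(geom, SPEC)
    assert res.energy == pytest.approx(oracle, abs=1e-8)


@pytest.mark.parametrize("basis,n_elec", [("sto-3g", 10), ("6-31g", 10)])
def test_reference_density_traces_to_electron_count(basis, n_elec):
    geom = Geometry(("O", "H", "H"),
                    [[0.0, 0.0, 0.12], [0.0, 0.75, -0.46], [0.0, -0.75, -0.48]])
    spec = MethodSpec("HF", basis)
    res = run_reference(geom, spec)
    ao = compute_ao_matrices(geom, spec)
    assert np.trace(res.gamma @ ao.S) == pytest.approx(n_elec, abs=1e-8)


def test_energy_functional_is_stationary_at_converged_density(water_eq_min):
    res = run_reference(water_eq_min, SPEC)
    e = energy_from_rdm(res.gamma, water_eq_min, SPEC)
    assert e == pytest.approx(res.energy, abs=1e-8)


def test_zero_density_gives_nuclear_repulsion_only(water_eq_min):
    ao = compute_ao_matrices(water_eq_min, SPEC)
    e = energy_from_rdm(np.zeros((ao.n_ao, ao.n_ao)), water_eq_min, SPEC)
    assert e == pytest.approx(water_eq_min.nuclear_repulsion(), abs=1e-12)


def test_energy_rises_monotonically_for_perturbed_purified_densities(water_eq_min, rng):
    """The HF functional is variational over Aufbau N-representable γ."""
    res = run_reference(water_eq_min, SPEC)
    ao = compute_ao_matrices(water_eq_min, SPEC)
    direction = rng.normal(size=res.gamma.shape)
    direction = 0.5 * (direction + direction.T)
    energies = [res.energy]
    for eps in (1e-4, 1e-3, 1e-2):
        g = purify_aufbau(res.gamma + eps * direction, ao.S, 10)
        energies.append(energy_from_rdm(g, water_eq_min, SPEC))
    assert all(e >= res.energy - 1e-10 for e in energies[1:])
    assert energies[1] <= energies[2] <= energies[3]


def test_forces_vanish_at_relaxed_geometry(water_eq_min):
    res = run_reference(water_eq_min, SPEC)
    assert np.abs(res.forces).max() < 1e-3


def test_forces_from_converged_density_equal_scf_gradient():
    geom = Geometry(("O", "H", "H"),
                    [[0.03, 0.0, 0.14], [0.0, 0.78, -0.42], [0.0, -0.72, -0.49]])
    res = run_reference(geom, SPEC)
    f = forces_from_rdm(res.gamma, geom, SPEC)
    np.testing.assert_allclose(f, res.forces, atol=1e-6)


def test_analytic_forces_match_finite_difference_oracle(h2_eq_min):
    geom = h2_eq_min.with_coords(h2_eq_min.coords + [[0, 0, 0], [0, 0, 0.05]])
    res = run_reference(geom, SPEC)
    h = 1e-4
    cp = geom.coords.copy()
    cp[1, 2] += h * BOHR_TO_ANG
    cm = geom.coords.copy()
    cm[1, 2] -= h * BOHR_TO_ANG
    fd = -(run_reference(geom.with_coords(cp), SPEC).energy
           - run_reference(geom.with_coords(cm), SPEC).energy) / (2 * h)
    assert res.forces[1, 2] == pytest.approx(fd, abs=1e-4)


def test_gap_matches_scf_and_is_rotation_invariant(water_eq_min):
    res = run_reference(water_eq_min, SPEC)
    nocc = 5
    gap_scf = res.mo_energies[nocc] - res.mo_energies[nocc - 1]
    assert homo_lumo_gap(res.gamma, water_eq_min, SPEC) == pytest.approx(
        gap_scf, abs=1e-8)
    # rigid rotation
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
    rot = water_eq_min.with_coords(water_eq_min.coords @ R.T)
    res_rot = run_reference(rot, SPEC)
    assert homo_lumo_gap(res_rot.gamma, rot, SPEC) == pytest.approx(
        gap_scf, abs=1e-8)


def test_gap_closes_monotonically_on_oh_stretch(water_eq_min):
    """Stretching one O-H bond narrows the frontier gap (conventional SCF)."""
    gaps = []
    for stretch in (1.0, 1.3, 1.6):
        c = water_eq_min.coords.copy()
        oh = c[1] - c[0]
        c[1] = c[0] + oh * stretch
        g = water_eq_min.with_coords(c)
        res = run_reference(g, SPEC)
        gaps.append(homo_lumo_gap(res.gamma, g, SPEC))
    assert gaps[0] > gaps[1] > gaps[2]


def test_orbital_cube_export(tmp_path, h2_eq_min):
    """Cube export writes a well-formed grid whose HOMO density is
    symmetric about the bond midpoint."""
    from rdmlearn.engine import write_cube

    res = run_reference(h2_eq_min, SPEC)
    path = tmp_path / "homo.cube"
    write_cube(path, h2_eq_min, SPEC, res.mo_coeff[:, 0], npts=12)
    lines = path.read_text().splitlines()
    assert int(lines[2].split()[0]) == 2          # atom count
    vals = np.array([float(v) for ln in lines[8:] for v in ln.split()])
    assert len(vals) == 12 ** 3
    grid = vals.reshape(12, 12, 12)
    # bonding orbital: mirror symmetry along the bond (z) axis
    np.testing.assert_allclose(grid, grid[:, :, ::-1], atol=1e-5)


# ---------------------------------------------------------------------------
# full CI

def test_h2_fci_matches_two_determinant_oracle(h2_eq_min):
    """Minimal-basis H2 full CI is a 2×2 eigenproblem in {|σg²⟩, |σu²⟩}.

    The oracle diagonalizes that matrix built directly from MO
    integrals (Slater–Condon by hand), independent of the string-based
    CI code.
    """
    spec = MethodSpec("FullCI", "sto-3g")
    res = run_reference(h2_eq_min, spec)

    hf = run_reference(h2_eq_min, SPEC)
    C = hf.mo_coeff
    sh = build_shells(h2_eq_min, "sto-3g")
    hmo = C.T @ (ints.kinetic(sh) + ints.nuclear_attraction(
        sh, h2_eq_min.coords_bohr(), h2_eq_min.numbers.astype(float))) @ C
    vmo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", ints.eri(sh), C, C, C, C)
    H00 = 2 * hmo[0, 0] + vmo[0, 0, 0, 0]
    H11 = 2 * hmo[1, 1] + vmo[1, 1, 1, 1]
    H01 = vmo[0, 1, 0, 1]
    w = np.linalg.eigvalsh(np.array([[H00, H01], [H01, H11]]))
    oracle = w[0] + h2_eq_min.nuclear_repulsion()
    assert res.energy == pytest.approx(oracle, abs=1e-10)
    # correlation lowers the energy below HF
    assert res.energy < hf.energy - 1e-3


def test_fci_density_has_fractional_occupations_summing_to_n(h2_eq_min):
    spec = MethodSpec("FullCI", "sto-3g")
    res = run_reference(h2_eq_min, spec)
    ao = compute_ao_matrices(h2_eq_min, spec)
    from rdmlearn.rdm import occupations

    occ = occupations(res.gamma, ao.S)
    assert occ.sum() == pytest.approx(2.0, abs=1e-10)
    assert 0.0 < occ[-1] < 0.1          # small but nonzero antibonding occ
    assert 1.9 < occ[0] < 2.0
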