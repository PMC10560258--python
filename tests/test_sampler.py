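"""Normal-mode sampling: widths, counts, distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rdmlearn.geometry import Geometry
from rdmlearn.sampler import (
    NormalModes,
    SamplePlan,
    default_sample_count,
    generate_samples,
    hessian_finite_difference,
    mode_sigma,
    n_vibrational,
    normal_modes_from_hessian,
    project_on_modes,
)
from rdmlearn.units import AMU_TO_ME, KB_HARTREE


def test_sample_count_rule_reproduces_benchmark_sizes():
    """N_vib³ rule: 27 / 216 / 5184 (3 conformers) / 13824 / 41472."""
    assert default_sample_count(3) == 27
    assert default_sample_count(6) == 216
    assert default_sample_count(12, n_conformers=3) == 5184
    assert default_sample_count(30) == 13824
    assert default_sample_count(30, n_conformers=3) == 41472


def test_sigma_formula_against_symbolic_oracle():
    """σ_i² = 2 k_B T N_atoms / [Ω² N_vib (1 − 2/(9 N_vib))³], exact."""
    import sympy as sp

    T, Na, Nv = 300.0, 3, 3
    omega = 0.01
    kb, Tt, om = sp.Float(KB_HARTREE, 30), sp.Integer(300), sp.Rational(1, 100)
    var = 2 * kb * Tt * Na / (om ** 2 * Nv * (1 - sp.Rational(2, 9 * Nv)) ** 3)
    expect = float(sp.sqrt(var))
    assert mode_sigma(omega, T, Na, Nv) == pytest.approx(expect, rel=1e-12)


def test_doubling_frequency_halves_sigma():
    s1 = mode_sigma(0.004, 300.0, 3, 3)
    s2 = mode_sigma(0.008, 300.0, 3, 3)
    assert s1 == pytest.approx(2.0 * s2, rel=1e-14)


@given(
    omegas=st.lists(st.floats(1e-4, 5e-2), min_size=2, max_size=8),
    temp=st.floats(10.0, 1000.0),
)
@settings(max_examples=50, deadline=None)
def test_energy_scaled_variance_is_mode_independent(omegas, temp):
    """σ_i²Ω_i² is one constant per molecule (algebraic identity)."""
    omegas = np.array(omegas)
    n_vib = len(omegas)
    sig = mode_sigma(omegas, temp, n_vib + 2, n_vib)
    scaled = sig ** 2 * omegas ** 2
    np.testing.assert_allclose(scaled, scaled[0], rtol=1e-12)


def test_nonpositive_frequency_rejected():
    with pytest.raises(ValueError):
        mode_sigma(0.0, 300.0, 3, 3)


def _toy_diatomic_modes(k_au=0.37, r0=0.74):
    """Analytic normal modes of a harmonic diatomic (spring constant k)."""
    geom = Geometry(("H", "H"), [[0, 0, 0], [0, 0, r0]])

    def forces(g):
        dz = (g.coords[1, 2] - g.coords[0, 2] - r0) / 0.529177210903
        f = k_au * dz
        return np.array([[0, 0, f], [0, 0, -f]])

    hess = hessian_finite_difference(forces, geom)
    return normal_modes_from_hessian(hess, geom), geom, k_au


def test_harmonic_diatomic_frequency_matches_closed_form():
    """ω = √(k/μ) for a spring dimer, recovered to 0.1%."""
    modes, geom, k = _toy_diatomic_modes()
    mu = geom.masses_au().prod() / geom.masses_au().sum()
    assert modes.n_vib == 1
    assert modes.frequencies[0] == pytest.approx(np.sqrt(k / mu), rel=1e-3)


def test_diatomic_has_single_vibration_and_water_three(water_modes_min):
    modes, _, _ = _toy_diatomic_modes()
    assert modes.n_vib == 1
    assert water_modes_min.n_vib == 3
    assert np.all(water_modes_min.frequencies > 0)
    assert np.all(np.diff(water_modes_min.frequencies) >= 0)


def test_linear_triatomic_keeps_four_modes():
    co2 = Geometry(("O", "C", "O"), [[0, 0, -1.16], [0, 0, 0], [0, 0, 1.16]])
    assert n_vibrational(co2) == 4


def test_samples_are_deterministic_and_centered(water_modes_min):
    plan = SamplePlan(temperature=300.0, n_samples=10, seed=5)
    a = generate_samples(water_modes_min, plan)
    b = generate_samples(water_modes_min, plan)
    for ga, gb in zip(a, b):
        np.testing.assert_array_equal(ga.coords, gb.coords)


def test_empirical_mode_variance_matches_sigma(water_modes_min):
    """Projected sample variance per mode is within 5% of σ_i² (10k draws)."""
    plan = SamplePlan(temperature=300.0, n_samples=10000, seed=2)
    samples = generate_samples(water_modes_min, plan)
    q = np.array([project_on_modes(water_modes_min, g) for g in samples])
    sig = mode_sigma(water_modes_min.frequencies, 300.0, 3, 3)
    np.testing.assert_allclose(q.std(axis=0), sig, rtol=0.05)


def test_zero_temperature_limit_returns_equilibrium(water_modes_min):
    """As σ→0 (T→0⁺) every sample approaches the equilibrium geometry."""
    plan = SamplePlan(temperature=1e-12, n_samples=5, seed=3)
    for g in generate_samples(water_modes_min, plan):
        np.testing.assert_allclose(
            g.coords, water_modes_min.equilibrium.coords, atol=1e-6)


def test_hydroxyl_rotation_generates_equally_spaced_conformers():
    """Rotating the O-H hydrogen about the C-O axis preserves the O-H
    bond length and spaces the H positions by 120° (3 conformers)."""
    from rdmlearn.sampler import hydroxyl_rotation_conformers

    methanol = Geometry(
        ("C", "O", "H", "H", "H", "H"),
        [[-0.047, 0.664, 0.0], [-0.047, -0.758, 0.0], [0.878, -1.048, 0.0],
         [-1.092, 0.969, 0.0], [0.437, 1.080, 0.891],
         [0.437, 1.080, -0.891]],
    )
    confs = hydroxyl_rotation_conformers(methanol, c_index=0, o_index=1,
                                         h_index=2, n_conformers=3)
    assert len(confs) == 3
    o = methanol.coords[1]
    d0 = np.linalg.norm(methanol.coords[2] - o)
    axis = (methanol.coords[1] - methanol.coords[0])
    axis /= np.linalg.norm(axis)
    angles = []
    for c in confs:
        assert np.linalg.norm(c.coords[2] - o) == pytest.approx(d0, abs=1e-10)
        # all other atoms untouched
        np.testing.assert_array_equal(np.delete(c.coords, 2, axis=0),
                                      np.delete(methanol.coords, 2, axis=0))
        v = c.coords[2] - o
        v_perp = v - (v @ axis) * axis
        angles.append(np.arctan2(np.cross(axis, v_perp) @ axis_ref(axis),
                                 v_perp @ axis_ref(axis)))
    diffs = np.diff(sorted(np.mod(angles, 2 * np.pi)))
    np.testing.assert_allclose(diffs, 2 * np.pi / 3, atol=1e-8)


def axis_ref(axis):
    """A unit vector perpendicular to the given axis (deterministic)."""
    trial = np.array([1.0, 0.0, 0.0])
    if abs(trial @ axis) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    v = trial - (trial @ axis) * axis
    return v / np.linalg.norm(v)


def test_sampled_energies_are_boltzmann_like(water_modes_min, spec_min,
                                             water_eq_min):
    """Sampled harmonic energies overlap a 300 K thermal distribution.

    Compares the harmonic-model energy histogram of the sampled
    geometries with the analytic Γ-like equipartition expectation by a
    two-sample Kolmogorov–Smirnov distance against a direct Boltzmann
    draw in normal coordinates.
    """
    from scipy.stats import ks_2samp

    plan = SamplePlan(temperature=300.0, n_samples=400, seed=8)
    samples = generate_samples(water_modes_min, plan)
    q = np.array([project_on_modes(water_modes_min, g) for g in samples])
    e_sample = 0.5 * (q ** 2 * water_modes_min.frequencies ** 2).sum(axis=1)
    rng = np.random.default_rng(9)
    sig = mode_sigma(water_modes_min.frequencies, 300.0, 3, 3)
    q_direct = rng.normal(0.0, sig, size=(400, 3))
    e_direct = 0.5 * (q_direct ** 2 * water_modes_min.frequencies ** 2).sum(axis=1)
    stat, p = ks_2samp(e_sample, e_direct)
    assert stat < 0.15
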