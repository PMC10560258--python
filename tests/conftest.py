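"""Shared fixtures.

Engine-heavy artifacts (relaxed water, normal modes, training sets) are
session-scoped so the expensive reference calculations run once per
test session.  Everything is generated programmatically — no stored
data files.
"""

from __future__ import annotations

import numpy as np
import pytest

from rdmlearn.engine import MethodSpec
from rdmlearn.geometry import Geometry
from rdmlearn.md import optimize_geometry
from rdmlearn.sampler import SamplePlan, generate_samples, normal_mode_analysis
from rdmlearn.store import build_training_set
from rdmlearn.surrogate import DensitySurrogate, engine_force_provider

WATER_GUESS = Geometry(
    ("O", "H", "H"),
    [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]],
)

H2_GUESS = Geometry(("H", "H"), [[0.0, 0.0, 0.0], [0.0, 0.0, 0.74]])


@pytest.fixture(scope="session")
def spec_min():
    return MethodSpec("HF", "sto-3g")


@pytest.fixture(scope="session")
def spec_dz():
    return MethodSpec("HF", "6-31g")


@pytest.fixture(scope="session")
def water_eq_min(spec_min):
    geom, _ = optimize_geometry(
        WATER_GUESS, engine_force_provider(spec_min), fmax=1e-5)
    return geom


@pytest.fixture(scope="session")
def water_modes_min(water_eq_min, spec_min):
    return normal_mode_analysis(water_eq_min, spec_min)


@pytest.fixture(scope="session")
def water_ts_min(water_eq_min, water_modes_min, spec_min):
    """27-sample STO-3G water training set at 300 K."""
    plan = SamplePlan(temperature=300.0, n_samples="auto", seed=11)
    return build_training_set(
        water_eq_min, spec_min, plan, modes_list=[water_modes_min])


@pytest.fixture(scope="session")
def water_surrogate_min(water_ts_min):
    return DensitySurrogate(lam=1e-10, alpha=1e-8).fit(water_ts_min)


@pytest.fixture(scope="session")
def water_test_geoms_min(water_modes_min):
    return generate_samples(
        water_modes_min, SamplePlan(temperature=300.0, n_samples=50, seed=999))


@pytest.fixture(scope="session")
def h2_eq_min(spec_min):
    geom, _ = optimize_geometry(
        H2_GUESS, engine_force_provider(spec_min), fmax=1e-6)
    return geom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# -- scaled benchmark in the split-valence basis (engine-heavy, built once) --

@pytest.fixture(scope="session")
def water_eq_dz(spec_dz):
    geom, _ = optimize_geometry(
        WATER_GUESS, engine_force_provider(spec_dz), fmax=1e-5)
    return geom


@pytest.fixture(scope="session")
def water_modes_dz(water_eq_dz, spec_dz):
    return normal_mode_analysis(water_eq_dz, spec_dz)


@pytest.fixture(scope="session")
def water_benchmark_dz(water_eq_dz, water_modes_dz, spec_dz):
    """27-sample water surrogate at 300 K, evaluated on 50 held-out
    geometries: the scaled benchmark table (one row per model variant)."""
    from rdmlearn.store import rmsd_report

    plan = SamplePlan(temperature=300.0, n_samples="auto", seed=11)
    ts = build_training_set(
        water_eq_dz, spec_dz, plan, modes_list=[water_modes_dz])
    surr = DensitySurrogate(lam=1e-10, alpha=1e-8).fit(ts)
    test = generate_samples(
        water_modes_dz, SamplePlan(temperature=300.0, n_samples=50, seed=999))
    report = rmsd_report(surr, test)
    return {"surrogate": surr, "training_set": ts, "report": report,
            "test_geometries": test}
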