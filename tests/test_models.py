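"""Map-1 KRR and map-2 ridge estimators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from rdmlearn.models import (
    DeltaRefiner,
    GammaKRR,
    featurize,
    trace_kernel,
    unfeaturize,
)


def _sym_stack(rng, n_samples, n):
    a = rng.normal(size=(n_samples, n, n))
    return 0.5 * (a + a.transpose(0, 2, 1))


# ---------------------------------------------------------------------------
# trace kernel

def test_trace_kernel_hand_value():
    """Tr([[1,2],[2,3]] · [[0,1],[1,0]]) = 4 by direct multiplication."""
    a = np.array([[1.0, 2.0], [2.0, 3.0]])
    b = np.array([[0.0, 1.0], [1.0, 0.0]])
    assert trace_kernel(a, b) == pytest.approx(4.0)
    assert trace_kernel(b, a) == pytest.approx(4.0)


def test_trace_kernel_zero_and_positivity(rng):
    v = _sym_stack(rng, 1, 4)[0]
    assert trace_kernel(np.zeros((4, 4)), v) == 0.0
    assert trace_kernel(v, v) >= 0.0
    with pytest.raises(ValueError):
        trace_kernel(np.eye(2), np.eye(3))


# ---------------------------------------------------------------------------
# GammaKRR

def test_single_sample_coefficient_formula(rng):
    """With one sample and λ=0: β = γ / K(v, v)."""
    V = _sym_stack(rng, 1, 3)
    G = _sym_stack(rng, 1, 3)
    m = GammaKRR(lam=0.0).fit(V, G)
    np.testing.assert_allclose(
        m.beta_[0], G[0] / trace_kernel(V[0], V[0]), atol=1e-12)


def test_two_sample_fit_matches_explicit_inverse(rng):
    """2×2 kernel system solved by the closed-form matrix inverse."""
    V = _sym_stack(rng, 2, 3)
    G = _sym_stack(rng, 2, 3)
    K = np.array([[trace_kernel(V[i], V[j]) for j in range(2)]
                  for i in range(2)])
    det = K[0, 0] * K[1, 1] - K[0, 1] * K[1, 0]
    Kinv = np.array([[K[1, 1], -K[0, 1]], [-K[1, 0], K[0, 0]]]) / det
    beta_oracle = np.einsum("ij,jpq->ipq", Kinv, G)
    m = GammaKRR(lam=0.0).fit(V, G)
    np.testing.assert_allclose(m.beta_, beta_oracle, atol=1e-10)


def test_interpolation_at_training_points(rng):
    """λ=0 + nonsingular kernel ⇒ exact reproduction of training γ̂."""
    V = _sym_stack(rng, 8, 4)
    G = _sym_stack(rng, 8, 4)
    m = GammaKRR(lam=0.0).fit(V, G)
    pred = m.predict(V)
    np.testing.assert_allclose(pred, G, atol=1e-8)


def test_prediction_is_symmetric(rng):
    V = _sym_stack(rng, 6, 5)
    G = _sym_stack(rng, 6, 5)
    m = GammaKRR(lam=1e-10).fit(V, G)
    g = m.predict_one(_sym_stack(rng, 1, 5)[0])
    assert np.abs(g - g.T).max() < 1e-12


def test_large_lambda_shrinks_coefficients_to_zero(rng):
    V = _sym_stack(rng, 5, 3)
    G = _sym_stack(rng, 5, 3)
    m = GammaKRR(lam=1e12).fit(V, G)
    assert np.abs(m.beta_).max() < 1e-8


def test_duplicate_samples_are_deduplicated(rng):
    V = _sym_stack(rng, 3, 3)
    V = np.concatenate([V, V[:1]])          # exact duplicate
    G = np.concatenate([_sym_stack(rng, 3, 3), _sym_stack(rng, 1, 3)])
    m = GammaKRR(lam=0.0).fit(V, G)
    assert len(m.V_train_) == 3


def test_agrees_with_generic_kernel_ridge(rng):
    """Independent cross-check against sklearn KernelRidge on the
    precomputed trace-kernel Gram matrix."""
    from sklearn.kernel_ridge import KernelRidge

    V = _sym_stack(rng, 10, 4)
    G = _sym_stack(rng, 10, 4)
    lam = 1e-6
    m = GammaKRR(lam=lam).fit(V, G)
    K = V.reshape(10, -1) @ V.reshape(10, -1).T
    skm = KernelRidge(alpha=lam, kernel="precomputed")
    skm.fit(K, G.reshape(10, -1))
    q = _sym_stack(rng, 4, 4)
    kq = V.reshape(10, -1) @ q.reshape(4, -1).T
    np.testing.assert_allclose(
        m.predict(q).reshape(4, -1), skm.predict(kq.T), atol=1e-8)


def test_loo_lambda_selection_handles_ill_conditioned_kernels(rng):
    """With nearly collinear samples, λ='loo' picks a finite ridge that
    beats the near-interpolation default on held-out points."""
    t = np.linspace(0, 1, 12)
    base = _sym_stack(rng, 3, 4)
    # smooth nonlinear 1-D family: ill-conditioned linear kernel
    V = np.stack([base[0] + s * base[1] + s ** 2 * base[2] for s in t])
    G = np.stack([np.cos(3 * s) * base[0] + np.sin(2 * s) * base[1]
                  for s in t])
    m_loo = GammaKRR(lam="loo").fit(V, G)
    assert m_loo.lambda_ > 0
    t_test = 0.5 * (t[3] + t[4])
    v_test = base[0] + t_test * base[1] + t_test ** 2 * base[2]
    g_true = np.cos(3 * t_test) * base[0] + np.sin(2 * t_test) * base[1]
    err_loo = np.linalg.norm(m_loo.predict_one(v_test) - g_true)
    m_def = GammaKRR(lam=1e-10).fit(V, G)
    err_def = np.linalg.norm(m_def.predict_one(v_test) - g_true)
    assert err_loo <= err_def * 1.001


def test_dimension_mismatch_raises(rng):
    m = GammaKRR().fit(_sym_stack(rng, 3, 3), _sym_stack(rng, 3, 3))
    with pytest.raises(ValueError, match="n_ao"):
        m.predict_one(np.eye(4))


def test_sklearn_param_interface_roundtrip():
    m = GammaKRR(lam=1e-5)
    assert m.get_params()["lam"] == 1e-5
    m.set_params(lam=1e-3)
    assert m.lam == 1e-3


# ---------------------------------------------------------------------------
# featurize

@given(st.integers(2, 8), st.integers(0, 2 ** 31 - 1))
@settings(max_examples=40, deadline=None)
def test_featurize_unfeaturize_roundtrip(n, seed):
    rng = np.random.default_rng(seed)
    g = _sym_stack(rng, 1, n)[0]
    vec = featurize(g)
    assert vec.shape == (n * (n + 1) // 2,)
    np.testing.assert_allclose(unfeaturize(vec, n), g, atol=1e-12)


def test_featurize_hand_ordering():
    g = np.array([[1.0, 2.0], [2.0, 3.0]])
    np.testing.assert_array_equal(featurize(g), [1.0, 2.0, 3.0])


def test_feature_length_for_24_orbitals():
    n = 24
    g = np.zeros((n, n))
    assert featurize(g).shape == (300,)


# ---------------------------------------------------------------------------
# DeltaRefiner

def test_constant_target_gives_intercept_only(rng):
    X = _sym_stack(rng, 6, 3)
    y = {"energy": np.full((6, 1), -7.5)}
    m = DeltaRefiner(alpha=1e-8).fit(X, y)
    assert np.abs(m.models_["energy"].coef_).max() < 1e-6
    pred = m.predict_one(_sym_stack(rng, 1, 3)[0], "energy")
    assert pred[0] == pytest.approx(-7.5, abs=1e-8)


def test_exactly_linear_map_is_recovered(rng):
    """E = w·features + b with α→0 recovers w to 1e-8."""
    X = _sym_stack(rng, 40, 4)
    w = rng.normal(size=10)
    y = featurize(X) @ w + 2.5
    m = DeltaRefiner(alpha=1e-12).fit(X, {"energy": y[:, None]})
    np.testing.assert_allclose(m.models_["energy"].coef_.ravel(), w, atol=1e-8)


def test_huge_alpha_predicts_target_mean(rng):
    X = _sym_stack(rng, 20, 3)
    y = rng.normal(size=(20, 1))
    m = DeltaRefiner(alpha=1e12).fit(X, {"energy": y})
    pred = m.predict_one(_sym_stack(rng, 1, 3)[0], "energy")
    assert pred[0] == pytest.approx(y.mean(), abs=1e-6)


def test_training_targets_reproduced_on_full_rank_design(rng):
    """Interpolation when features outnumber samples and α→0."""
    X = _sym_stack(rng, 5, 4)       # 10 features > 5 samples
    y = rng.normal(size=(5, 2))
    m = DeltaRefiner(alpha=1e-14).fit(X, {"dipole": y})
    np.testing.assert_allclose(m.predict(X, "dipole"), y, atol=1e-6)


def test_nonfinite_target_is_named(rng):
    X = _sym_stack(rng, 4, 3)
    y = np.zeros((4, 1))
    y[2] = np.nan
    with pytest.raises(ValueError, match="2"):
        DeltaRefiner().fit(X, {"energy": y})


def test_multi_target_shapes_roundtrip(rng):
    X = _sym_stack(rng, 12, 3)
    forces = rng.normal(size=(12, 3, 3))
    m = DeltaRefiner(alpha=1e-8).fit(X, {"forces": forces})
    out = m.predict_one(X[0], "forces")
    assert out.shape == (3, 3)
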