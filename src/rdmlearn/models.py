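"""The two learned maps, as scikit-learn-style estimators.

``GammaKRR`` (map 1, "γ-learning") is kernel ridge regression from
external-potential matrices v̂ to 1-rdms γ̂ with the trace kernel
K(v̂_i, v̂_j) = Tr[v̂_i v̂_j].  The dual coefficients are themselves
AO×AO matrices, β̂_i = Σ_j [(K + λI)⁻¹]_{ij} γ̂_j, and the prediction is
γ̂[v̂] = Σ_i β̂_i K(v̂_i, v̂).  With λ → 0 and a nonsingular kernel the
model interpolates its training set exactly — the regime in which the
predicted densities reach SCF-level accuracy.

``DeltaRefiner`` (map 2, "γ+δ-learning") is regularized linear (ridge)
regression from the flattened upper triangle of a predicted γ to any
requested targets: the residual Δγ = γ̂ − γ̂^p, the total energy, the
atomic forces (in the aligned internal frame) and the dipole vector.

Both estimators follow scikit-learn conventions: ``fit``/``predict``,
``get_params``/``set_params``, fitted attributes with a trailing
underscore, and validation on entry.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# symmetric-matrix (un)flattening

def featurize(gamma: np.ndarray) -> np.ndarray:
    """Upper-triangular entries of a symmetric matrix, row-major."""
    gamma = np.asarray(gamma)
    n = gamma.shape[-1]
    iu = np.triu_indices(n)
    return gamma[..., iu[0], iu[1]]


def unfeaturize(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`featurize` onto a symmetric n×n matrix."""
    iu = np.triu_indices(n)
    out = np.zeros(vec.shape[:-1] + (n, n))
    out[..., iu[0], iu[1]] = vec
    out = out + np.swapaxes(out, -1, -2)
    diag = np.arange(n)
    out[..., diag, diag] *= 0.5
    return out


def trace_kernel(v_a: np.ndarray, v_b: np.ndarray) -> float:
    """K(v_a, v_b) = Tr[v_a v_b] for symmetric operator matrices."""
    v_a, v_b = np.asarray(v_a), np.asarray(v_b)
    if v_a.shape != v_b.shape:
        raise ValueError(f"kernel dimension mismatch: {v_a.shape} vs {v_b.shape}")
    return float(np.einsum("pq,qp->", v_a, v_b))


def _as_stack(X, name):
    X = np.asarray(X, dtype=float)
    if X.ndim != 3 or X.shape[1] != X.shape[2]:
        raise ValueError(f"{name} must be a stack of square matrices, got {X.shape}")
    return X


class GammaKRR(BaseEstimator, RegressorMixin):
    """Map 1: trace-kernel ridge regression from v̂ matrices to 1-rdms.

    Parameters
    ----------
    lam : float or "loo", default 1e-10
        Ridge regularization λ.  The near-zero default targets exact
        interpolation of the training densities; ``"loo"`` selects λ on
        a logarithmic grid by minimizing the closed-form leave-one-out
        residual of the training 1-rdms (useful when the kernel matrix
        is severely ill-conditioned, e.g. samples along a 1-D scan).
    dedup_tol : float, default 1e-12
        Relative tolerance used to drop duplicate training potentials
        (which would make the kernel matrix exactly singular).

    Attributes
    ----------
    V_train_ : (N, n, n) retained training potentials
    beta_ : (N, n, n) dual coefficient matrices β̂_i
    lambda_ : float, the regularization actually used
    condition_number_ : float, condition number of K + λI
    """

    def __init__(self, lam=1e-10, dedup_tol: float = 1e-12):
        self.lam = lam
        self.dedup_tol = dedup_tol

    @staticmethod
    def _loo_lambda(K, Y):
        """λ minimizing the closed-form KRR leave-one-out RMS residual."""
        scale = np.trace(K) / len(K)
        best = (np.inf, scale * 1e-12)
        for lam in scale * np.logspace(-12, -2, 21):
            try:
                Ainv = np.linalg.inv(K + lam * np.eye(len(K)))
            except np.linalg.LinAlgError:
                continue
            alpha = Ainv @ Y
            loo = alpha / np.diag(Ainv)[:, None]
            rms = float(np.sqrt(np.mean(loo ** 2)))
            if rms < best[0]:
                best = (rms, lam)
        return best[1]

    def fit(self, X, y):
        V = _as_stack(X, "X (potentials)")
        G = _as_stack(y, "y (1-rdms)")
        if len(V) != len(G):
            raise ValueError("need one target 1-rdm per training potential")
        if len(V) < 1:
            raise ValueError("need at least one training sample")
        if self.lam != "loo" and self.lam < 0:
            raise ValueError("lam must be >= 0 or 'loo'")
        keep = self._dedup(V)
        if len(keep) < len(V):
            log.warning("dropped %d duplicate training potentials",
                        len(V) - len(keep))
        V, G = V[keep], G[keep]
        N = len(V)
        Vf = V.reshape(N, -1)
        K = Vf @ Vf.T          # Tr[v_i v_j] for symmetric matrices
        if self.lam == "loo":
            self.lambda_ = self._loo_lambda(K, G.reshape(N, -1))
            log.info("leave-one-out selected lambda = %.3e", self.lambda_)
        else:
            self.lambda_ = float(self.lam)
        A = K + self.lambda_ * np.eye(N)
        self.condition_number_ = float(np.linalg.cond(A))
        log.info("kernel matrix condition number: %.3e", self.condition_number_)
        try:
            c, low = cho_factor(A)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "kernel matrix is singular; increase lam or remove "
                "duplicate samples"
            ) from err
        B = cho_solve((c, low), G.reshape(N, -1))
        self.V_train_ = V
        self.beta_ = B.reshape(N, *V.shape[1:])
        self.n_ao_ = V.shape[1]
        return self

    def _dedup(self, V):
        keep = []
        flat = V.reshape(len(V), -1)
        norms = np.linalg.norm(flat, axis=1)
        scale = norms.max() if len(norms) else 1.0
        for i in range(len(V)):
            dup = any(
                np.linalg.norm(flat[i] - flat[j]) <= self.dedup_tol * max(scale, 1.0)
                for j in keep
            )
            if not dup:
                keep.append(i)
        return np.array(keep, dtype=int)

    def _kvec(self, v):
        v = np.asarray(v, dtype=float)
        if v.shape != (self.n_ao_, self.n_ao_):
            raise ValueError(
                f"query potential shape {v.shape} does not match "
                f"training n_ao={self.n_ao_}"
            )
        return self.V_train_.reshape(len(self.V_train_), -1) @ v.ravel()

    def predict_one(self, v: np.ndarray) -> np.ndarray:
        """Predict the 1-rdm γ^p for one external-potential matrix."""
        k = self._kvec(v)
        return np.einsum("i,ipq->pq", k, self.beta_)

    def predict(self, X):
        V = _as_stack(X, "X (potentials)")
        return np.stack([self.predict_one(v) for v in V])


class DeltaRefiner(BaseEstimator):
    """Map 2: ridge regression from γ^p features to refinement targets.

    Targets are supplied to :meth:`fit` as a dict of arrays keyed by
    name ("delta_gamma", "energy", "forces", "dipole", ...); each is
    regressed independently (one ridge block per target) on the
    upper-triangle features of the predicted 1-rdms.  Forces should be
    given in the aligned internal frame.

    Parameters
    ----------
    alpha : float, default 1e-8
        Ridge penalty; near-zero reproduces training targets on a
        full-rank design (interpolation).
    """

    def __init__(self, alpha: float = 1e-8):
        self.alpha = alpha

    def fit(self, X, y: dict):
        G = _as_stack(X, "X (predicted 1-rdms)")
        N = len(G)
        if N < 2:
            raise ValueError("map 2 needs at least two training samples")
        feats = featurize(G)
        self.n_ao_ = G.shape[1]
        self.models_ = {}
        self.target_shapes_ = {}
        self.residuals_ = {}
        for name, target in y.items():
            t = np.asarray(target, dtype=float)
            if len(t) != N:
                raise ValueError(f"target {name!r} has {len(t)} rows, expected {N}")
            if not np.all(np.isfinite(t)):
                bad = np.where(~np.isfinite(t.reshape(N, -1)).all(axis=1))[0]
                raise ValueError(
                    f"non-finite values in target {name!r} at sample(s) {bad}"
                )
            self.target_shapes_[name] = t.shape[1:]
            ridge = Ridge(alpha=self.alpha, fit_intercept=True)
            ridge.fit(feats, t.reshape(N, -1))
            self.models_[name] = ridge
            res = ridge.predict(feats) - t.reshape(N, -1)
            self.residuals_[name] = float(np.sqrt(np.mean(res ** 2)))
            log.info("map-2 target %s: training RMS residual %.3e",
                     name, self.residuals_[name])
        return self

    def predict(self, X, target: str):
        G = _as_stack(X, "X (predicted 1-rdms)")
        if G.shape[1] != self.n_ao_:
            raise ValueError(
                f"n_ao mismatch: model fitted with {self.n_ao_}, got {G.shape[1]}"
            )
        raw = self.models_[target].predict(featurize(G))
        return raw.reshape((len(G),) + self.target_shapes_[target])

    def predict_one(self, gamma_p: np.ndarray, target: str):
        return self.predict(gamma_p[None], target)[0]

    @property
    def targets_(self):
        return tuple(self.models_)
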