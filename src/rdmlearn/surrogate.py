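"""The composite surrogate electronic-structure method.

``DensitySurrogate`` packages the whole pipeline: align a query
geometry to the training reference frame, compute its external-
potential matrix, predict the 1-rdm with map 1 (γ-learning), optionally
refine it with map 2 (γ+δ-learning), purify to restore non-interacting
N-representability, and evaluate observables — either directly from the
predicted density through the engine's one-shot functionals, or from
map 2's own energy/force/dipole regressions.

The three prediction routes mirror the method-variant nomenclature used
throughout the benchmarks:

- ``route="gamma"``      : observables computed from γ^p          (QM^ML[γ^p])
- ``route="refined"``    : observables computed from γ^p + Δγ^p   (QM^ML[γ^p+Δγ^p])
- ``route="direct"``     : energy/forces taken from map 2 itself  (QM^ML)
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator

from . import engine as qm
from .frames import align_to_reference
from .geometry import Geometry
from .models import DeltaRefiner, GammaKRR
from .rdm import dipole_moment, kinetic_energy, purify_aufbau

log = logging.getLogger(__name__)

ROUTES = ("gamma", "refined", "direct")


class DensitySurrogate(BaseEstimator):
    """Surrogate electronic-structure method learned from a training set.

    Parameters
    ----------
    spec : MethodSpec
        Theory level and basis of the reference engine.
    lam : float
        Map-1 (KRR) regularization λ.
    alpha : float
        Map-2 ridge penalty α.
    purify : bool
        Aufbau-purify predicted 1-rdms before computing observables
        (skipped automatically for full-CI surrogates, whose
        occupations are fractional).

    Attributes (after fit)
    ----------------------
    reference_ : Geometry — equilibrium/alignment reference
    gamma_model_ : GammaKRR
    delta_model_ : DeltaRefiner
    """

    def __init__(self, spec=None, lam: float = 1e-10, alpha: float = 1e-8,
                 purify: bool = True):
        self.spec = spec
        self.lam = lam
        self.alpha = alpha
        self.purify = purify

    # -- training ----------------------------------------------------------

    def fit(self, training_set):
        """Fit both maps from a :class:`~rdmlearn.store.TrainingSet`."""
        ts = training_set
        if self.spec is None:
            self.spec = ts.spec
        self.reference_ = ts.reference
        self.references_all_ = list(ts.references)
        V = np.asarray(ts.potentials)
        G = np.asarray(ts.gammas)
        self.gamma_model_ = GammaKRR(lam=self.lam).fit(V, G)
        gamma_p = self.gamma_model_.predict(V)
        targets = {
            "delta_gamma": G - gamma_p,
            "energy": np.asarray(ts.energies)[:, None],
        }
        if ts.forces is not None:
            targets["forces"] = np.asarray(ts.forces)   # aligned frame
        if ts.dipoles is not None:
            targets["dipole"] = np.asarray(ts.dipoles)  # aligned frame
        self.delta_model_ = DeltaRefiner(alpha=self.alpha).fit(gamma_p, targets)
        self.n_electrons_ = ts.reference.n_electrons
        return self

    # -- prediction --------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "gamma_model_"):
            raise RuntimeError("surrogate is not fitted")

    def _aligned(self, geom: Geometry):
        refs = getattr(self, "references_all_", [self.reference_])
        for ref in refs:
            if ref.symbols == geom.symbols:
                return align_to_reference(geom, ref)
        # species not in the training references (transferability queries
        # constructed directly in the internal frame)
        log.info("no alignment reference matches %s; using identity frame",
                 "".join(geom.symbols))
        from .frames import FrameTransform

        tf = FrameTransform(rotation=np.eye(3), centroid=np.zeros(3),
                            ref_centroid=np.zeros(3))
        return geom, tf

    def references_saved(self):
        return list(getattr(self, "references_all_", [self.reference_]))

    def predict_gamma(self, geom: Geometry, refined: bool = True,
                      purify: bool | None = None):
        """Predicted 1-rdm for a geometry (in the aligned frame).

        Returns (gamma, aligned_geometry, frame_transform).
        """
        self._check_fitted()
        aligned, tf = self._aligned(geom)
        ao = qm.compute_ao_matrices(aligned, self.spec)
        gp = self.gamma_model_.predict_one(ao.v)
        if refined:
            gp = gp + self.delta_model_.predict_one(gp, "delta_gamma")
            gp = 0.5 * (gp + gp.T)
        if purify is None:
            purify = self.purify and self.spec.theory != "FullCI"
        if purify:
            gp = purify_aufbau(gp, ao.S, self.n_electrons_)
        return gp, aligned, tf

    def energy(self, geom: Geometry, route: str = "refined") -> float:
        """Total energy (Hartree) by the requested prediction route."""
        self._check_fitted()
        if route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}")
        if route == "direct":
            aligned, tf = self._aligned(geom)
            ao = qm.compute_ao_matrices(aligned, self.spec)
            gp = self.gamma_model_.predict_one(ao.v)
            return float(self.delta_model_.predict_one(gp, "energy")[0])
        gp, aligned, _ = self.predict_gamma(geom, refined=(route == "refined"))
        return qm.energy_from_rdm(gp, aligned, self.spec)

    def forces(self, geom: Geometry, route: str = "refined") -> np.ndarray:
        """Forces (Hartree/Bohr, lab frame) by the requested route."""
        self._check_fitted()
        if route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}")
        if route == "direct":
            aligned, tf = self._aligned(geom)
            ao = qm.compute_ao_matrices(aligned, self.spec)
            gp = self.gamma_model_.predict_one(ao.v)
            f_int = self.delta_model_.predict_one(gp, "forces")
            return tf.rotate_back(f_int)
        gp, aligned, tf = self.predict_gamma(geom, refined=(route == "refined"))
        f_int = qm.forces_from_rdm(gp, aligned, self.spec)
        return tf.rotate_back(f_int)

    def energy_and_forces(self, geom: Geometry, route: str = "refined"):
        """One-pass energy + forces (shares the γ prediction)."""
        self._check_fitted()
        aligned, tf = self._aligned(geom)
        ao = qm.compute_ao_matrices(aligned, self.spec)
        gp = self.gamma_model_.predict_one(ao.v)
        if route == "direct":
            e = float(self.delta_model_.predict_one(gp, "energy")[0])
            f = tf.rotate_back(self.delta_model_.predict_one(gp, "forces"))
            return e, f
        if route == "refined":
            gp = gp + self.delta_model_.predict_one(gp, "delta_gamma")
            gp = 0.5 * (gp + gp.T)
        if self.purify and self.spec.theory != "FullCI":
            gp = purify_aufbau(gp, ao.S, self.n_electrons_)
        e = qm.energy_from_rdm(gp, aligned, self.spec)
        f = tf.rotate_back(qm.forces_from_rdm(gp, aligned, self.spec))
        return e, f

    def dipole(self, geom: Geometry, route: str = "refined") -> np.ndarray:
        """Dipole vector (Debye, lab frame)."""
        self._check_fitted()
        if route == "direct":
            aligned, tf = self._aligned(geom)
            ao = qm.compute_ao_matrices(aligned, self.spec)
            gp = self.gamma_model_.predict_one(ao.v)
            return tf.rotate_back(self.delta_model_.predict_one(gp, "dipole"))
        gp, aligned, tf = self.predict_gamma(geom, refined=(route == "refined"))
        ao = qm.compute_ao_matrices(aligned, self.spec)
        return tf.rotate_back(dipole_moment(gp, ao.D, aligned))

    def kinetic_energy(self, geom: Geometry, route: str = "refined") -> float:
        gp, aligned, _ = self.predict_gamma(geom, refined=(route == "refined"))
        ao = qm.compute_ao_matrices(aligned, self.spec)
        return kinetic_energy(gp, ao.t)

    def homo_lumo_gap(self, geom: Geometry, refined: bool = True) -> float:
        """Gap (Hartree) from one Fock diagonalization at the predicted γ."""
        gp, aligned, _ = self.predict_gamma(geom, refined=refined)
        return qm.homo_lumo_gap(gp, aligned, self.spec)

    def orbitals(self, geom: Geometry, refined: bool = True):
        gp, aligned, _ = self.predict_gamma(geom, refined=refined)
        eps, C, gap = qm.fock_and_orbitals(gp, aligned, self.spec)
        return eps, C, gap

    # -- force-provider protocol for the dynamics driver -------------------

    def force_provider(self, route: str = "direct"):
        """A callable geom -> (energy, forces) for MD/optimization."""
        def provider(geom: Geometry):
            return self.energy_and_forces(geom, route=route)
        provider.label = f"surrogate[{route}]"
        return provider


def engine_force_provider(spec):
    """Conventional-engine provider (full SCF each call) for twin runs."""
    def provider(geom: Geometry):
        ref = qm.run_reference(geom, spec)
        return ref.energy, ref.forces
    provider.label = f"engine[{spec.theory}]"
    return provider
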