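"""Internal reference frames: Kabsch alignment and the Eckart frame.

Operator matrices of two geometries are only comparable when rigid
rotation and translation have been removed; every training or query
geometry is therefore aligned to the equilibrium reference before its
external-potential matrix is computed.  The mass-weighted least-squares
(Kabsch) superposition used here is exactly the Eckart construction:
its stationarity conditions are the translational (Σ m_i Δr_i = 0) and
rotational (Σ m_i r_i^ref × Δr_i = 0) Eckart conditions, which is what
the dipole time series needs before Fourier transformation.

No permutational (identical-atom relabeling) matching is attempted;
atom ordering must agree with the reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry


@dataclass(frozen=True)
class FrameTransform:
    """aligned = (coords - centroid) @ rotation.T + ref_centroid"""

    rotation: np.ndarray     # (3, 3) proper rotation
    centroid: np.ndarray     # of the raw geometry (weighted), Å
    ref_centroid: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-10):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("improper rotation (determinant -1)")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (coords - self.centroid) @ self.rotation.T + self.ref_centroid

    def rotate_vectors(self, vecs: np.ndarray) -> np.ndarray:
        """Rotate direction vectors (forces, dipoles) into the frame."""
        return vecs @ self.rotation.T

    def rotate_back(self, vecs: np.ndarray) -> np.ndarray:
        return vecs @ self.rotation


def _kabsch_rotation(P, Q, weights):
    """Proper rotation R minimizing Σ w |R p - q|² (rows are points)."""
    H = (P * weights[:, None]).T @ Q
    U, s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def align_to_reference(geom: Geometry, ref: Geometry,
                       mass_weighted: bool = True):
    """Superimpose ``geom`` onto ``ref``; returns (aligned, transform).

    Minimizes the (mass-weighted) RMSD over proper rotations and
    translations.  Deterministic; raises if the atom composition or
    ordering differs from the reference.
    """
    if geom.symbols != ref.symbols:
        raise ValueError(
            "atom count/ordering mismatch with the reference geometry "
            "(no automatic permutation matching)"
        )
    w = geom.masses_amu() if mass_weighted else np.ones(geom.n_atoms)
    w = w / w.sum()
    c_geom = w @ geom.coords
    c_ref = w @ ref.coords
    P = geom.coords - c_geom
    Q = ref.coords - c_ref
    R = _kabsch_rotation(P, Q, w)
    tf = FrameTransform(rotation=R, centroid=c_geom, ref_centroid=c_ref)
    return geom.with_coords(tf.apply(geom.coords)), tf


def rmsd(geom: Geometry, ref: Geometry, mass_weighted: bool = True) -> float:
    w = geom.masses_amu() if mass_weighted else np.ones(geom.n_atoms)
    w = w / w.sum()
    d = geom.coords - ref.coords
    return float(np.sqrt(np.sum(w[:, None] * d * d)))


def eckart_transform(traj_coords, ref: Geometry):
    """Map every frame of a trajectory into the Eckart frame of ``ref``.

    Returns (coords_list, transforms).  Each frame satisfies the
    translational and rotational Eckart conditions with respect to the
    reference (mass-weighted Kabsch superposition per frame); for rigid
    motion the transformed coordinates are constant in time.
    """
    out_coords, transforms = [], []
    for coords in traj_coords:
        g = ref.with_coords(np.asarray(coords))
        aligned, tf = align_to_reference(g, ref, mass_weighted=True)
        out_coords.append(aligned.coords)
        transforms.append(tf)
    return out_coords, transforms


def eckart_residuals(coords: np.ndarray, ref: Geometry) -> tuple:
    """(|Σ m Δr|, |Σ m r_ref × Δr|) — both vanish in the Eckart frame."""
    m = ref.masses_amu()
    d = coords - ref.coords
    t_cond = m @ d
    r_cond = np.sum(m[:, None] * np.cross(ref.coords - ref.center_of_mass(), d),
                    axis=0)
    return np.linalg.norm(t_cond), np.linalg.norm(r_cond)
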