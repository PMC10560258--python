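"""1-rdm utilities: occupations, Aufbau purification, observables.

The predicted 1-rdm of a closed-shell system must be non-interacting
N-representable (idempotent up to the factor 2, correct electron count)
before it can drive stable dynamics.  Purification diagonalizes the
Löwdin-orthonormalized γ, sets the top N/2 occupations to 2 and the
rest to 0, and rebuilds the AO-basis matrix.  For full-CI densities the
occupations are fractional and purification is deliberately skipped.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.linalg import eigh, fractional_matrix_power

from .units import AU_TO_DEBYE

log = logging.getLogger(__name__)

SYMMETRY_TOL = 1e-8


def _check_symmetric(gamma, tol=SYMMETRY_TOL):
    asym = np.abs(gamma - gamma.T).max()
    if asym > tol:
        raise ValueError(f"1-rdm not symmetric (max |γ-γᵀ| = {asym:.2e})")


def _lowdin(S):
    return fractional_matrix_power(S, 0.5), fractional_matrix_power(S, -0.5)


def occupations(gamma: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Natural occupation numbers (eigenvalues of S½ γ S½), descending."""
    _check_symmetric(gamma)
    s_half, _ = _lowdin(S)
    w = np.linalg.eigvalsh(s_half @ gamma @ s_half)
    return w[::-1]


def purify_aufbau(gamma: np.ndarray, S: np.ndarray, n_electrons: int) -> np.ndarray:
    """Project γ onto integer (0/2) occupations with the exact electron count.

    Natural orbitals are retained; the top n_electrons/2 of them get
    occupation 2.  The result satisfies (γ'S)(γ'S) = 2 γ'S and
    Tr[γ'S] = n_electrons exactly (up to roundoff).
    """
    if n_electrons % 2:
        raise ValueError("Aufbau purification requires an even electron count")
    _check_symmetric(gamma)
    s_half, s_minus = _lowdin(S)
    w, U = np.linalg.eigh(s_half @ gamma @ s_half)
    # eigh returns ascending; occupy the top npair
    npair = n_electrons // 2
    if npair > 0 and len(w) > npair:
        fermi_gap = w[-npair] - w[-npair - 1]
        if fermi_gap < 1e-6:
            log.warning(
                "near-degenerate occupations at the Fermi split "
                "(gap %.2e); deterministic tie-break by eigenvalue order",
                fermi_gap,
            )
    occ = np.zeros(len(w))
    occ[len(w) - npair:] = 2.0
    gamma_orth = (U * occ) @ U.T
    out = s_minus @ gamma_orth @ s_minus
    return 0.5 * (out + out.T)


def kinetic_energy(gamma: np.ndarray, t: np.ndarray) -> float:
    """Non-interacting kinetic energy T_s = Tr[γ t], Hartree."""
    if gamma.shape != t.shape:
        raise ValueError("dimension mismatch between γ and kinetic matrix")
    return float(np.einsum("pq,pq->", gamma, t))


def dipole_moment(gamma: np.ndarray, D: np.ndarray, geom, origin_bohr=None) -> np.ndarray:
    """Total dipole vector in Debye from γ and position-operator matrices.

    ``D`` must be the (3, n, n) position matrices taken about
    ``origin_bohr`` (default: center of nuclear charge, which makes the
    neutral-molecule dipole origin-independent).
    """
    z = geom.numbers.astype(float)
    if origin_bohr is None:
        origin_bohr = z @ geom.coords_bohr() / z.sum()
    el = -np.einsum("kpq,pq->k", D, gamma)
    nuc = z @ (geom.coords_bohr() - origin_bohr)
    return (el + nuc) * AU_TO_DEBYE
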