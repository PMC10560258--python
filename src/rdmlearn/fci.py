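"""Determinant full configuration interaction for few-orbital systems.

Builds the complete CI Hamiltonian over all closed-shell-count
determinants of the HF molecular-orbital basis via the Slater–Condon
rules, diagonalizes it, and returns the ground-state energy together
with the spin-summed 1-rdm back-transformed to the AO basis.  Intended
for systems where the determinant space is tiny (H2, HeH+, minimal-
basis triatomics); the cost grows combinatorially by construction.

Full-CI forces are central finite differences of the full-CI energy
(there is no Hellmann–Feynman shortcut without CI-response terms at
this code's scale).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .geometry import Geometry

MAX_DETERMINANTS = 20000


def _mo_integrals(geom, spec):
    from . import integrals as ints
    from .basis import build_shells
    from .engine import _scf

    e_hf, P, C, eps, ao, V2, shells = _scf(geom, spec)
    hmo = C.T @ (ao.t + ao.v) @ C
    vmo = np.einsum("pqrs,pi,qj,rk,sl->ijkl", V2, C, C, C, C, optimize=True)
    return hmo, vmo, C, ao


def _strings(norb, nelec):
    return list(combinations(range(norb), nelec))


def _excitation(occ1, occ2):
    """(annihilated, created, sign) between two sorted occupation tuples."""
    s1, s2 = set(occ1), set(occ2)
    ann = sorted(s1 - s2)
    cre = sorted(s2 - s1)
    # apply p->q one at a time, counting crossings for the fermionic sign
    work = list(occ1)
    sign = 1
    for p, q in zip(ann, cre):
        ip = work.index(p)
        work.pop(ip)
        iq = 0
        while iq < len(work) and work[iq] < q:
            iq += 1
        sign *= (-1) ** (ip + iq)
        work.insert(iq, q)
    return ann, cre, sign


def _build_hamiltonian(hmo, vmo, astrings, bstrings):
    na, nb = len(astrings), len(bstrings)
    dim = na * nb
    H = np.zeros((dim, dim))

    # pre-tabulate pair data within each spin channel
    def pair_table(strings):
        n = len(strings)
        table = {}
        for i in range(n):
            for j in range(n):
                ann, cre, sign = _excitation(strings[i], strings[j])
                if len(ann) <= 2:
                    table[(i, j)] = (ann, cre, sign)
        return table

    atab = pair_table(astrings)
    btab = pair_table(bstrings)

    def h1_single(p, q, occ_same, occ_other):
        val = hmo[p, q]
        for r in occ_same:
            if r != p:
                val += vmo[p, q, r, r] - vmo[p, r, r, q]
        for r in occ_other:
            val += vmo[p, q, r, r]
        return val

    for ia, aocc in enumerate(astrings):
        for ib, bocc in enumerate(bstrings):
            I = ia * nb + ib
            # diagonal
            e = sum(hmo[p, p] for p in aocc) + sum(hmo[p, p] for p in bocc)
            for p in aocc:
                for q in aocc:
                    e += 0.5 * (vmo[p, p, q, q] - vmo[p, q, q, p])
            for p in bocc:
                for q in bocc:
                    e += 0.5 * (vmo[p, p, q, q] - vmo[p, q, q, p])
            for p in aocc:
                for q in bocc:
                    e += vmo[p, p, q, q]
            H[I, I] = e

    for (ia, ja), (ann_a, cre_a, sign_a) in atab.items():
        da = len(ann_a)
        for (ib, jb), (ann_b, cre_b, sign_b) in btab.items():
            db = len(ann_b)
            deg = da + db
            if deg == 0 or deg > 2:
                continue
            I, J = ia * nb + ib, ja * nb + jb
            if deg == 1:
                if da == 1:
                    p, q = ann_a[0], cre_a[0]
                    val = sign_a * h1_single(p, q, astrings[ia], bstrings[ib])
                else:
                    p, q = ann_b[0], cre_b[0]
                    val = sign_b * h1_single(p, q, bstrings[ib], astrings[ia])
            elif da == 2:
                (p1, p2), (q1, q2) = ann_a, cre_a
                val = sign_a * (vmo[p1, q1, p2, q2] - vmo[p1, q2, p2, q1])
            elif db == 2:
                (p1, p2), (q1, q2) = ann_b, cre_b
                val = sign_b * (vmo[p1, q1, p2, q2] - vmo[p1, q2, p2, q1])
            else:  # one alpha + one beta
                val = (sign_a * sign_b
                       * vmo[ann_a[0], cre_a[0], ann_b[0], cre_b[0]])
            H[I, J] = val
    return H


def _one_rdm_mo(c, astrings, bstrings, norb):
    """Spin-summed MO-basis 1-rdm of the CI vector c."""
    na, nb = len(astrings), len(bstrings)
    gamma = np.zeros((norb, norb))
    C = c.reshape(na, nb)
    # diagonal occupations
    for ia, aocc in enumerate(astrings):
        for ib, bocc in enumerate(bstrings):
            w = C[ia, ib] ** 2
            for p in aocc:
                gamma[p, p] += w
            for p in bocc:
                gamma[p, p] += w
    # alpha single excitations
    for ia in range(na):
        for ja in range(na):
            if ia == ja:
                continue
            ann, cre, sign = _excitation(astrings[ia], astrings[ja])
            if len(ann) != 1:
                continue
            val = sign * (C[ia] @ C[ja])
            gamma[ann[0], cre[0]] += val
    # beta single excitations
    for ib in range(nb):
        for jb in range(nb):
            if ib == jb:
                continue
            ann, cre, sign = _excitation(bstrings[ib], bstrings[jb])
            if len(ann) != 1:
                continue
            val = sign * (C[:, ib] @ C[:, jb])
            gamma[ann[0], cre[0]] += val
    return gamma


def fci_energy_and_gamma(geom: Geometry, spec) -> tuple:
    """Ground-state full-CI total energy and AO-basis 1-rdm."""
    from .engine import EngineError

    hmo, vmo, Cmo, ao = _mo_integrals(geom, spec)
    norb = hmo.shape[0]
    npair = geom.n_electrons // 2
    astrings = _strings(norb, npair)
    dim = len(astrings) ** 2
    if dim > MAX_DETERMINANTS:
        raise EngineError(
            f"full-CI determinant space ({dim}) exceeds the built-in limit "
            f"({MAX_DETERMINANTS}); full CI is for small systems only"
        )
    H = _build_hamiltonian(hmo, vmo, astrings, astrings)
    w, V = np.linalg.eigh(H)
    c0 = V[:, 0]
    gamma_mo = _one_rdm_mo(c0, astrings, astrings, norb)
    gamma_ao = Cmo @ gamma_mo @ Cmo.T
    e_tot = float(w[0]) + geom.nuclear_repulsion()
    return e_tot, gamma_ao, ao


def run_fci(geom: Geometry, spec, fd_step_bohr: float = 5e-3):
    """ReferenceResult at the full-CI level (finite-difference forces)."""
    from .engine import ReferenceResult, _dipole_from_gamma
    from .units import BOHR_TO_ANG

    e0, gamma, ao = fci_energy_and_gamma(geom, spec)
    coords = geom.coords
    forces = np.zeros_like(coords)
    step_ang = fd_step_bohr * BOHR_TO_ANG
    for a in range(geom.n_atoms):
        for x in range(3):
            cp = coords.copy()
            cp[a, x] += step_ang
            ep, _, _ = fci_energy_and_gamma(geom.with_coords(cp), spec)
            cm = coords.copy()
            cm[a, x] -= step_ang
            em, _, _ = fci_energy_and_gamma(geom.with_coords(cm), spec)
            forces[a, x] = -(ep - em) / (2.0 * fd_step_bohr)
    return ReferenceResult(
        gamma=gamma, energy=e0, forces=forces,
        dipole=_dipole_from_gamma(gamma, ao, geom),
    )
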