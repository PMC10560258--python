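"""McMurchie–Davidson evaluation of GTO matrix elements.

Overlap, kinetic, nuclear-attraction (the "external potential" feature),
dipole and two-electron repulsion integrals over contracted Cartesian
Gaussians, plus the analytic nuclear-coordinate derivatives of all of
them.  Cartesian Gaussian products are expanded in Hermite Gaussians
via the E-coefficient recursion; Coulomb-type integrals contract the
Hermite expansions with the Boys-function R-tensor.

Derivatives use the exact operator identity
``d/dA_x G_i(A) = 2a G_{i+1}(A) - i G_{i-1}(A)``
so every gradient integral is assembled from angular-momentum-shifted
Hermite expansions; the operator-center derivative of the nuclear
attraction follows from translational invariance.

All quantities in Hartree atomic units.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import hyp1f1

from .basis import cartesian_components

__all__ = [
    "overlap", "kinetic", "nuclear_attraction", "dipole_matrices", "eri",
    "grad_overlap", "grad_kinetic", "grad_nuclear_attraction", "grad_eri",
    "shell_pair_overlap",
]


# ---------------------------------------------------------------------------
# Hermite expansion coefficients

def _e_table(la: int, lb: int, a: float, b: float, AB: float) -> np.ndarray:
    """E[i, j, t] for one Cartesian direction, t up to i+j (+1 margin)."""
    p = a + b
    E = np.zeros((la + 1, lb + 1, la + lb + 2))
    E[0, 0, 0] = np.exp(-a * b / p * AB * AB)
    X_PA = -b * AB / p
    X_PB = a * AB / p
    inv2p = 0.5 / p
    for i in range(la):
        for t in range(i + 2):
            E[i + 1, 0, t] = (
                (inv2p * E[i, 0, t - 1] if t > 0 else 0.0)
                + X_PA * E[i, 0, t]
                + (t + 1) * E[i, 0, t + 1]
            )
    for j in range(lb):
        for i in range(la + 1):
            for t in range(i + j + 2):
                E[i, j + 1, t] = (
                    (inv2p * E[i, j, t - 1] if t > 0 else 0.0)
                    + X_PB * E[i, j, t]
                    + (t + 1) * E[i, j, t + 1]
                )
    return E


# ---------------------------------------------------------------------------
# Boys function and Hermite Coulomb tensor

def boys(nmax: int, T) -> np.ndarray:
    """F_n(T) for n = 0..nmax (confluent-hypergeometric form, stable).

    Scalar T gives shape (nmax+1,); array T appends the batch axes.
    """
    n = np.arange(nmax + 1)
    T = np.asarray(T, dtype=float)
    if T.ndim == 0:
        return hyp1f1(n + 0.5, n + 1.5, -T) / (2.0 * n + 1.0)
    nn = n.reshape((nmax + 1,) + (1,) * T.ndim)
    return hyp1f1(nn + 0.5, nn + 1.5, -T[None]) / (2.0 * nn + 1.0)


def _r_table(L: int, p: float, PC: np.ndarray) -> np.ndarray:
    """Hermite Coulomb integrals R_{tuv} for t+u+v <= L (order-0 slice)."""
    T = p * float(PC @ PC)
    F = boys(L, T)
    R = np.zeros((L + 1, L + 1, L + 1, L + 1))  # [n, t, u, v]
    R[:, 0, 0, 0] = (-2.0 * p) ** np.arange(L + 1) * F
    x, y, z = PC
    for t in range(1, L + 1):
        for n in range(L + 1 - t):
            R[n, t, 0, 0] = x * R[n + 1, t - 1, 0, 0] + (
                (t - 1) * R[n + 1, t - 2, 0, 0] if t > 1 else 0.0
            )
    for u in range(1, L + 1):
        for t in range(L + 1 - u):
            for n in range(L + 1 - t - u):
                R[n, t, u, 0] = y * R[n + 1, t, u - 1, 0] + (
                    (u - 1) * R[n + 1, t, u - 2, 0] if u > 1 else 0.0
                )
    for v in range(1, L + 1):
        for u in range(L + 1 - v):
            for t in range(L + 1 - u - v):
                for n in range(L + 1 - t - u - v):
                    R[n, t, u, v] = z * R[n + 1, t, u, v - 1] + (
                        (v - 1) * R[n + 1, t, u, v - 2] if v > 1 else 0.0
                    )
    return R[0]


def _r_table_batch(L: int, p: np.ndarray, PC: np.ndarray) -> np.ndarray:
    """Batched Hermite Coulomb tensor: p (B,), PC (B, 3) -> (B, L+1,L+1,L+1)."""
    B = len(p)
    T = p * np.einsum("bd,bd->b", PC, PC)
    F = boys(L, T)                      # (L+1, B)
    R = np.zeros((L + 1, B, L + 1, L + 1, L + 1))  # [n, b, t, u, v]
    pow_fac = (-2.0 * p[None, :]) ** np.arange(L + 1)[:, None]
    R[:, :, 0, 0, 0] = pow_fac * F
    x, y, z = PC[:, 0], PC[:, 1], PC[:, 2]
    for t in range(1, L + 1):
        for n in range(L + 1 - t):
            R[n, :, t, 0, 0] = x * R[n + 1, :, t - 1, 0, 0] + (
                (t - 1) * R[n + 1, :, t - 2, 0, 0] if t > 1 else 0.0
            )
    for u in range(1, L + 1):
        for t in range(L + 1 - u):
            for n in range(L + 1 - t - u):
                R[n, :, t, u, 0] = y * R[n + 1, :, t, u - 1, 0] + (
                    (u - 1) * R[n + 1, :, t, u - 2, 0] if u > 1 else 0.0
                )
    for v in range(1, L + 1):
        for u in range(L + 1 - v):
            for t in range(L + 1 - u - v):
                for n in range(L + 1 - t - u - v):
                    R[n, :, t, u, v] = z * R[n + 1, :, t, u, v - 1] + (
                        (v - 1) * R[n + 1, :, t, u, v - 2] if v > 1 else 0.0
                    )
    return R[0]


# ---------------------------------------------------------------------------
# one-electron integrals

def _pair_etabs(sha, shb, ca, aa, cb, ab, ma=0, mb=0):
    """Per-dimension E tables for one primitive pair with index margins."""
    AB = sha.center - shb.center
    return [_e_table(sha.l + ma, shb.l + mb, aa, ab, AB[d]) for d in range(3)]


def _s1d(E, i, j):
    if i < 0 or j < 0:
        return 0.0
    return E[i, j, 0]


def shell_pair_overlap(sha, shb) -> np.ndarray:
    comps_a = cartesian_components(sha.l)
    comps_b = cartesian_components(shb.l)
    block = np.zeros((len(comps_a), len(comps_b)))
    for ca, aa in zip(sha.coefs, sha.exps):
        for cb, ab in zip(shb.coefs, shb.exps):
            E = _pair_etabs(sha, shb, ca, aa, cb, ab)
            fac = ca * cb * (np.pi / (aa + ab)) ** 1.5
            for ia, la in enumerate(comps_a):
                for ib, lb in enumerate(comps_b):
                    block[ia, ib] += fac * (
                        E[0][la[0], lb[0], 0]
                        * E[1][la[1], lb[1], 0]
                        * E[2][la[2], lb[2], 0]
                    )
    return block


def _shell_pair_kinetic(sha, shb) -> np.ndarray:
    comps_a = cartesian_components(sha.l)
    comps_b = cartesian_components(shb.l)
    block = np.zeros((len(comps_a), len(comps_b)))
    for ca, aa in zip(sha.coefs, sha.exps):
        for cb, ab in zip(shb.coefs, shb.exps):
            E = _pair_etabs(sha, shb, ca, aa, cb, ab, mb=2)
            fac = ca * cb * (np.pi / (aa + ab)) ** 1.5
            for ia, la in enumerate(comps_a):
                for ib, lb in enumerate(comps_b):
                    s = [_s1d(E[d], la[d], lb[d]) for d in range(3)]
                    k = [
                        -2.0 * ab * ab * _s1d(E[d], la[d], lb[d] + 2)
                        + ab * (2 * lb[d] + 1) * s[d]
                        - 0.5 * lb[d] * (lb[d] - 1) * _s1d(E[d], la[d], lb[d] - 2)
                        for d in range(3)
                    ]
                    block[ia, ib] += fac * (
                        k[0] * s[1] * s[2] + s[0] * k[1] * s[2] + s[0] * s[1] * k[2]
                    )
    return block


def _shell_offsets(shells):
    offs, o = [], 0
    for sh in shells:
        offs.append(o)
        o += sh.n_components
    return offs, o


def _assemble_symmetric(shells, pair_block):
    offs, n = _shell_offsets(shells)
    M = np.zeros((n, n))
    for i, sha in enumerate(shells):
        for j in range(i, len(shells)):
            blk = pair_block(sha, shells[j])
            oa, ob = offs[i], offs[j]
            M[oa:oa + blk.shape[0], ob:ob + blk.shape[1]] = blk
            M[ob:ob + blk.shape[1], oa:oa + blk.shape[0]] = blk.T
    return M


def overlap(shells) -> np.ndarray:
    return _assemble_symmetric(shells, shell_pair_overlap)


def kinetic(shells) -> np.ndarray:
    return _assemble_symmetric(shells, _shell_pair_kinetic)


def nuclear_attraction(shells, coords_bohr, charges) -> np.ndarray:
    """Electron–nuclear attraction matrix (negative-definite tendency)."""

    def block(sha, shb):
        comps_a = cartesian_components(sha.l)
        comps_b = cartesian_components(shb.l)
        blk = np.zeros((len(comps_a), len(comps_b)))
        for ca, aa in zip(sha.coefs, sha.exps):
            for cb, ab in zip(shb.coefs, shb.exps):
                p = aa + ab
                P = (aa * sha.center + ab * shb.center) / p
                E = _pair_etabs(sha, shb, ca, aa, cb, ab)
                fac = ca * cb * 2.0 * np.pi / p
                L = sha.l + shb.l
                for C, Z in zip(coords_bohr, charges):
                    R3 = _r_table(L, p, P - C)
                    for ia, la in enumerate(comps_a):
                        for ib, lb in enumerate(comps_b):
                            v = np.einsum(
                                "t,u,v,tuv->",
                                E[0][la[0], lb[0], : la[0] + lb[0] + 1],
                                E[1][la[1], lb[1], : la[1] + lb[1] + 1],
                                E[2][la[2], lb[2], : la[2] + lb[2] + 1],
                                R3[: la[0] + lb[0] + 1,
                                   : la[1] + lb[1] + 1,
                                   : la[2] + lb[2] + 1],
                            )
                            blk[ia, ib] += -Z * fac * v
        return blk

    return _assemble_symmetric(shells, block)


def dipole_matrices(shells, origin_bohr) -> np.ndarray:
    """Position-operator matrices ⟨μ|(r_k - O_k)|ν⟩, shape (3, n, n)."""
    offs, n = _shell_offsets(shells)
    D = np.zeros((3, n, n))
    for i, sha in enumerate(shells):
        for j in range(i, len(shells)):
            shb = shells[j]
            comps_a = cartesian_components(sha.l)
            comps_b = cartesian_components(shb.l)
            blk = np.zeros((3, len(comps_a), len(comps_b)))
            for ca, aa in zip(sha.coefs, sha.exps):
                for cb, ab in zip(shb.coefs, shb.exps):
                    E = _pair_etabs(sha, shb, ca, aa, cb, ab, mb=1)
                    fac = ca * cb * (np.pi / (aa + ab)) ** 1.5
                    for ia, la in enumerate(comps_a):
                        for ib, lb in enumerate(comps_b):
                            s = [_s1d(E[d], la[d], lb[d]) for d in range(3)]
                            for k in range(3):
                                # (r_k - O_k)|b> = |b, l_k+1> + (B_k - O_k)|b>
                                mk = _s1d(E[k], la[k], lb[k] + 1) + (
                                    shb.center[k] - origin_bohr[k]
                                ) * s[k]
                                val = mk
                                for d in range(3):
                                    if d != k:
                                        val *= s[d]
                                blk[k, ia, ib] += fac * val
            oa, ob = offs[i], offs[j]
            na, nb = blk.shape[1], blk.shape[2]
            D[:, oa:oa + na, ob:ob + nb] = blk
            D[:, ob:ob + nb, oa:oa + na] = blk.transpose(0, 2, 1)
    return D


# ---------------------------------------------------------------------------
# two-electron integrals

def _hermite_sign(L: int) -> np.ndarray:
    t = np.arange(L + 1)
    s = (-1.0) ** t
    return s[:, None, None] * s[None, :, None] * s[None, None, :]


_EINSUM_PATHS: dict = {}


def _einsum_cached(subscripts, *ops):
    """einsum with a memoized contraction path (hot loop helper)."""
    key = (subscripts, tuple(op.shape for op in ops))
    path = _EINSUM_PATHS.get(key)
    if path is None:
        path = np.einsum_path(subscripts, *ops, optimize="greedy")[0]
        _EINSUM_PATHS[key] = path
    return np.einsum(subscripts, *ops, optimize=path)


def _bra_data(sha, shb, deriv: bool) -> dict:
    """Hermite expansion tensors for one shell pair, batched over primitives.

    Returns arrays: p (Np,), P (Np, 3), c (Np,), E (Np, na, nb, nt, nt, nt)
    and, when ``deriv``, dA/dB of shape (3, Np, na, nb, nt, nt, nt) holding
    the bra-/ket-center derivative expansions (Hermite order one higher).
    """
    comps_a = cartesian_components(sha.l)
    comps_b = cartesian_components(shb.l)
    La, Lb = sha.l, shb.l
    nt = La + Lb + 1 + (1 if deriv else 0)
    m = 1 if deriv else 0
    ps, Ps, cs, Es, dAs, dBs = [], [], [], [], [], []
    for ca, aa in zip(sha.coefs, sha.exps):
        for cb, ab in zip(shb.coefs, shb.exps):
            p = aa + ab
            E = _pair_etabs(sha, shb, ca, aa, cb, ab, ma=m, mb=m)
            Eab = np.zeros((len(comps_a), len(comps_b), nt, nt, nt))
            dEa = np.zeros((3,) + Eab.shape) if deriv else None
            dEb = np.zeros((3,) + Eab.shape) if deriv else None
            for ia, la in enumerate(comps_a):
                for ib, lb in enumerate(comps_b):
                    e1d = [E[d][la[d], lb[d], :nt] for d in range(3)]
                    Eab[ia, ib] = (e1d[0][:, None, None]
                                   * e1d[1][None, :, None]
                                   * e1d[2][None, None, :])
                    if deriv:
                        for x in range(3):
                            da = 2.0 * aa * E[x][la[x] + 1, lb[x], :nt]
                            if la[x] > 0:
                                da = da - la[x] * E[x][la[x] - 1, lb[x], :nt]
                            db = 2.0 * ab * E[x][la[x], lb[x] + 1, :nt]
                            if lb[x] > 0:
                                db = db - lb[x] * E[x][la[x], lb[x] - 1, :nt]
                            parts_a = list(e1d)
                            parts_a[x] = da
                            parts_b = list(e1d)
                            parts_b[x] = db
                            dEa[x][ia, ib] = (parts_a[0][:, None, None]
                                              * parts_a[1][None, :, None]
                                              * parts_a[2][None, None, :])
                            dEb[x][ia, ib] = (parts_b[0][:, None, None]
                                              * parts_b[1][None, :, None]
                                              * parts_b[2][None, None, :])
            ps.append(p)
            Ps.append((aa * sha.center + ab * shb.center) / p)
            cs.append(ca * cb)
            Es.append(Eab)
            if deriv:
                dAs.append(dEa)
                dBs.append(dEb)
    out = {
        "p": np.array(ps), "P": np.array(Ps), "c": np.array(cs),
        "E": np.array(Es),
    }
    if deriv:
        out["dA"] = np.array(dAs).transpose(1, 0, 2, 3, 4, 5, 6)
        out["dB"] = np.array(dBs).transpose(1, 0, 2, 3, 4, 5, 6)
    return out


def _quartet_blocks(bra, ket, L_bra, L_ket, deriv: bool):
    """Contract bra/ket Hermite batches into an ERI block (or derivatives)."""
    m = 1 if deriv else 0
    Np, Nq = len(bra["p"]), len(ket["p"])
    pq_sum = bra["p"][:, None] + ket["p"][None, :]
    alpha = bra["p"][:, None] * ket["p"][None, :] / pq_sum
    pref = (
        bra["c"][:, None] * ket["c"][None, :]
        * 2.0 * np.pi ** 2.5
        / (bra["p"][:, None] * ket["p"][None, :] * np.sqrt(pq_sum))
    )
    PQ = bra["P"][:, None, :] - ket["P"][None, :, :]
    L = L_bra + L_ket + 2 * m
    R3 = _r_table_batch(L, alpha.ravel(), PQ.reshape(-1, 3))
    R3 = R3.reshape(Np, Nq, L + 1, L + 1, L + 1)
    w0 = L_ket + 1 + m
    Rsub = sliding_window_view(R3, (w0, w0, w0), axis=(2, 3, 4))
    sgn = _hermite_sign(L_ket + m)
    Ecd_s = ket["E"] * sgn[None, None, None,
                           : ket["E"].shape[3], : ket["E"].shape[4],
                           : ket["E"].shape[5]]
    nt = bra["E"].shape[3]
    if not deriv:
        blk = _einsum_cached(
            "pabtuv,pqtuvxyz,qcdxyz,pq->abcd",
            bra["E"], Rsub, Ecd_s, pref,
        )
        return blk, None
    nb_lo = nt - 1                       # bra Hermite range without derivative
    shape = (4, 3) + bra["E"].shape[1:3] + ket["E"].shape[1:3]
    dblk = np.zeros(shape)
    Rsub_bra = Rsub[:, :, :, :, :, : w0 - 1, : w0 - 1, : w0 - 1]
    Ecd_lo = Ecd_s[:, :, :, : w0 - 1, : w0 - 1, : w0 - 1]
    for x in range(3):
        dblk[0, x] = _einsum_cached(
            "pabtuv,pqtuvxyz,qcdxyz,pq->abcd",
            bra["dA"][x], Rsub_bra, Ecd_lo, pref,
        )
        dblk[1, x] = _einsum_cached(
            "pabtuv,pqtuvxyz,qcdxyz,pq->abcd",
            bra["dB"][x], Rsub_bra, Ecd_lo, pref,
        )
        dEc_s = ket["dA"][x] * sgn[None, None, None]
        dEd_s = ket["dB"][x] * sgn[None, None, None]
        Rsub_ket = Rsub[:, :, : nb_lo, : nb_lo, : nb_lo]
        Eab_lo = bra["E"][:, :, :, : nb_lo, : nb_lo, : nb_lo]
        dblk[2, x] = _einsum_cached(
            "pabtuv,pqtuvxyz,qcdxyz,pq->abcd",
            Eab_lo, Rsub_ket, dEc_s, pref,
        )
        dblk[3, x] = _einsum_cached(
            "pabtuv,pqtuvxyz,qcdxyz,pq->abcd",
            Eab_lo, Rsub_ket, dEd_s, pref,
        )
    return None, dblk


def _canonical_quartets(nsh):
    pairs = [(i, j) for i in range(nsh) for j in range(i, nsh)]
    for a, (i, j) in enumerate(pairs):
        for k, l in pairs[a:]:
            yield i, j, k, l


def eri(shells) -> np.ndarray:
    """Full two-electron repulsion tensor (μν|λσ), chemist notation."""
    offs, n = _shell_offsets(shells)
    V = np.zeros((n, n, n, n))
    bra_cache = {}

    def pdata(i, j):
        if (i, j) not in bra_cache:
            bra_cache[(i, j)] = _bra_data(shells[i], shells[j], deriv=False)
        return bra_cache[(i, j)]

    for i, j, k, l in _canonical_quartets(len(shells)):
        blk, _ = _quartet_blocks(
            pdata(i, j), pdata(k, l),
            shells[i].l + shells[j].l, shells[k].l + shells[l].l, False,
        )
        _scatter_eri(V, blk, offs[i], offs[j], offs[k], offs[l])
    return V


def _scatter_eri(V, blk, oa, ob, oc, od):
    na, nb, nc, nd = blk.shape
    sa, sb = slice(oa, oa + na), slice(ob, ob + nb)
    sc, sd = slice(oc, oc + nc), slice(od, od + nd)
    V[sa, sb, sc, sd] = blk
    V[sb, sa, sc, sd] = blk.transpose(1, 0, 2, 3)
    V[sa, sb, sd, sc] = blk.transpose(0, 1, 3, 2)
    V[sb, sa, sd, sc] = blk.transpose(1, 0, 3, 2)
    V[sc, sd, sa, sb] = blk.transpose(2, 3, 0, 1)
    V[sd, sc, sa, sb] = blk.transpose(3, 2, 0, 1)
    V[sc, sd, sb, sa] = blk.transpose(2, 3, 1, 0)
    V[sd, sc, sb, sa] = blk.transpose(3, 2, 1, 0)


def grad_eri(shells, n_atoms: int) -> np.ndarray:
    """d(μν|λσ)/dR_A for every atom A; shape (n_atoms, 3, n, n, n, n).

    The derivative with respect to an *atom* is invariant under the
    integral's permutational symmetries, so canonical quartets suffice.
    """
    offs, n = _shell_offsets(shells)
    dV = np.zeros((n_atoms, 3, n, n, n, n))
    bra_cache = {}

    def pdata(i, j):
        if (i, j) not in bra_cache:
            bra_cache[(i, j)] = _bra_data(shells[i], shells[j], deriv=True)
        return bra_cache[(i, j)]

    for i, j, k, l in _canonical_quartets(len(shells)):
        _, dblk = _quartet_blocks(
            pdata(i, j), pdata(k, l),
            shells[i].l + shells[j].l, shells[k].l + shells[l].l, True,
        )
        atom_blocks = {}
        for slot, sh_idx in enumerate((i, j, k, l)):
            at = shells[sh_idx].atom_index
            atom_blocks.setdefault(at, np.zeros_like(dblk[0]))
            atom_blocks[at] += dblk[slot]
        for at, ab_blk in atom_blocks.items():
            for x in range(3):
                _scatter_eri(dV[at, x], ab_blk[x], offs[i], offs[j], offs[k], offs[l])
    return dV


# ---------------------------------------------------------------------------
# one-electron gradients

def _grad_pair_overlap_like(sha, shb, kinetic_op: bool):
    """d/dA and d/dB of the overlap or kinetic block for one shell pair."""
    comps_a = cartesian_components(sha.l)
    comps_b = cartesian_components(shb.l)
    dA = np.zeros((3, len(comps_a), len(comps_b)))
    dB = np.zeros_like(dA)
    for ca, aa in zip(sha.coefs, sha.exps):
        for cb, ab in zip(shb.coefs, shb.exps):
            E = _pair_etabs(sha, shb, ca, aa, cb, ab, ma=1, mb=3 if kinetic_op else 1)
            fac = ca * cb * (np.pi / (aa + ab)) ** 1.5

            def val1d(d, i, j):
                if kinetic_op:
                    return (
                        -2.0 * ab * ab * _s1d(E[d], i, j + 2)
                        + ab * (2 * j + 1) * _s1d(E[d], i, j)
                        - 0.5 * j * (j - 1) * _s1d(E[d], i, j - 2)
                    )
                return _s1d(E[d], i, j)

            for ia, la in enumerate(comps_a):
                for ib, lb in enumerate(comps_b):
                    s = [_s1d(E[d], la[d], lb[d]) for d in range(3)]
                    o = [val1d(d, la[d], lb[d]) for d in range(3)]
                    for x in range(3):
                        da_o = 2.0 * aa * val1d(x, la[x] + 1, lb[x]) - la[x] * val1d(x, la[x] - 1, lb[x])
                        db_o = 2.0 * ab * val1d(x, la[x], lb[x] + 1) - lb[x] * val1d(x, la[x], lb[x] - 1)
                        da_s = 2.0 * aa * _s1d(E[x], la[x] + 1, lb[x]) - la[x] * _s1d(E[x], la[x] - 1, lb[x])
                        db_s = 2.0 * ab * _s1d(E[x], la[x], lb[x] + 1) - lb[x] * _s1d(E[x], la[x], lb[x] - 1)
                        if not kinetic_op:
                            dA[x, ia, ib] += fac * da_s * s[(x + 1) % 3] * s[(x + 2) % 3]
                            dB[x, ia, ib] += fac * db_s * s[(x + 1) % 3] * s[(x + 2) % 3]
                        else:
                            y, z = (x + 1) % 3, (x + 2) % 3
                            dA[x, ia, ib] += fac * (
                                da_o * s[y] * s[z]
                                + da_s * o[y] * s[z]
                                + da_s * s[y] * o[z]
                            )
                            dB[x, ia, ib] += fac * (
                                db_o * s[y] * s[z]
                                + db_s * o[y] * s[z]
                                + db_s * s[y] * o[z]
                            )
    return dA, dB


def _grad_assemble(shells, n_atoms, pair_fn):
    offs, n = _shell_offsets(shells)
    dM = np.zeros((n_atoms, 3, n, n))
    for i, sha in enumerate(shells):
        for j in range(i, len(shells)):
            shb = shells[j]
            dA, dB = pair_fn(sha, shb)
            oa, ob = offs[i], offs[j]
            na, nb = dA.shape[1], dA.shape[2]
            for x in range(3):
                dM[sha.atom_index, x, oa:oa + na, ob:ob + nb] += dA[x]
                dM[shb.atom_index, x, oa:oa + na, ob:ob + nb] += dB[x]
                if i != j:
                    dM[sha.atom_index, x, ob:ob + nb, oa:oa + na] += dA[x].T
                    dM[shb.atom_index, x, ob:ob + nb, oa:oa + na] += dB[x].T
    return dM


def grad_overlap(shells, n_atoms: int) -> np.ndarray:
    return _grad_assemble(
        shells, n_atoms, lambda a, b: _grad_pair_overlap_like(a, b, False)
    )


def grad_kinetic(shells, n_atoms: int) -> np.ndarray:
    return _grad_assemble(
        shells, n_atoms, lambda a, b: _grad_pair_overlap_like(a, b, True)
    )


def grad_nuclear_attraction(shells, coords_bohr, charges, n_atoms: int) -> np.ndarray:
    """Gradient of the electron–nuclear attraction matrix.

    Bra/ket-center derivatives come from angular-momentum shifts; the
    derivative with respect to the nuclear position follows from
    translational invariance of each single-nucleus term.
    """
    offs, n = _shell_offsets(shells)
    dM = np.zeros((n_atoms, 3, n, n))
    for i, sha in enumerate(shells):
        for j in range(i, len(shells)):
            shb = shells[j]
            comps_a = cartesian_components(sha.l)
            comps_b = cartesian_components(shb.l)
            na, nb = len(comps_a), len(comps_b)
            for iC, (C, Z) in enumerate(zip(coords_bohr, charges)):
                dA = np.zeros((3, na, nb))
                dB = np.zeros((3, na, nb))
                for ca, aa in zip(sha.coefs, sha.exps):
                    for cb, ab in zip(shb.coefs, shb.exps):
                        p = aa + ab
                        P = (aa * sha.center + ab * shb.center) / p
                        E = _pair_etabs(sha, shb, ca, aa, cb, ab, ma=1, mb=1)
                        fac = -Z * ca * cb * 2.0 * np.pi / p
                        L = sha.l + shb.l + 1
                        R3 = _r_table(L, p, P - C)

                        def vint(la, lb):
                            if min(la + lb) < 0:
                                return 0.0
                            return np.einsum(
                                "t,u,v,tuv->",
                                E[0][la[0], lb[0], : la[0] + lb[0] + 1],
                                E[1][la[1], lb[1], : la[1] + lb[1] + 1],
                                E[2][la[2], lb[2], : la[2] + lb[2] + 1],
                                R3[: la[0] + lb[0] + 1,
                                   : la[1] + lb[1] + 1,
                                   : la[2] + lb[2] + 1],
                            )

                        for ia, la in enumerate(comps_a):
                            for ib, lb in enumerate(comps_b):
                                for x in range(3):
                                    ea = np.array(la)
                                    eb = np.array(lb)
                                    ea[x] += 1
                                    va = 2.0 * aa * vint(tuple(ea), lb)
                                    if la[x] > 0:
                                        ea[x] -= 2
                                        va -= la[x] * vint(tuple(ea), lb)
                                    eb[x] += 1
                                    vb = 2.0 * ab * vint(la, tuple(eb))
                                    if lb[x] > 0:
                                        eb[x] -= 2
                                        vb -= lb[x] * vint(la, tuple(eb))
                                    dA[x, ia, ib] += fac * va
                                    dB[x, ia, ib] += fac * vb
                oa, ob = offs[i], offs[j]

                def add(atom, arr):
                    for x in range(3):
                        dM[atom, x, oa:oa + na, ob:ob + nb] += arr[x]
                        if i != j:
                            dM[atom, x, ob:ob + nb, oa:oa + na] += arr[x].T

                add(sha.atom_index, dA)
                add(shb.atom_index, dB)
                add(iC, -(dA + dB))
    return dM
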