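"""Gaussian-type-orbital basis sets.

Contracted Cartesian GTO shells over which every operator matrix is
represented.  Two standard Pople families are embedded (exponents and
contraction coefficients as published): the minimal STO-3G set and the
split-valence 6-31G set, covering H–Ne as far as the data tables below
go.  Each "SP" entry contributes one s shell and one p shell sharing
exponents.

AO ordering convention (documented, relied on package-wide): shells are
emitted atom by atom in the order listed in the basis table; within a
shell, Cartesian components are ordered x, y, z for l=1 (general l uses
lexicographically decreasing (lx, ly, lz)).  Every contracted AO is
normalized to unit self-overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import Geometry
from .units import ANG_TO_BOHR

# ---------------------------------------------------------------------------
# basis data: element -> list of (shell_type, [(exponent, coef[, coef_p])...])

_STO3G = {
    "H": [("S", [(3.42525091, 0.15432897),
                 (0.62391373, 0.53532814),
                 (0.16885540, 0.44463454)])],
    "He": [("S", [(6.36242139, 0.15432897),
                  (1.15892300, 0.53532814),
                  (0.31364979, 0.44463454)])],
    "B": [("S", [(48.7911130, 0.15432897),
                 (8.88736220, 0.53532814),
                 (2.40526700, 0.44463454)]),
          ("SP", [(2.23695610, -0.09996723, 0.15591627),
                  (0.51982050, 0.39951283, 0.60768372),
                  (0.16906180, 0.70011547, 0.39195739)])],
    "C": [("S", [(71.6168370, 0.15432897),
                 (13.0450960, 0.53532814),
                 (3.53051220, 0.44463454)]),
          ("SP", [(2.94124940, -0.09996723, 0.15591627),
                  (0.68348310, 0.39951283, 0.60768372),
                  (0.22228990, 0.70011547, 0.39195739)])],
    "N": [("S", [(99.1061690, 0.15432897),
                 (18.0523120, 0.53532814),
                 (4.88566020, 0.44463454)]),
          ("SP", [(3.78045590, -0.09996723, 0.15591627),
                  (0.87849660, 0.39951283, 0.60768372),
                  (0.28571440, 0.70011547, 0.39195739)])],
    "O": [("S", [(130.709320, 0.15432897),
                 (23.8088610, 0.53532814),
                 (6.44360830, 0.44463454)]),
          ("SP", [(5.03315130, -0.09996723, 0.15591627),
                  (1.16959610, 0.39951283, 0.60768372),
                  (0.38038900, 0.70011547, 0.39195739)])],
    "F": [("S", [(166.679130, 0.15432897),
                 (30.3608120, 0.53532814),
                 (8.21682070, 0.44463454)]),
          ("SP", [(6.46480320, -0.09996723, 0.15591627),
                  (1.50228120, 0.39951283, 0.60768372),
                  (0.48858850, 0.70011547, 0.39195739)])],
    "Ne": [("S", [(207.015610, 0.15432897),
                  (37.7081510, 0.53532814),
                  (10.2052970, 0.44463454)]),
           ("SP", [(8.24631510, -0.09996723, 0.15591627),
                   (1.91626620, 0.39951283, 0.60768372),
                   (0.62322930, 0.70011547, 0.39195739)])],
}

_631G = {
    "H": [("S", [(18.7311370, 0.03349460),
                 (2.82539370, 0.23472695),
                 (0.64012170, 0.81375733)]),
          ("S", [(0.16127780, 1.0)])],
    "C": [("S", [(3047.52490, 0.0018347),
                 (457.369510, 0.0140373),
                 (103.948690, 0.0688426),
                 (29.2101550, 0.2321844),
                 (9.28666300, 0.4679413),
                 (3.16392700, 0.3623120)]),
          ("SP", [(7.86827240, -0.1193324, 0.0689991),
                  (1.88128850, -0.1608542, 0.3164240),
                  (0.54424930, 1.1434564, 0.7443083)]),
          ("SP", [(0.16871440, 1.0, 1.0)])],
    "N": [("S", [(4173.51100, 0.0018348),
                 (627.457900, 0.0139950),
                 (142.902100, 0.0685870),
                 (40.2343300, 0.2322410),
                 (12.8202100, 0.4690700),
                 (4.39043700, 0.3604550)]),
          ("SP", [(11.6263580, -0.1149610, 0.0675800),
                  (2.71628000, -0.1691180, 0.3239070),
                  (0.77221800, 1.1458520, 0.7408950)]),
          ("SP", [(0.21203130, 1.0, 1.0)])],
    "O": [("S", [(5484.67170, 0.0018311),
                 (825.234950, 0.0139501),
                 (188.046960, 0.0684451),
                 (52.9645000, 0.2327143),
                 (16.8975700, 0.4701930),
                 (5.79963530, 0.3585209)]),
          ("SP", [(15.5396160, -0.1107775, 0.0708743),
                  (3.59993360, -0.1480263, 0.3397528),
                  (1.01376180, 1.1307670, 0.7271586)]),
          ("SP", [(0.27000580, 1.0, 1.0)])],
}

BASIS_SETS = {"sto-3g": _STO3G, "6-31g": _631G}


@dataclass
class Shell:
    """One contracted Cartesian shell."""

    l: int
    center: np.ndarray          # Bohr
    exps: np.ndarray
    coefs: np.ndarray           # primitive-normalized contraction coefficients
    atom_index: int

    @property
    def n_components(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


_L_OF = {"S": 0, "P": 1, "D": 2}


def cartesian_components(l: int):
    """(lx, ly, lz) triples in the package's canonical order."""
    return [
        (lx, ly, l - lx - ly)
        for lx in range(l, -1, -1)
        for ly in range(l - lx, -1, -1)
    ]


def _primitive_norm(l: int, alpha: float) -> float:
    # norm of an (l,0,0) Cartesian primitive; per-component double-factorial
    # corrections are absorbed in the final contracted normalization
    from scipy.special import factorial2

    return (
        (2.0 * alpha / np.pi) ** 0.75
        * (4.0 * alpha) ** (l / 2.0)
        / np.sqrt(float(factorial2(2 * l - 1)) if l > 0 else 1.0)
    )


def build_shells(geom: Geometry, basis_name: str) -> list:
    """Expand a geometry into contracted shells of the named basis set."""
    key = basis_name.lower()
    if key not in BASIS_SETS:
        raise KeyError(
            f"basis {basis_name!r} not available; embedded sets: "
            f"{sorted(BASIS_SETS)}"
        )
    table = BASIS_SETS[key]
    shells = []
    coords_b = geom.coords_bohr()
    for ia, sym in enumerate(geom.symbols):
        if sym not in table:
            raise KeyError(f"element {sym} not tabulated in basis {basis_name}")
        for shell_type, prims in table[sym]:
            prims = np.asarray(prims, dtype=float)
            exps = prims[:, 0]
            if shell_type == "SP":
                cols = [("S", prims[:, 1]), ("P", prims[:, 2])]
            else:
                cols = [(shell_type, prims[:, 1])]
            for st, raw_coefs in cols:
                l = _L_OF[st]
                norms = np.array([_primitive_norm(l, a) for a in exps])
                shells.append(Shell(
                    l=l, center=coords_b[ia].copy(), exps=exps.copy(),
                    coefs=raw_coefs * norms, atom_index=ia,
                ))
    _normalize_contractions(shells)
    return shells


def _normalize_contractions(shells) -> None:
    """Scale contraction coefficients so each contracted AO has unit norm.

    For the s/p shells used here all components of a shell share one
    normalization constant.
    """
    from .integrals import shell_pair_overlap

    for sh in shells:
        diag = np.diagonal(shell_pair_overlap(sh, sh))
        sh.coefs = sh.coefs / np.sqrt(diag[0])


def n_ao(shells) -> int:
    return sum(sh.n_components for sh in shells)


def ao_atom_indices(shells) -> np.ndarray:
    """Atom index of every AO, in the canonical AO ordering."""
    return np.concatenate([
        np.full(sh.n_components, sh.atom_index) for sh in shells
    ])
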