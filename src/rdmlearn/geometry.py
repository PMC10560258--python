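"""Molecular geometries and extended-XYZ input/output.

A :class:`Geometry` is the object that gets sampled, propagated and fed
to the electronic-structure engine: element symbols, Cartesian
coordinates in Å, total charge and spin multiplicity.  All systems
treated here are closed shell (multiplicity 1).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .units import AMU_TO_ME, ANG_TO_BOHR

# standard atomic weights (amu) and nuclear charges
ATOMIC_NUMBER = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7,
    "O": 8, "F": 9, "Ne": 10,
}
ATOMIC_MASS_AMU = {
    "H": 1.008, "He": 4.002602, "Li": 6.94, "Be": 9.0121831,
    "B": 10.81, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998403163, "Ne": 20.1797,
}


@dataclass(frozen=True)
class Geometry:
    """A molecular configuration.

    Parameters
    ----------
    symbols : list of str
        Element symbols, one per atom.
    coords : (N, 3) float array
        Cartesian coordinates in Å.
    charge : int
        Total charge.
    multiplicity : int
        Spin multiplicity (2S+1); only 1 is supported downstream.
    """

    symbols: tuple
    coords: np.ndarray
    charge: int = 0
    multiplicity: int = 1
    comment: str = field(default="", compare=False)

    def __post_init__(self):
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.shape != (len(self.symbols), 3):
            raise ValueError(
                f"coords shape {coords.shape} does not match "
                f"{len(self.symbols)} atoms"
            )
        object.__setattr__(self, "symbols", tuple(self.symbols))
        object.__setattr__(self, "coords", coords)
        for s in self.symbols:
            if s not in ATOMIC_NUMBER:
                raise ValueError(f"unknown element symbol {s!r}")

    @property
    def n_atoms(self) -> int:
        return len(self.symbols)

    @property
    def numbers(self) -> np.ndarray:
        return np.array([ATOMIC_NUMBER[s] for s in self.symbols])

    @property
    def n_electrons(self) -> int:
        return int(self.numbers.sum()) - self.charge

    def masses_amu(self) -> np.ndarray:
        return np.array([ATOMIC_MASS_AMU[s] for s in self.symbols])

    def masses_au(self) -> np.ndarray:
        """Nuclear masses in electron-mass units."""
        return self.masses_amu() * AMU_TO_ME

    def coords_bohr(self) -> np.ndarray:
        return self.coords * ANG_TO_BOHR

    def center_of_mass(self) -> np.ndarray:
        m = self.masses_amu()
        return m @ self.coords / m.sum()

    def with_coords(self, coords: np.ndarray, comment: str | None = None) -> "Geometry":
        return replace(
            self, coords=np.asarray(coords, dtype=float),
            comment=self.comment if comment is None else comment,
        )

    def nuclear_repulsion(self) -> float:
        """Nuclear-nuclear repulsion energy, Hartree."""
        r = self.coords_bohr()
        z = self.numbers.astype(float)
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e


# ---------------------------------------------------------------------------
# extended-XYZ I/O

def _format_frame(geom: Geometry, comment: str | None = None) -> str:
    lines = [str(geom.n_atoms)]
    props = f'Properties=species:S:1:pos:R:3 charge={geom.charge} multiplicity={geom.multiplicity}'
    extra = comment if comment is not None else geom.comment
    lines.append((props + (" " + extra if extra else "")).strip())
    for s, (x, y, z) in zip(geom.symbols, geom.coords):
        lines.append(f"{s:2s} {x:18.10f} {y:18.10f} {z:18.10f}")
    return "\n".join(lines) + "\n"


def write_xyz(path_or_file, geoms, comments=None) -> None:
    """Write one or more geometries as (extended-)XYZ frames."""
    if isinstance(geoms, Geometry):
        geoms = [geoms]
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    fh = open(path_or_file, "w") if own else path_or_file
    try:
        for i, g in enumerate(geoms):
            fh.write(_format_frame(g, None if comments is None else comments[i]))
    finally:
        if own:
            fh.close()


def _parse_key_values(comment: str) -> dict:
    out = {}
    for tok in comment.split():
        if "=" in tok:
            k, _, v = tok.partition("=")
            out[k.lower()] = v
    return out


def read_xyz(path_or_file) -> list:
    """Read all frames of an (extended-)XYZ file into Geometry objects."""
    own = isinstance(path_or_file, (str, bytes)) or hasattr(path_or_file, "__fspath__")
    fh = open(path_or_file) if own else path_or_file
    try:
        text = fh.read()
    finally:
        if own:
            fh.close()
    lines = text.splitlines()
    frames = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        kv = _parse_key_values(comment)
        symbols, coords = [], []
        for j in range(n):
            parts = lines[i + 2 + j].split()
            symbols.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        frames.append(Geometry(
            symbols=tuple(symbols), coords=np.array(coords),
            charge=int(kv.get("charge", 0)),
            multiplicity=int(kv.get("multiplicity", 1)),
            comment=comment,
        ))
        i += 2 + n
    return frames


def loads_xyz(text: str) -> list:
    return read_xyz(io.StringIO(text))
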