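"""Infrared spectra from the dipole-derivative autocorrelation.

Pipeline: bring every trajectory frame (and its dipole vector) into the
Eckart frame of the reference geometry, differentiate the dipole by
central differences, autocorrelate, apply a Hann window, zero-pad to
the next power of two, Fourier transform, and report intensities on an
ascending wavenumber grid.  A vibrational scaling factor (default 0.97)
multiplies the wavenumber axis.

Two production presets mirror common protocols: per-mode velocity
"kicks" from the equilibrium geometry (small molecules), and NVT
equilibration followed by several NVE segments with the dipole recorded
each step (larger molecules).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .frames import eckart_transform
from .geometry import Geometry
from .md import Trajectory, mode_kick_velocities, run_md
from .units import INV_FS_TO_WAVENUMBER

DEFAULT_SCALING = 0.97


@dataclass
class IRSpectrum:
    wavenumbers: np.ndarray      # cm^-1, ascending
    intensities: np.ndarray      # arbitrary units, >= 0
    scaling: float = DEFAULT_SCALING

    def __post_init__(self):
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumber grid must be ascending")
        if np.any(self.intensities < 0):
            raise ValueError("negative intensity")

    def save_csv(self, path):
        np.savetxt(path, np.column_stack([self.wavenumbers, self.intensities]),
                   delimiter=",", header="wavenumber_cm-1,intensity",
                   comments="")


def autocorrelation(x: np.ndarray) -> np.ndarray:
    """One-sided autocorrelation of a (T, k) series, summed over k."""
    x = np.atleast_2d(x.T).T
    T = len(x)
    n = 1 << (2 * T - 1).bit_length()
    X = np.fft.rfft(x, n=n, axis=0)
    acf = np.fft.irfft((X * X.conj()).real, n=n, axis=0)[:T]
    return acf.sum(axis=1)


def spectrum_from_dipoles(dipoles: np.ndarray, dt_fs: float,
                          scaling: float = DEFAULT_SCALING,
                          window: str = "hann",
                          zero_pad: bool = True) -> IRSpectrum:
    """IR spectrum from an (already frame-fixed) dipole time series."""
    dipoles = np.asarray(dipoles, dtype=float)
    if dipoles.ndim == 1:
        dipoles = dipoles[:, None]
    if len(dipoles) < 8:
        raise ValueError("trajectory too short for a spectrum")
    # central-difference dipole derivative
    dmu = (dipoles[2:] - dipoles[:-2]) / (2.0 * dt_fs)
    acf = autocorrelation(dmu)
    if window == "hann":
        w = np.hanning(2 * len(acf))[len(acf):]
    elif window in (None, "none"):
        w = np.ones(len(acf))
    else:
        raise ValueError(f"unknown window {window!r}")
    acf_w = acf * w
    n = len(acf_w)
    if zero_pad:
        n = 1 << (2 * len(acf_w) - 1).bit_length()
    spec = np.abs(np.fft.rfft(acf_w, n=n))
    freqs = np.fft.rfftfreq(n, d=dt_fs) * INV_FS_TO_WAVENUMBER
    return IRSpectrum(wavenumbers=freqs * scaling, intensities=spec,
                      scaling=scaling)


def ir_spectrum(traj: Trajectory, ref: Geometry,
                scaling: float = DEFAULT_SCALING,
                window: str = "hann", zero_pad: bool = True) -> IRSpectrum:
    """IR spectrum of one trajectory with recorded dipoles.

    Coordinates are Eckart-aligned to ``ref`` frame by frame and the
    same rotations are applied to the dipole vectors before the
    derivative-autocorrelation transform.
    """
    if traj.dipoles is None:
        raise ValueError("trajectory has no recorded dipoles")
    if traj.dt_fs <= 0:
        raise ValueError("trajectory needs at least two frames")
    _, tfs = eckart_transform(list(traj.coords), ref)
    mu = np.array([
        tf.rotate_vectors(d) for tf, d in zip(tfs, traj.dipoles)
    ])
    return spectrum_from_dipoles(mu, traj.dt_fs, scaling=scaling,
                                 window=window, zero_pad=zero_pad)


def average_spectra(spectra) -> IRSpectrum:
    """Average spectra sharing one wavenumber grid."""
    ref = spectra[0]
    for s in spectra[1:]:
        if len(s.wavenumbers) != len(ref.wavenumbers) or not np.allclose(
                s.wavenumbers, ref.wavenumbers):
            raise ValueError("spectra grids differ; cannot average")
    inten = np.mean([s.intensities for s in spectra], axis=0)
    return IRSpectrum(ref.wavenumbers.copy(), inten, ref.scaling)


# ---------------------------------------------------------------------------
# production presets

def kicked_mode_spectrum(modes, force_provider, dipole_provider,
                         t_kick: float = 50.0, dt_fs: float = 0.5,
                         n_steps: int = 2000,
                         scaling: float = DEFAULT_SCALING) -> IRSpectrum:
    """One NVE run per normal mode with a per-mode velocity kick.

    Each trajectory starts at equilibrium with velocities along a single
    vibrational mode at an instantaneous temperature ``t_kick``; the
    spectra are averaged.
    """
    spectra = []
    for i in range(modes.n_vib):
        v0 = mode_kick_velocities(modes, i, t_kick)
        traj = run_md(modes.equilibrium, v0, force_provider, dt_fs=dt_fs,
                      n_steps=n_steps, ensemble="nve",
                      dipole_provider=dipole_provider)
        spectra.append(ir_spectrum(traj, modes.equilibrium, scaling=scaling))
    return average_spectra(spectra)


def sampled_nve_spectrum(geom: Geometry, force_provider, dipole_provider,
                         temperature: float = 300.0, dt_fs: float = 0.5,
                         n_equil_steps: int = 2000, n_segments: int = 3,
                         segment_steps: int = 2000, seed: int = 0,
                         scaling: float = DEFAULT_SCALING) -> IRSpectrum:
    """NVT equilibration, then several NVE segments with dipoles recorded."""
    from .md import maxwell_boltzmann_velocities

    v0 = maxwell_boltzmann_velocities(geom, temperature, seed=seed)
    nvt = run_md(geom, v0, force_provider, dt_fs=dt_fs,
                 n_steps=n_equil_steps, ensemble="nvt",
                 temperature=temperature, seed=seed)
    spectra = []
    pick = np.linspace(len(nvt.times) // 2, len(nvt.times) - 1,
                       n_segments).astype(int)
    for k, idx in enumerate(pick):
        g = geom.with_coords(nvt.coords[idx])
        traj = run_md(g, nvt.velocities[idx], force_provider, dt_fs=dt_fs,
                      n_steps=segment_steps, ensemble="nve",
                      dipole_provider=dipole_provider)
        spectra.append(ir_spectrum(traj, geom, scaling=scaling))
    return average_spectra(spectra)
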