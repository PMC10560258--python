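"""Physical constants and unit conversions.

Internal computations use Hartree atomic units throughout; public
interfaces speak Å, kcal/mol, kcal/(mol Å), Debye, femtoseconds and
Kelvin.  Values follow CODATA 2018 (via scipy.constants).
"""

from scipy import constants as _c

# lengths
BOHR_TO_ANG: float = _c.value("Bohr radius") * 1e10          # 0.529177...
ANG_TO_BOHR: float = 1.0 / BOHR_TO_ANG

# energies
HARTREE_TO_EV: float = _c.value("Hartree energy in eV")       # 27.2114...
HARTREE_TO_KCALMOL: float = (
    _c.value("Hartree energy") * _c.N_A / (_c.calorie * 1000.0)
)                                                             # 627.5095...
KCALMOL_TO_HARTREE: float = 1.0 / HARTREE_TO_KCALMOL

# Boltzmann constant in Hartree / K
KB_HARTREE: float = _c.k / _c.value("Hartree energy")         # 3.16681e-6

# dipole: atomic units (e*a0) -> Debye
AU_TO_DEBYE: float = (
    _c.e * _c.value("Bohr radius") / 1e-21 * _c.c
)                                                             # 2.54175...

# time: 1 atomic time unit in fs, and its inverse
AU_TIME_FS: float = _c.value("atomic unit of time") * 1e15    # 0.0241888...
FS_TO_AU: float = 1.0 / AU_TIME_FS                            # 41.3414...

# masses
AMU_TO_ME: float = _c.value("atomic mass constant") / _c.m_e  # 1822.888...

# spectroscopy: Hartree (= a.u. angular frequency) -> wavenumber cm^-1
HARTREE_TO_WAVENUMBER: float = (
    _c.value("hartree-inverse meter relationship") / 100.0
)                                                             # 219474.63...

# frequency grid of an FFT over an fs-spaced series -> cm^-1
INV_FS_TO_WAVENUMBER: float = 1e15 / (_c.c * 100.0)           # 33356.41...
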