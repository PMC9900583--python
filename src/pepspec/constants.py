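"""Physical constants and unit conversions.

Internal unit system for model dynamics: amu / Å / fs (so energies are in
amu·Å²/fs²).  Spectroscopy is in wavenumbers (cm⁻¹), Gibbs energies in
kcal/mol, dipoles in Debye, densities in nm⁻³.
"""

from scipy import constants as _sc

#: Speed of light in cm/s (wavenumber ↔ time conversions).
C_CM_PER_S: float = _sc.c * 100.0

#: Speed of light expressed so that ν[cm⁻¹]·C_CM_PER_FS has units fs⁻¹.
C_CM_PER_FS: float = C_CM_PER_S * 1e-15

#: 2π·c in rad·cm/fs: angular frequency ω[rad/fs] = TWO_PI_C_FS · ν[cm⁻¹].
TWO_PI_C_FS: float = 2.0 * _sc.pi * C_CM_PER_FS

#: Boltzmann constant in kcal/(mol·K).
KB_KCAL_PER_MOL_K: float = _sc.R / _sc.calorie / 1000.0

#: Boltzmann constant in amu·Å²/fs²/K (for velocity initialization).
KB_AMU_A2_FS2: float = _sc.k / (_sc.atomic_mass * 1e-20 / 1e-30)

#: Second radiation constant h·c/k_B in cm·K (wavenumber → temperature).
HC_OVER_KB_CM_K: float = _sc.h * C_CM_PER_S / _sc.k

#: Dipole conversion: 1 e·Å = 4.8032 Debye.
E_ANG_TO_DEBYE: float = _sc.e * 1e-10 / 3.33564095e-30

#: Bohr radius in Å (cube-file axes are conventionally in bohr).
BOHR_TO_ANG: float = _sc.physical_constants["Bohr radius"][0] * 1e10

#: Electron density conversion: 1 a.u. (bohr⁻³) in nm⁻³ (≈ 6748.33).
AU_DENSITY_TO_NM3: float = 1.0 / (BOHR_TO_ANG / 10.0) ** 3
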