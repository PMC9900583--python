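"""Integrator-induced frequency blue-shift power law.

A finite MD time step blue-shifts every dynamic frequency ν_D relative to
its harmonic value ν_H.  In the dimensionless variable x = ν·c·Δt the
shift Δx = (ν_D − ν_H)·c·Δt follows a molecule-independent power law
Δx = a·x^b that depends only on the integration scheme.  This module fits
the law from (ν_H, ν_D, Δt) points, predicts forward shifts, and inverts
the law to correct spectra run at long time steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .constants import C_CM_PER_FS, HC_OVER_KB_CM_K
from .errors import ConvergenceError, ValidationError


@dataclass
class PowerLaw:
    """Δx = a·x^b in dimensionless frequency x = ν·c·Δt."""

    a: float
    b: float
    residual: Optional[float] = None   # RMS log-residual of the fit
    n_points: Optional[int] = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValidationError("power-law constant must be positive")
        if self.b <= 1:
            raise ValidationError("power-law exponent must exceed 1")


#: Named calibration profiles.  "admp-b3lyp-n07d" carries the published
#: calibration for the ADMP propagator; "velocity-verlet" the analytic
#: leading order (2π)²/24·x³ of the velocity-Verlet harmonic oscillator.
PROFILES: dict[str, PowerLaw] = {
    "admp-b3lyp-n07d": PowerLaw(2.95, 3.25),
    "velocity-verlet": PowerLaw((2.0 * np.pi) ** 2 / 24.0, 3.0),
}


@dataclass
class ShiftPoint:
    """One calibration point: harmonic/dynamic frequency pair at Δt."""

    nu_h: float        # cm⁻¹
    nu_d: float        # cm⁻¹
    dt_fs: float
    uncertainty: Optional[float] = None

    def __post_init__(self) -> None:
        if self.nu_h < 0 or self.nu_d < self.nu_h:
            raise ValidationError("require ν_D >= ν_H >= 0")
        if self.dt_fs <= 0:
            raise ValidationError("time step must be positive")


def dimensionless(nu: float, dt_fs: float) -> float:
    """x = ν·c·Δt (non-angular convention)."""
    if dt_fs <= 0:
        raise ValidationError("time step must be positive")
    return nu * C_CM_PER_FS * dt_fs


def fit_power_law(points: Sequence[ShiftPoint]) -> PowerLaw:
    """Least squares of log Δx on log x.

    Points with zero (or negative) shift carry no log-space information
    and are excluded with a warning; at least two usable points with
    distinct x are required.
    """
    xs, dxs = [], []
    dropped = 0
    for p in points:
        dx = (p.nu_d - p.nu_h) * C_CM_PER_FS * p.dt_fs
        if dx <= 0:
            dropped += 1
            continue
        xs.append(dimensionless(p.nu_h, p.dt_fs))
        dxs.append(dx)
    if dropped:
        warnings.warn(f"excluded {dropped} point(s) with non-positive shift")
    if len(set(xs)) < 2:
        raise ValidationError("need >= 2 usable points with distinct x")
    lx, ldx = np.log(xs), np.log(dxs)
    b, loga = np.polyfit(lx, ldx, 1)
    resid = float(np.sqrt(np.mean((ldx - (b * lx + loga)) ** 2)))
    return PowerLaw(float(np.exp(loga)), float(b), residual=resid,
                    n_points=len(xs))


def predict_shift(nu_h: float, dt_fs: float, law: PowerLaw) -> float:
    """Forward blue shift Δν = a·(ν_H·c·Δt)^b / (c·Δt) in cm⁻¹."""
    if nu_h == 0:
        return 0.0
    x = dimensionless(nu_h, dt_fs)
    return law.a * x ** law.b / (C_CM_PER_FS * dt_fs)


def correct_frequency(
    nu_d: float,
    dt_fs: float,
    law: PowerLaw,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> float:
    """Invert the law: find ν_H with ν_H + Δν(ν_H) = ν_D (Newton)."""
    c_dt = C_CM_PER_FS * dt_fs
    nu = float(nu_d)
    for _ in range(max_iter):
        x = nu * c_dt
        f = nu + law.a * x ** law.b / c_dt - nu_d
        if abs(f) < tol:
            return nu
        fp = 1.0 + law.a * law.b * x ** (law.b - 1.0)
        nu -= f / fp
    raise ConvergenceError(
        f"Newton iteration did not reach {tol} cm⁻¹ in {max_iter} steps"
    )


def width_match_temperature(nu: float) -> float:
    """Temperature (K) at which the classical thermal energy matches the
    vibrational quantum: k_B·T = h·c·ν."""
    if nu < 0:
        raise ValidationError("frequency must be non-negative")
    return HC_OVER_KB_CM_K * nu
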