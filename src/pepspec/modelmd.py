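"""Velocity-Verlet dynamics of analytic model systems with dipole output.

Reproduces the published BOMD protocol — Maxwell–Boltzmann initial
velocities at twice the target temperature (so each mode carries k_B·T on
ensemble average), removal of linear and angular momenta by projection,
velocity-Verlet propagation, dipole recording — with forces from analytic
potentials (site/bond harmonic springs, Morse pairs) instead of an
electronic-structure surface, keeping every downstream spectral stage
testable at desk scale.

Units: amu, Å, fs; energies in amu·Å²/fs²; dipoles from point charges (e)
reported in Debye.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .constants import E_ANG_TO_DEBYE, KB_AMU_A2_FS2, TWO_PI_C_FS
from .errors import InstabilityError, UnstableStepError, ValidationError
from .structures import DipoleTrajectory


@dataclass
class ModelSystem:
    """Point masses on analytic potentials, with charges for the dipole.

    ``site_springs``: (atom, k) isotropic tethers to the atom's anchor
    point (``site_anchors``, defaulting to the initial coordinates);
    ``bond_springs``: (i, j, k, r0) harmonic pair springs;
    ``morse``: (i, j, D, alpha, r0) Morse pairs.  Spring constants are in
    amu/fs² (i.e. energy/Å²), D in amu·Å²/fs², alpha in 1/Å.
    """

    masses: np.ndarray
    coords0: np.ndarray
    charges: np.ndarray
    site_springs: list[tuple[int, float]] = field(default_factory=list)
    bond_springs: list[tuple[int, int, float, float]] = field(default_factory=list)
    morse: list[tuple[int, int, float, float, float]] = field(default_factory=list)
    site_anchors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.masses = np.atleast_1d(np.asarray(self.masses, float))
        self.coords0 = np.asarray(self.coords0, float).reshape(-1, 3)
        self.charges = np.atleast_1d(np.asarray(self.charges, float))
        if self.site_anchors is None:
            self.site_anchors = self.coords0.copy()
        else:
            self.site_anchors = np.asarray(self.site_anchors, float).reshape(-1, 3)
        n = self.masses.size
        if self.coords0.shape[0] != n or self.charges.size != n \
                or self.site_anchors.shape[0] != n:
            raise ValidationError("masses/coords/charges length mismatch")
        if np.any(self.masses <= 0):
            raise ValidationError("masses must be positive")
        for _, k in self.site_springs:
            if k <= 0:
                raise ValidationError("spring constants must be positive")
        for _, _, k, _ in self.bond_springs:
            if k <= 0:
                raise ValidationError("spring constants must be positive")
        for _, _, d, a, _ in self.morse:
            if d <= 0 or a <= 0:
                raise ValidationError("Morse parameters must be positive")

    @property
    def n_atoms(self) -> int:
        return self.masses.size

    @classmethod
    def harmonic_oscillator(cls, nu_cm: float, mass: float = 1.0,
                            charge: float = 1.0,
                            displacement: float = 0.01) -> "ModelSystem":
        """A 1-D harmonic oscillator with mode wavenumber ``nu_cm``.

        One atom tethered to the origin with k = m·ω², displaced along x
        by ``displacement`` Å so the dipole μx = q·x oscillates at ν.
        """
        omega = TWO_PI_C_FS * nu_cm          # rad/fs
        k = mass * omega ** 2
        return cls(
            masses=[mass],
            coords0=[[displacement, 0.0, 0.0]],
            charges=[charge],
            site_springs=[(0, k)],
            site_anchors=[[0.0, 0.0, 0.0]],
        )

    def max_harmonic_omega(self) -> float:
        """Largest harmonic angular frequency (rad/fs) for stability checks."""
        omegas = [np.sqrt(k / self.masses[i]) for i, k in self.site_springs]
        for i, j, k, _ in self.bond_springs:
            mu = 1.0 / (1.0 / self.masses[i] + 1.0 / self.masses[j])
            omegas.append(np.sqrt(k / mu))
        return max(omegas, default=0.0)

    def forces_energy(self, x: np.ndarray) -> tuple[np.ndarray, float]:
        f = np.zeros_like(x)
        e = 0.0
        for i, k in self.site_springs:
            d = x[i] - self.site_anchors[i]
            f[i] -= k * d
            e += 0.5 * k * float(d @ d)
        for i, j, k, r0 in self.bond_springs:
            d = x[i] - x[j]
            r = np.linalg.norm(d)
            u = d / r
            f[i] -= k * (r - r0) * u
            f[j] += k * (r - r0) * u
            e += 0.5 * k * (r - r0) ** 2
        for i, j, de, al, r0 in self.morse:
            d = x[i] - x[j]
            r = np.linalg.norm(d)
            u = d / r
            ex = np.exp(-al * (r - r0))
            f_mag = 2.0 * de * al * ex * (1.0 - ex)
            f[i] -= f_mag * u
            f[j] += f_mag * u
            e += de * (1.0 - ex) ** 2
        return f, e

    def dipole(self, x: np.ndarray) -> np.ndarray:
        return (self.charges[:, None] * x).sum(axis=0) * E_ANG_TO_DEBYE


@dataclass
class SimulationConfig:
    """Run controls mirroring the BOMD protocol."""

    dt_fs: float = 0.5
    steps: int = 5000
    temperature: float = 0.0
    seed: int = 0
    velocity_init: str = "maxwell-boltzmann-2t"   # or "zero"
    project_momenta: bool = True

    def __post_init__(self) -> None:
        if self.dt_fs <= 0:
            raise ValidationError("time step must be positive")
        if self.steps < 1:
            raise ValidationError("need at least one step")
        if self.velocity_init not in ("maxwell-boltzmann-2t", "zero"):
            raise ValidationError(f"unknown init {self.velocity_init!r}")


def init_velocities(masses: np.ndarray, temperature: float,
                    seed: int | np.random.Generator = 0) -> np.ndarray:
    """Maxwell–Boltzmann velocities at temperature parameter 2T.

    Each component is normal with variance k_B·(2T)/m, so after
    equipartition between kinetic and potential energy each vibrational
    mode carries k_B·T on ensemble average.
    """
    if temperature < 0:
        raise ValidationError("temperature must be non-negative")
    masses = np.atleast_1d(np.asarray(masses, float))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    if temperature == 0:
        return np.zeros((masses.size, 3))
    sigma = np.sqrt(KB_AMU_A2_FS2 * 2.0 * temperature / masses)
    return rng.standard_normal((masses.size, 3)) * sigma[:, None]


def remove_momenta(positions: np.ndarray, velocities: np.ndarray,
                   masses: np.ndarray) -> np.ndarray:
    """Project out total linear and angular momentum.

    The angular projection solves I·ω = L with the pseudo-inverse of the
    inertia tensor, so for (near-)collinear systems only the well-defined
    rotation axes are removed.
    """
    x = np.asarray(positions, float).reshape(-1, 3)
    v = np.asarray(velocities, float).reshape(-1, 3).copy()
    m = np.atleast_1d(np.asarray(masses, float))
    com = (m[:, None] * x).sum(axis=0) / m.sum()
    v -= (m[:, None] * v).sum(axis=0) / m.sum()
    if x.shape[0] >= 2:
        r = x - com
        ell = (m[:, None] * np.cross(r, v)).sum(axis=0)
        inertia = np.zeros((3, 3))
        for mi, ri in zip(m, r):
            inertia += mi * (float(ri @ ri) * np.eye(3) - np.outer(ri, ri))
        omega = np.linalg.pinv(inertia, rcond=1e-10) @ ell
        v -= np.cross(omega, r)
    return v


def simulate(system: ModelSystem, config: SimulationConfig,
             initial_velocities: Optional[np.ndarray] = None
             ) -> DipoleTrajectory:
    """Velocity-Verlet propagation recording the dipole every step.

    Raises :class:`UnstableStepError` when Δt exceeds the harmonic
    stability limit 2/ω_max and :class:`InstabilityError` if the total
    energy grows beyond 10× its initial magnitude.
    """
    omega_max = system.max_harmonic_omega()
    if omega_max > 0 and config.dt_fs >= 2.0 / omega_max:
        raise UnstableStepError(
            f"Δt = {config.dt_fs} fs >= stability limit "
            f"{2.0 / omega_max:.3g} fs"
        )
    x = system.coords0.copy()
    if initial_velocities is not None:
        v = np.asarray(initial_velocities, float).reshape(-1, 3).copy()
    elif config.velocity_init == "zero":
        v = np.zeros_like(x)
    else:
        v = init_velocities(system.masses, config.temperature, config.seed)
    if config.project_momenta and system.n_atoms >= 2:
        v = remove_momenta(x, v, system.masses)

    m = system.masses[:, None]
    dt = config.dt_fs
    f, pe = system.forces_energy(x)
    e0 = pe + 0.5 * float((m * v * v).sum())
    e_scale = max(abs(e0), 1e-12)
    mus = [system.dipole(x)]
    energies = [e0]
    for step in range(config.steps):
        v_half = v + 0.5 * dt * f / m
        x = x + dt * v_half
        f, pe = system.forces_energy(x)
        v = v_half + 0.5 * dt * f / m
        mus.append(system.dipole(x))
        if step % 100 == 0 or step == config.steps - 1:
            e = pe + 0.5 * float((m * v * v).sum())
            energies.append(e)
            if e - e0 > 10.0 * e_scale:
                raise InstabilityError(
                    f"energy diverged at step {step}: {e:.3g} vs {e0:.3g}"
                )
    return DipoleTrajectory(dt, np.array(mus),
                            metadata={"steps": config.steps,
                                      "temperature": config.temperature,
                                      "seed": config.seed,
                                      "energy_samples": energies})


def analytic_vv_frequency(nu_cm: float, dt_fs: float) -> float:
    """Exact oscillation wavenumber of velocity Verlet on a harmonic mode.

    ν_D = (2/Δt)·asin(ωΔt/2)/(2πc) with ω = 2πcν; the blue shift grows as
    ν·(ωΔt)²/24 at leading order.
    """
    if dt_fs <= 0:
        raise ValidationError("time step must be positive")
    if nu_cm == 0:
        return 0.0
    arg = TWO_PI_C_FS * nu_cm * dt_fs / 2.0
    if arg >= 1.0:
        raise UnstableStepError(
            f"ωΔt/2 = {arg:.3f} >= 1: unstable step for ν = {nu_cm} cm⁻¹"
        )
    return float(2.0 / dt_fs * np.arcsin(arg) / TWO_PI_C_FS)
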