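import numpy as np
import pytest

from pepspec.constants import KB_AMU_A2_FS2
from pepspec.dynamic import PSDOptions, psd
from pepspec.errors import InstabilityError, UnstableStepError, ValidationError
from pepspec.modelmd import (
    ModelSystem,
    SimulationConfig,
    analytic_vv_frequency,
    init_velocities,
    remove_momenta,
    simulate,
)


def test_zero_temperature_zero_velocities():
    v = init_velocities(np.ones(5), 0.0, seed=0)
    assert np.all(v == 0.0)


def test_equipartition_at_double_temperature():
    """2T initialization: mean kinetic energy per atom (3/2)·k_B·(2T)."""
    rng = np.random.default_rng(0)
    masses = np.full(20_000, 3.0)
    v = init_velocities(masses, 300.0, rng)
    ke = 0.5 * (masses[:, None] * v ** 2).sum() / masses.size
    assert ke == pytest.approx(1.5 * KB_AMU_A2_FS2 * 600.0, rel=0.02)


def test_velocity_seed_reproducible():
    a = init_velocities(np.ones(10), 150.0, seed=42)
    b = init_velocities(np.ones(10), 150.0, seed=42)
    assert np.array_equal(a, b)


def test_remove_uniform_drift():
    x = np.random.default_rng(0).standard_normal((4, 3))
    v = np.tile([1.0, -2.0, 0.5], (4, 1))
    assert np.abs(remove_momenta(x, v, np.ones(4))).max() < 1e-12


def test_remove_rigid_rotation():
    rng = np.random.default_rng(1)
    x = rng.standard_normal((5, 3))
    m = np.abs(rng.standard_normal(5)) + 0.5
    com = (m[:, None] * x).sum(0) / m.sum()
    omega = np.array([0.3, -0.2, 0.7])
    v = np.cross(omega, x - com)
    assert np.abs(remove_momenta(x, v, m)).max() < 1e-12


def test_remove_mixed_field_residuals():
    rng = np.random.default_rng(2)
    x, v = rng.standard_normal((6, 3)), rng.standard_normal((6, 3))
    m = np.abs(rng.standard_normal(6)) + 0.5
    v2 = remove_momenta(x, v, m)
    com = (m[:, None] * x).sum(0) / m.sum()
    p = (m[:, None] * v2).sum(0)
    ell = (m[:, None] * np.cross(x - com, v2)).sum(0)
    scale = np.abs(m[:, None] * v).sum()
    assert np.abs(p).max() / scale < 1e-12
    assert np.abs(ell).max() / scale < 1e-12


def test_oscillator_psd_peak_at_integrator_frequency():
    system = ModelSystem.harmonic_oscillator(1000.0)
    cfg = SimulationConfig(dt_fs=2.0, steps=2000, velocity_init="zero")
    traj = simulate(system, cfg)
    spec = psd(traj, PSDOptions(pad_factor=8))
    peak = spec.grid[np.argmax(spec.values)]
    assert abs(peak - analytic_vv_frequency(1000.0, 2.0)) <= spec.spacing


def test_static_system_constant_dipole():
    system = ModelSystem(masses=[1.0], coords0=[[0.5, 0, 0]],
                         charges=[1.0], site_springs=[(0, 0.1)],
                         site_anchors=[[0.5, 0, 0]])
    traj = simulate(system, SimulationConfig(dt_fs=0.5, steps=200,
                                             velocity_init="zero"))
    assert np.ptp(traj.mu, axis=0).max() < 1e-12


def test_energy_conservation_no_secular_drift():
    """Velocity Verlet over 1e5 steps: the total energy oscillates within
    the shadow-Hamiltonian band ≈ (ωΔt)²/8 but shows no secular drift."""
    system = ModelSystem.harmonic_oscillator(2000.0, displacement=0.05)
    traj = simulate(system, SimulationConfig(dt_fs=0.5, steps=100_000,
                                             velocity_init="zero"))
    e = np.array(traj.metadata["energy_samples"])
    omega_dt = system.max_harmonic_omega() * 0.5
    assert np.ptp(e) / e.mean() < omega_dt ** 2 / 2.0  # bounded oscillation
    # no secular growth: the late-run excursion stays within the band
    # already explored early on
    early = e[: e.size // 5]
    assert e.max() <= early.max() + 0.05 * np.ptp(early)
    assert e.min() >= early.min() - 0.05 * np.ptp(early)


def test_unstable_step_rejected():
    system = ModelSystem.harmonic_oscillator(2000.0)
    with pytest.raises(UnstableStepError):
        simulate(system, SimulationConfig(dt_fs=6.0, steps=10))


def test_morse_blowup_raises_instability():
    """A Morse pair started deep inside the repulsive wall with a step far
    beyond stability diverges and is reported, not silently returned."""
    system = ModelSystem(
        masses=[1.0, 1.0],
        coords0=[[0.0, 0, 0], [0.4, 0, 0]],
        charges=[0.5, -0.5],
        morse=[(0, 1, 0.1, 2.0, 1.0)],
    )
    with pytest.raises(InstabilityError):
        simulate(system, SimulationConfig(dt_fs=2.5, steps=500,
                                          project_momenta=False,
                                          velocity_init="zero"))


def test_analytic_vv_frequency_values():
    assert analytic_vv_frequency(1000.0, 2.0) == pytest.approx(1006.01,
                                                               abs=0.02)
    assert analytic_vv_frequency(1000.0, 1e-6) == pytest.approx(1000.0,
                                                                abs=1e-6)
    s2 = analytic_vv_frequency(1000.0, 2.0) - 1000.0
    s1 = analytic_vv_frequency(1000.0, 1.0) - 1000.0
    assert s2 / s1 == pytest.approx(4.0, rel=0.02)  # quadratic in Δt
    with pytest.raises(UnstableStepError):
        analytic_vv_frequency(4000.0, 3.0)


def test_config_validation():
    with pytest.raises(ValidationError):
        SimulationConfig(dt_fs=-0.5)
    with pytest.raises(ValidationError):
        SimulationConfig(steps=0)
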