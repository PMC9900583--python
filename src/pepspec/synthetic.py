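"""Synthetic-data generators for every pipeline input.

These generators define the study conditions under which the pipeline is
validated: dipole signals with known mode content, idealized polyalanine
geometries with prescribed backbone torsions and turn motifs, analytic
electron-density grids with controllable H-bond bridge features, and
IRMPD ion counts drawn from the same survival/fragmentation model the
extraction formula assumes.  All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np

from .constants import C_CM_PER_FS
from .errors import FixtureError, ValidationError
from .structures import (
    DipoleTrajectory,
    IonCountRecord,
    MolecularStructure,
    ScalarField,
)

# --------------------------------------------------------------------------
# dipole signals
# --------------------------------------------------------------------------

def gen_dipole_signal(
    modes: Sequence[tuple[float, float, float]],
    dt_fs: float = 0.5,
    tau_ps: float = 2.5,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> DipoleTrajectory:
    """Sum-of-cosines dipole along x plus white noise on all components.

    ``modes`` is a list of (ν/cm⁻¹, amplitude/Debye, phase/rad); the exact
    mode list is kept in the trajectory metadata.  Frequencies at or above
    the Nyquist limit 1/(2cΔt) are rejected.
    """
    nyquist = 1.0 / (2.0 * C_CM_PER_FS * dt_fs)
    for nu, _, _ in modes:
        if nu >= nyquist:
            raise ValidationError(
                f"mode at {nu} cm⁻¹ at/above Nyquist {nyquist:.0f} cm⁻¹"
            )
    n = int(round(tau_ps * 1000.0 / dt_fs)) + 1
    t = np.arange(n) * dt_fs
    mu = np.zeros((n, 3))
    for nu, amp, phase in modes:
        mu[:, 0] += amp * np.cos(2.0 * np.pi * C_CM_PER_FS * nu * t + phase)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        mu += rng.standard_normal(mu.shape) * noise_sigma
    return DipoleTrajectory(dt_fs, mu, metadata={"modes": list(modes),
                                                 "noise_sigma": noise_sigma,
                                                 "seed": seed})


# --------------------------------------------------------------------------
# toy peptides
# --------------------------------------------------------------------------

# idealized internal coordinates (Å / degrees)
_B = {"N-CA": 1.458, "CA-C": 1.525, "C-N": 1.329, "C=O": 1.231,
      "C-OX": 1.340, "O-H": 0.970, "N-H": 1.010, "CA-CB": 1.530,
      "CA-HA": 1.090, "CB-HB": 1.090}
_A = {"N-CA-C": 111.0, "CA-C-N": 116.2, "C-N-CA": 121.7, "CA-C=O": 120.8,
      "N-CA-CB": 110.5, "CA-C-OX": 111.4, "C-O-H": 107.0, "C-N-H": 119.0,
      "CA-N-H": 109.5, "CA-CB-HB": 109.5}

# canonical turn torsions (φ, ψ) for the enclosed residues of each motif
_MOTIF_TORSIONS = {
    "beta": [(-60.0, -30.0), (-90.0, 0.0)],    # type-I β-turn, i+1 and i+2
    "gamma": [(-79.0, 69.0)],                  # inverse γ-turn, i+1
    "c5": [(-160.0, 165.0)],                   # extended unit at residue i
}
_MOTIF_SPAN = {"beta": 3, "gamma": 2, "c5": 0}


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place atom D bonded to c with angle(b,c,D) and torsion(a,b,c,D)."""
    ang, tor = np.radians(angle), np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise FixtureError("collinear reference frame in peptide builder")
    n /= nn
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def gen_toy_peptide(
    n_residues: int,
    torsions: Optional[Sequence[float]] = None,
    motifs: Optional[Sequence[tuple[str, int]]] = None,
) -> MolecularStructure:
    """Idealized polyalanine with prescribed backbone torsions.

    ``torsions`` lists the 2·n informative angles (φ_N, ψ1, φ2, ψ2, …,
    φ_n, ψ_C), defaulting to all-trans (180°).  ``motifs`` are
    (kind, start_residue) pairs with kind in {"beta", "gamma", "c5"};
    each overrides the enclosed residues' φ/ψ with canonical turn values
    (β: i+1, i+2; γ: i+1; C5: the extended unit at i).  ω torsions are
    trans; bond lengths and angles are idealized, so the realized
    backbone torsions match the request to well under 1°.
    """
    if n_residues < 1:
        raise FixtureError("need at least one residue")
    n_angles = 2 * n_residues
    if torsions is None:
        torsions = [180.0] * n_angles
    torsions = [float(v) for v in torsions]
    if len(torsions) != n_angles:
        raise FixtureError(
            f"{n_residues} residues require {n_angles} torsions, "
            f"got {len(torsions)}"
        )
    for kind, start in motifs or ():
        if kind not in _MOTIF_TORSIONS:
            raise FixtureError(f"unknown motif {kind!r}")
        if not 1 <= start <= n_residues - _MOTIF_SPAN[kind]:
            raise FixtureError(
                f"motif {kind!r} at residue {start} cannot close within "
                f"{n_residues} residues"
            )
        for off, (phi, psi) in enumerate(_MOTIF_TORSIONS[kind],
                                         start=1 if kind != "c5" else 0):
            r = start + off  # 1-based residue whose φ/ψ are set
            torsions[2 * (r - 1)] = phi
            torsions[2 * (r - 1) + 1] = psi

    phis = torsions[0::2]   # φ_N, φ2, …, φ_n
    psis = torsions[1::2]   # ψ1, …, ψ_{n-1}, ψ_C

    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int]] = []
    labels: list[str] = []

    def add(sym: str, pos: np.ndarray, res: int,
            bond_to: Optional[int] = None) -> int:
        elements.append(sym)
        coords.append(np.asarray(pos, float))
        labels.append(f"ALA{res}")
        idx = len(elements) - 1
        if bond_to is not None:
            bonds.append((bond_to, idx))
        return idx

    # residue 1 backbone seed in the xy-plane
    n1 = add("N", np.array([0.0, 0.0, 0.0]), 1)
    ca = add("C", np.array([_B["N-CA"], 0.0, 0.0]), 1, n1)
    ang = np.radians(180.0 - _A["N-CA-C"])
    c = add("C", coords[ca] + _B["CA-C"] * np.array(
        [np.cos(ang), np.sin(ang), 0.0]), 1, ca)

    # amine hydrogens: torsions φ_N ± 60° about N-CA so their centroid
    # realizes φ_N exactly
    for sgn in (+60.0, -60.0):
        h = _place(coords[c], coords[ca], coords[n1], _B["N-H"],
                   _A["CA-N-H"], phis[0] + sgn)
        add("H", h, 1, n1)

    prev_n, prev_ca, prev_c = n1, ca, c
    res_atoms = [(n1, ca, c)]
    for i in range(2, n_residues + 1):
        psi = psis[i - 2]
        n_new = _place(coords[prev_n], coords[prev_ca], coords[prev_c],
                       _B["C-N"], _A["CA-C-N"], psi)
        o_prev = _place(coords[prev_n], coords[prev_ca], coords[prev_c],
                        _B["C=O"], _A["CA-C=O"], psi + 180.0)
        ni = add("N", n_new, i, prev_c)
        oi = add("O", o_prev, i - 1, prev_c)
        ca_new = _place(coords[prev_ca], coords[prev_c], coords[ni],
                        _B["N-CA"], _A["C-N-CA"], 180.0)  # ω trans
        cai = add("C", ca_new, i, ni)
        h_n = _place(coords[oi], coords[prev_c], coords[ni],
                     _B["N-H"], _A["C-N-H"], 180.0)  # amide H anti to O
        add("H", h_n, i, ni)
        c_new = _place(coords[prev_c], coords[ni], coords[cai],
                       _B["CA-C"], _A["N-CA-C"], phis[i - 1])
        ci = add("C", c_new, i, cai)
        _decorate_ca(elements, coords, bonds, labels, i - 1, *res_atoms[-1])
        res_atoms.append((ni, cai, ci))
        prev_n, prev_ca, prev_c = ni, cai, ci

    # C-terminal carboxyl: hydroxyl O continues the backbone at ψ_C
    psi_c = psis[-1]
    ox = _place(coords[prev_n], coords[prev_ca], coords[prev_c],
                _B["C-OX"], _A["CA-C-OX"], psi_c)
    o2 = _place(coords[prev_n], coords[prev_ca], coords[prev_c],
                _B["C=O"], _A["CA-C=O"], psi_c + 180.0)
    oxi = add("O", ox, n_residues, prev_c)
    add("O", o2, n_residues, prev_c)
    h_ox = _place(coords[prev_ca], coords[prev_c], coords[oxi],
                  _B["O-H"], _A["C-O-H"], 180.0)
    add("H", h_ox, n_residues, oxi)
    _decorate_ca(elements, coords, bonds, labels, n_residues, *res_atoms[-1])

    return MolecularStructure(elements, np.array(coords), bonds=bonds,
                              residue_labels=labels,
                              metadata={"torsions": torsions})


def _decorate_ca(elements, coords, bonds, labels, res_no, n_i, ca_i, c_i):
    """Attach Cβ (with methyl hydrogens) and Hα to a Cα."""
    u1 = coords[n_i] - coords[ca_i]
    u1 /= np.linalg.norm(u1)
    u2 = coords[c_i] - coords[ca_i]
    u2 /= np.linalg.norm(u2)
    w1 = -(u1 + u2)
    w1 /= np.linalg.norm(w1)
    w2 = np.cross(u1, u2)
    w2 /= np.linalg.norm(w2)
    cb_dir = w1 * np.cos(np.radians(35.0)) + w2 * np.sin(np.radians(35.0))
    ha_dir = w1 * np.cos(np.radians(35.0)) - w2 * np.sin(np.radians(35.0))

    def add(sym, pos, bond_to):
        elements.append(sym)
        coords.append(np.asarray(pos, float))
        labels.append(f"ALA{res_no}")
        bonds.append((bond_to, len(elements) - 1))
        return len(elements) - 1

    cb = add("C", coords[ca_i] + _B["CA-CB"] * cb_dir, ca_i)
    add("H", coords[ca_i] + _B["CA-HA"] * ha_dir, ca_i)
    for chi in (60.0, 180.0, 300.0):
        hb = _place(coords[n_i], coords[ca_i], coords[cb],
                    _B["CB-HB"], _A["CA-CB-HB"], chi)
        add("H", hb, cb)


# --------------------------------------------------------------------------
# density grids
# --------------------------------------------------------------------------

@dataclass
class BridgeSpec:
    """A density bridge between a donor hydrogen and an acceptor atom."""

    h_index: int
    acceptor_index: int
    rho_peak: float          # nm⁻³ total density at the bridge midpoint
    width: float = 0.30      # Å


def gen_density_grid(
    s: MolecularStructure,
    amplitudes: Optional[dict[str, float]] = None,
    widths: Optional[dict[str, float]] = None,
    bridges: Sequence[BridgeSpec] = (),
    spacing: float = 0.1,
    padding: float = 2.5,
) -> ScalarField:
    """Analytic electron-density stand-in: atom Gaussians plus bridges.

    ρ(r) = Σ_a A_a·exp(−|r−r_a|²/2w_a²) with amplitudes in nm⁻³, plus for
    each bridge a Gaussian midway between the hydrogen and the acceptor
    whose amplitude is chosen so the total midpoint density equals
    ``rho_peak`` — producing a density-bridge critical point with λ₂ < 0
    and vanishing reduced gradient, as a real H-bond does.
    """
    amplitudes = {"H": 500.0, "default": 2000.0, **(amplitudes or {})}
    widths = {"H": 0.15, "default": 0.20, **(widths or {})}
    lo = s.coords.min(axis=0) - padding
    hi = s.coords.max(axis=0) + padding
    counts = np.ceil((hi - lo) / spacing).astype(int) + 1
    axes = np.diag([spacing] * 3)
    grids = [lo[k] + spacing * np.arange(counts[k]) for k in range(3)]
    gx, gy, gz = np.meshgrid(*grids, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)

    def gaussian(center, amp, w):
        d2 = ((pts - center) ** 2).sum(axis=-1)
        return amp * np.exp(-0.5 * d2 / w ** 2)

    values = np.zeros(tuple(counts))
    for sym, pos in zip(s.elements, s.coords):
        amp = amplitudes.get(sym, amplitudes["default"])
        w = widths.get(sym, widths["default"])
        values += gaussian(pos, amp, w)

    for br in bridges:
        mid = 0.5 * (s.coords[br.h_index] + s.coords[br.acceptor_index])
        background = 0.0
        for sym, pos in zip(s.elements, s.coords):
            amp = amplitudes.get(sym, amplitudes["default"])
            w = widths.get(sym, widths["default"])
            background += amp * np.exp(
                -0.5 * ((mid - pos) ** 2).sum() / w ** 2)
        amp_bridge = br.rho_peak - background
        if amp_bridge <= 0:
            raise FixtureError(
                f"bridge peak {br.rho_peak} nm⁻³ below the atomic "
                f"background {background:.1f} nm⁻³"
            )
        values += gaussian(mid, amp_bridge, br.width)

    return ScalarField(lo, axes, values)


# --------------------------------------------------------------------------
# ion counts
# --------------------------------------------------------------------------

def gen_ion_counts(
    sigma: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    nus: np.ndarray,
    phi_tau: float | np.ndarray = 1.0,
    frag_fraction: float = 0.1,
    n_molecules: int = 100_000,
    seed: int = 0,
) -> tuple[list[IonCountRecord], np.ndarray]:
    """Generative twin of the IRMPD survival model.

    At each frequency, molecules survive the IR pulse with probability
    exp(−Φτ·σ(ν)); a ν-independent ``frag_fraction`` of ionized parents
    then fragments post-ionization.  Returns the count records and the
    generating σ values.
    """
    nus = np.atleast_1d(np.asarray(nus, float))
    sig = np.atleast_1d(sigma(nus) if callable(sigma)
                        else np.asarray(sigma, float))
    if sig.shape != nus.shape:
        raise ValidationError("sigma values do not match frequencies")
    if np.any(sig < 0):
        raise ValidationError("generating cross-sections must be >= 0")
    if not 0 <= frag_fraction < 1:
        raise ValidationError("fragmentation fraction must be in [0, 1)")
    phi = np.broadcast_to(np.asarray(phi_tau, float), nus.shape)
    rng = np.random.default_rng(seed)
    records = []
    for nu, s_val, ph in zip(nus, sig, phi):
        survive = np.exp(-ph * s_val)
        p_on = rng.binomial(n_molecules, survive * (1.0 - frag_fraction))
        p_off = rng.binomial(n_molecules, 1.0 - frag_fraction)
        records.append(IonCountRecord(
            nu=float(nu),
            p_on=int(p_on), f_on=int(n_molecules - p_on),
            p_off=int(p_off), f_off=int(n_molecules - p_off),
            phi_tau=float(ph),
        ))
    return records, sig
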