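"""Core molecular domain types: structures, grids, trajectories, spectra.

Coordinates are Cartesian Å throughout.  Electron densities are canonically
nm⁻³ (the unit in which the H-bond thresholds are stated); dipoles are Debye.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .errors import PeptideStructureError, ValidationError

# Covalent radii (Å), Cordero consensus values except H, which uses the
# traditional 0.37 Å so that H2 (0.74 Å) bonds at scale 1.15; doubles as
# the set of recognised element symbols.
COVALENT_RADII: dict[str, float] = {
    "H": 0.37, "He": 0.28,
    "Li": 1.28, "Be": 0.96, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66,
    "F": 0.57, "Ne": 0.58,
    "Na": 1.66, "Mg": 1.41, "Al": 1.21, "Si": 1.11, "P": 1.07, "S": 1.05,
    "Cl": 1.02, "Ar": 1.06,
    "K": 2.03, "Ca": 1.76, "Fe": 1.32, "Co": 1.26, "Ni": 1.24, "Cu": 1.32,
    "Zn": 1.22, "Br": 1.20, "Kr": 1.16, "I": 1.39, "Xe": 1.40,
}

#: Standard atomic masses (amu) for the elements above that appear in peptides.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "C": 12.011, "N": 14.007, "O": 15.999,
    "F": 18.998, "Na": 22.990, "P": 30.974, "S": 32.06, "Cl": 35.45,
}

#: Minimum allowed interatomic distance before bond perception refuses (Å).
MIN_ATOM_SEPARATION = 0.4


@dataclass
class MolecularStructure:
    """A molecule: element symbols, coordinates (Å), covalent bonds.

    Bonds are undirected index pairs; ``residue_labels`` (e.g. from PDB)
    are optional and parallel to the atom list.
    """

    elements: list[str]
    coords: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)
    residue_labels: Optional[list[str]] = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.elements), 3):
            raise ValidationError(
                f"coords shape {self.coords.shape} does not match "
                f"{len(self.elements)} atoms"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("non-finite coordinates")
        for sym in self.elements:
            if sym not in COVALENT_RADII:
                raise ValidationError(f"unknown element symbol {sym!r}")
        n = len(self.elements)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n and i != j):
                raise ValidationError(f"bond ({i},{j}) references invalid atoms")
        if self.residue_labels is not None and len(self.residue_labels) != n:
            raise ValidationError("residue_labels length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return sorted(out)


def perceive_bonds(s: MolecularStructure, scale: float = 1.15) -> MolecularStructure:
    """Assign covalent bonds by the sum-of-covalent-radii criterion.

    Atoms i, j are bonded iff ``d(i,j) <= scale * (r_cov(i) + r_cov(j))``.
    Returns a new structure; raises if any two atoms are closer than
    ``MIN_ATOM_SEPARATION`` (overlapping atoms make topology meaningless).
    """
    radii = np.array([COVALENT_RADII[e] for e in s.elements])
    diff = s.coords[:, None, :] - s.coords[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(s.n_atoms, k=1)
    if s.n_atoms > 1 and dist[iu].min() < MIN_ATOM_SEPARATION:
        raise ValidationError(
            f"overlapping atoms: minimum separation {dist[iu].min():.3f} Å"
        )
    cutoff = scale * (radii[:, None] + radii[None, :])
    bonded = (dist <= cutoff) & (dist > 0)
    bonds = [(int(i), int(j)) for i, j in zip(*np.nonzero(np.triu(bonded, k=1)))]
    return replace(s, bonds=bonds)


@dataclass
class ResidueAtoms:
    """Atom indices of one peptide residue (N→C ordering)."""

    n: int
    ca: int
    c: int
    o: int
    h_n: Optional[int] = None  # amide H; None for the N-terminal residue
    cb: Optional[int] = None   # side-chain Cβ; None for glycine


@dataclass
class BackboneAnnotation:
    """Peptide backbone: residues N→C plus terminal functional groups."""

    residues: list[ResidueAtoms]
    n_term_h: list[int]                      # amine hydrogens on residue 1's N
    c_term: tuple[int, int, int, int]        # (C, =O, -O(H), H) of the COOH

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def residue_of(self, atom: int) -> Optional[int]:
        """1-based residue index owning ``atom`` (terminal atoms included)."""
        for r, res in enumerate(self.residues, start=1):
            if atom in (res.n, res.ca, res.c, res.o, res.h_n, res.cb):
                return r
        if atom in self.n_term_h:
            return 1
        if atom in self.c_term:
            return self.n_residues
        return None


def annotate_backbone(s: MolecularStructure) -> BackboneAnnotation:
    """Identify the peptide backbone of a linear peptide with free termini.

    Walks from the C-terminal carboxyl (a carbon bearing two oxygens, one
    hydroxylic) back along C(=O)–N peptide links to the N-terminal amine.
    """
    if not s.bonds:
        raise PeptideStructureError("bonds not perceived")

    def elem(i: int) -> str:
        return s.elements[i]

    # --- locate the carboxyl carbon -------------------------------------
    carboxyl = None
    for i in range(s.n_atoms):
        if elem(i) != "C":
            continue
        oxy = [j for j in s.neighbors(i) if elem(j) == "O"]
        if len(oxy) != 2:
            continue
        hydroxyl = [o for o in oxy if any(elem(k) == "H" for k in s.neighbors(o))]
        if len(hydroxyl) == 1:
            carbonyl_o = next(o for o in oxy if o != hydroxyl[0])
            oh_h = next(k for k in s.neighbors(hydroxyl[0]) if elem(k) == "H")
            carboxyl = (i, carbonyl_o, hydroxyl[0], oh_h)
            break
    if carboxyl is None:
        raise PeptideStructureError("no COOH group found")

    c_term_c = carboxyl[0]
    ca = [j for j in s.neighbors(c_term_c) if elem(j) == "C"]
    if len(ca) != 1:
        raise PeptideStructureError("carboxyl carbon lacks a unique Cα")

    # --- walk N-ward ----------------------------------------------------
    residues_rev: list[ResidueAtoms] = []
    cur_c, cur_ca = c_term_c, ca[0]
    while True:
        nn = [j for j in s.neighbors(cur_ca) if elem(j) == "N"]
        if len(nn) != 1:
            raise PeptideStructureError("Cα lacks a unique backbone N")
        cur_n = nn[0]
        carbonyl_o = next(
            (j for j in s.neighbors(cur_c) if elem(j) == "O"), None
        ) if cur_c != c_term_c else carboxyl[1]
        if carbonyl_o is None:
            raise PeptideStructureError("backbone carbonyl O missing")
        cb = next(
            (j for j in s.neighbors(cur_ca)
             if elem(j) == "C" and j != cur_c), None
        )
        n_hydrogens = [j for j in s.neighbors(cur_n) if elem(j) == "H"]
        # preceding residue's carbonyl carbon, if any
        prev_c = next(
            (j for j in s.neighbors(cur_n)
             if elem(j) == "C" and j != cur_ca
             and any(elem(k) == "O" for k in s.neighbors(j))),
            None,
        )
        if prev_c is not None:
            if len(n_hydrogens) != 1:
                raise PeptideStructureError("amide N without exactly one H")
            residues_rev.append(
                ResidueAtoms(cur_n, cur_ca, cur_c, carbonyl_o,
                             h_n=n_hydrogens[0], cb=cb)
            )
            cur_c = prev_c
            next_ca = [j for j in s.neighbors(prev_c)
                       if elem(j) == "C" and j != cur_ca]
            if len(next_ca) != 1:
                raise PeptideStructureError("peptide C lacks a unique Cα")
            cur_ca = next_ca[0]
        else:
            if len(n_hydrogens) < 2:
                raise PeptideStructureError("no N-terminal amine found")
            residues_rev.append(
                ResidueAtoms(cur_n, cur_ca, cur_c, carbonyl_o, h_n=None, cb=cb)
            )
            n_term_h = sorted(n_hydrogens)
            break

    return BackboneAnnotation(
        residues=list(reversed(residues_rev)),
        n_term_h=n_term_h,
        c_term=carboxyl,
    )


@dataclass
class ScalarField:
    """A scalar grid (electron density, nm⁻³) on a parallelepiped lattice."""

    origin: np.ndarray          # (3,) Å
    axes: np.ndarray            # (3,3); row k is the step vector of axis k, Å
    values: np.ndarray          # (n0, n1, n2)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValidationError("values must be a 3-D array")
        if abs(np.linalg.det(self.axes)) < 1e-12:
            raise ValidationError("axis vectors are linearly dependent")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def fractional(self, points: np.ndarray) -> np.ndarray:
        """Cartesian points (Å) → continuous grid-index coordinates."""
        return (np.atleast_2d(points) - self.origin) @ np.linalg.inv(self.axes)


@dataclass
class DipoleTrajectory:
    """Uniformly sampled dipole series: Δt (fs) and μ(t) (Debye, shape (n,3))."""

    dt_fs: float
    mu: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.dt_fs <= 0:
            raise ValidationError("time step must be positive")
        if self.mu.ndim != 2 or self.mu.shape[1] != 3 or self.mu.shape[0] < 2:
            raise ValidationError("dipole series must be (n>=2, 3)")

    @property
    def n_samples(self) -> int:
        return self.mu.shape[0]

    @property
    def duration_fs(self) -> float:
        return (self.n_samples - 1) * self.dt_fs

    @property
    def times_fs(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_fs


@dataclass
class StickSpectrum:
    """Discrete IR bands: frequencies (cm⁻¹) and integrated intensities."""

    frequencies: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, float))
        self.intensities = np.atleast_1d(np.asarray(self.intensities, float))
        if self.frequencies.shape != self.intensities.shape:
            raise ValidationError("frequency/intensity length mismatch")
        if self.frequencies.size and np.any(self.frequencies <= 0):
            raise ValidationError("band frequencies must be positive")
        if self.intensities.size and np.any(self.intensities < 0):
            raise ValidationError("band intensities must be non-negative")

    @property
    def n_bands(self) -> int:
        return self.frequencies.size


@dataclass
class Spectrum:
    """Continuous spectrum on a strictly increasing uniform cm⁻¹ grid."""

    grid: np.ndarray
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape or self.grid.ndim != 1:
            raise ValidationError("grid/values must be matching 1-D arrays")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("non-finite spectrum values")
        if self.grid.size >= 2:
            d = np.diff(self.grid)
            if np.any(d <= 0):
                raise ValidationError("grid must be strictly increasing")
            if not np.allclose(d, d[0], rtol=1e-6, atol=1e-9 * abs(d[0])):
                raise ValidationError("grid must be uniform")

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass
class IonCountRecord:
    """One IRMPD measurement point: IR-on and IR-off ion counts at ν."""

    nu: float          # cm⁻¹
    p_on: float        # parent ion counts, IR on
    f_on: float        # summed fragment counts, IR on
    p_off: float
    f_off: float
    phi_tau: float     # macropulse photon measure, arbitrary units > 0

    def __post_init__(self) -> None:
        if self.nu <= 0:
            raise ValidationError("frequency must be positive")
        if min(self.p_on, self.f_on, self.p_off, self.f_off) < 0:
            raise ValidationError("counts must be non-negative")
        if self.p_on + self.f_on <= 0 or self.p_off + self.f_off <= 0:
            raise ValidationError("each shutter state needs at least one ion")
        if self.phi_tau <= 0:
            raise ValidationError("photon measure must be positive")
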