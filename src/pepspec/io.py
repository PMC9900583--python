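"""Readers and writers for the pipeline's text formats.

XYZ and Gaussian-cube files are parsed directly (both are simple
line-oriented formats); PDB goes through biotite.  Columnar files (dipole
series, stick spectra, spectra, Gibbs tables, ion counts) are whitespace- or
comma-delimited text with ``#`` comments.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .constants import AU_DENSITY_TO_NM3, BOHR_TO_ANG
from .errors import ParseError, ValidationError
from .structures import (
    COVALENT_RADII,
    DipoleTrajectory,
    IonCountRecord,
    MolecularStructure,
    ScalarField,
    Spectrum,
    StickSpectrum,
)

PathLike = Union[str, Path]

_ATOMIC_NUMBERS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18, "K": 19, "Ca": 20, "Fe": 26, "Co": 27,
    "Ni": 28, "Cu": 29, "Zn": 30, "Br": 35, "Kr": 36, "I": 53, "Xe": 54,
}
_SYMBOLS = {z: sym for sym, z in _ATOMIC_NUMBERS.items()}


# --------------------------------------------------------------------------
# molecular structures
# --------------------------------------------------------------------------

def read_structure(path: PathLike, format: str | None = None) -> MolecularStructure:
    """Read a molecular structure from an XYZ or PDB file.

    ``format`` defaults to the file suffix.  Bonds are left empty; call
    :func:`pepspec.structures.perceive_bonds` afterwards.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        return _read_xyz(path)
    if fmt == "pdb":
        return _read_pdb(path)
    raise ValidationError(f"unknown structure format {fmt!r}")


def write_structure(s: MolecularStructure, path: PathLike,
                    format: str | None = None, comment: str = "") -> None:
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        _write_xyz(s, path, comment)
    elif fmt == "pdb":
        _write_pdb(s, path)
    else:
        raise ValidationError(f"unknown structure format {fmt!r}")


def _read_xyz(path: Path) -> MolecularStructure:
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}:1: expected an atom count") from None
    if len(lines) < n + 2:
        raise ParseError(f"{path}: truncated after line {len(lines)}")
    elements, coords = [], []
    for k in range(n):
        ln = lines[2 + k].split()
        if len(ln) < 4:
            raise ParseError(f"{path}:{3 + k}: expected 'El x y z'")
        sym = ln[0].capitalize()
        if sym not in COVALENT_RADII:
            raise ValidationError(f"{path}:{3 + k}: unknown element {ln[0]!r}")
        try:
            coords.append([float(v) for v in ln[1:4]])
        except ValueError:
            raise ParseError(f"{path}:{3 + k}: bad coordinate") from None
        elements.append(sym)
    return MolecularStructure(elements, np.array(coords))


def _write_xyz(s: MolecularStructure, path: Path, comment: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{s.n_atoms}\n{comment}\n")
        for sym, (x, y, z) in zip(s.elements, s.coords):
            fh.write(f"{sym:2s} {x:15.6f} {y:15.6f} {z:15.6f}\n")


def _read_pdb(path: Path) -> MolecularStructure:
    import biotite.structure.io.pdb as pdb

    try:
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
    except Exception as exc:  # biotite raises several parse-error types
        raise ParseError(f"{path}: {exc}") from exc
    elements = [e.capitalize() for e in arr.element]
    for sym in elements:
        if sym not in COVALENT_RADII:
            raise ValidationError(f"{path}: unknown element {sym!r}")
    labels = [f"{rn}{ri}" for rn, ri in zip(arr.res_name, arr.res_id)]
    return MolecularStructure(elements, np.asarray(arr.coord, float),
                              residue_labels=labels)


def _write_pdb(s: MolecularStructure, path: Path) -> None:
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    arr = struc.AtomArray(s.n_atoms)
    arr.coord = np.asarray(s.coords, np.float32)
    arr.element = np.array([e.upper() for e in s.elements])
    arr.atom_name = np.array(
        [f"{e.upper()}{i + 1}" for i, e in enumerate(s.elements)]
    )
    if s.residue_labels is not None:
        names, ids = [], []
        seen: dict[str, int] = {}
        for lab in s.residue_labels:
            if lab not in seen:
                seen[lab] = len(seen) + 1
            names.append(lab[:3].upper())
            ids.append(seen[lab])
        arr.res_name = np.array(names)
        arr.res_id = np.array(ids)
    else:
        arr.res_name = np.array(["UNK"] * s.n_atoms)
        arr.res_id = np.ones(s.n_atoms, int)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))


# --------------------------------------------------------------------------
# density grids (Gaussian cube)
# --------------------------------------------------------------------------

def read_density_grid(path: PathLike, density_unit: str = "nm^-3") -> ScalarField:
    """Read a Gaussian cube file into a :class:`ScalarField` (Å, nm⁻³).

    Cube axes/origin are in bohr by convention (positive voxel counts).
    ``density_unit`` declares the unit of the stored values: ``"nm^-3"`` or
    ``"au"`` (atomic units, converted by 6748.33 nm⁻³ per a.u.).
    """
    if density_unit not in ("nm^-3", "au"):
        raise ValidationError(f"unknown density unit {density_unit!r}")
    lines = Path(path).read_text().split("\n")
    try:
        hdr = lines[2].split()
        natoms = int(hdr[0])
        origin = np.array([float(v) for v in hdr[1:4]]) * BOHR_TO_ANG
        counts, axes = [], []
        for k in range(3):
            f = lines[3 + k].split()
            counts.append(abs(int(f[0])))
            scale = BOHR_TO_ANG if int(f[0]) > 0 else 1.0
            axes.append([float(v) * scale for v in f[1:4]])
        data_start = 6 + abs(natoms)
        values = np.fromstring(" ".join(lines[data_start:]), sep=" ")
    except (ValueError, IndexError) as exc:
        raise ParseError(f"{path}: malformed cube header/data: {exc}") from exc
    n0, n1, n2 = counts
    if values.size != n0 * n1 * n2:
        raise ParseError(
            f"{path}: {values.size} values for a {n0}x{n1}x{n2} grid"
        )
    if density_unit == "au":
        values = values * AU_DENSITY_TO_NM3
    return ScalarField(origin, np.array(axes), values.reshape(n0, n1, n2))


def write_density_grid(f: ScalarField, path: PathLike,
                       structure: MolecularStructure | None = None) -> None:
    """Write a cube file (axes in bohr, densities as stored: nm⁻³)."""
    n0, n1, n2 = f.shape
    atoms = structure.elements if structure is not None else []
    coords = structure.coords if structure is not None else np.zeros((0, 3))
    with open(path, "w") as fh:
        fh.write("pepspec density grid\nvalues in nm^-3\n")
        ox, oy, oz = f.origin / BOHR_TO_ANG
        fh.write(f"{max(len(atoms), 1):5d} {ox:12.6f} {oy:12.6f} {oz:12.6f}\n")
        for n, ax in zip((n0, n1, n2), f.axes / BOHR_TO_ANG):
            fh.write(f"{n:5d} {ax[0]:12.6f} {ax[1]:12.6f} {ax[2]:12.6f}\n")
        if atoms:
            for sym, (x, y, z) in zip(atoms, coords / BOHR_TO_ANG):
                z_num = _ATOMIC_NUMBERS[sym]
                fh.write(f"{z_num:5d} {0.0:12.6f} {x:12.6f} {y:12.6f} {z:12.6f}\n")
        else:
            fh.write(f"{1:5d} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f} {0.0:12.6f}\n")
        flat = f.values.reshape(-1)
        for k in range(0, flat.size, 6):
            fh.write(" ".join(f"{v: .6e}" for v in flat[k:k + 6]) + "\n")


# --------------------------------------------------------------------------
# columnar files
# --------------------------------------------------------------------------

def _load_columns(path: PathLike, n_min: int) -> np.ndarray:
    try:
        data = np.atleast_2d(np.loadtxt(path, comments="#", delimiter=None))
    except ValueError:
        try:
            data = np.atleast_2d(np.loadtxt(path, comments="#", delimiter=","))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if data.size == 0:
        raise ParseError(f"{path}: no data rows")
    if data.shape[1] < n_min:
        raise ParseError(f"{path}: expected >= {n_min} columns")
    return data


def read_dipole_trajectory(path: PathLike) -> DipoleTrajectory:
    """Read columns (t/fs, μx, μy, μz); the sampling must be uniform."""
    data = _load_columns(path, 4)
    t = data[:, 0]
    if t.size < 2:
        raise ValidationError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6,
                                          atol=1e-9 * abs(dt[0])):
        raise ValidationError(f"{path}: non-uniform time sampling")
    return DipoleTrajectory(float(dt[0]), data[:, 1:4])


def write_dipole_trajectory(traj: DipoleTrajectory, path: PathLike) -> None:
    data = np.column_stack([traj.times_fs, traj.mu])
    np.savetxt(path, data, header="t_fs mu_x mu_y mu_z (Debye)")


def read_stick_spectrum(path: PathLike) -> StickSpectrum:
    """Read columns (ν/cm⁻¹, intensity)."""
    data = _load_columns(path, 2)
    return StickSpectrum(data[:, 0], data[:, 1])


def write_stick_spectrum(s: StickSpectrum, path: PathLike) -> None:
    np.savetxt(path, np.column_stack([s.frequencies, s.intensities]),
               header="nu_cm-1 intensity")


def read_spectrum(path: PathLike, provenance: str = "") -> Spectrum:
    data = _load_columns(path, 2)
    return Spectrum(data[:, 0], data[:, 1], provenance=provenance)


def write_spectrum(s: Spectrum, path: PathLike) -> None:
    np.savetxt(path, np.column_stack([s.grid, s.values]),
               header=f"nu_cm-1 value  [{s.provenance}]")


def read_ion_counts(path: PathLike) -> list[IonCountRecord]:
    """Read columns (ν, P_on, F_on, P_off, F_off, Φτ)."""
    data = _load_columns(path, 6)
    return [IonCountRecord(*row[:6]) for row in data]


def write_ion_counts(records: list[IonCountRecord], path: PathLike) -> None:
    rows = [[r.nu, r.p_on, r.f_on, r.p_off, r.f_off, r.phi_tau]
            for r in records]
    np.savetxt(path, rows, header="nu_cm-1 P_on F_on P_off F_off phi_tau")


def read_gibbs_table(path: PathLike) -> pd.DataFrame:
    """Read a per-conformer Gibbs table: columns ``name`` (optional), ``G``.

    Plain two-column text (name, kcal/mol) or a single energy column.
    """
    rows = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#")[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            g = float(parts[-1])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: bad energy value") from None
        name = parts[0] if len(parts) > 1 else f"conf{len(rows) + 1}"
        rows.append((name, g))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return pd.DataFrame(rows, columns=["name", "gibbs_kcal"])
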