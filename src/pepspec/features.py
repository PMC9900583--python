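"""Conformer structural features.

Backbone torsions and their four-letter classification (cis/gauche/
anticlinal/trans), hydrogen-bond assignment — either from an electron
density grid via the NCI criteria (density threshold, reduced density
gradient, sign of the Hessian's second eigenvalue) or from a geometric
distance/angle fallback — pseudo-ring orders (C5, C7 = γ-turn,
C10 = β-turn), descriptive conformer names, and Boltzmann abundances
from Gibbs energies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .constants import KB_KCAL_PER_MOL_K
from .errors import (
    CoverageError,
    DegenerateGeometryError,
    ValidationError,
)
from .structures import BackboneAnnotation, MolecularStructure, ScalarField

# defaults for the geometric H-bond fallback (common literature cutoffs)
GEOMETRIC_DMAX_ANG = 2.5
GEOMETRIC_THETA_MIN_DEG = 120.0
# default NCI thresholds: electron density in nm⁻³, reduced gradient unitless
NCI_RHO_HBOND_NM3 = 18.0
NCI_RHO_WEAK_NM3 = 15.0
NCI_S_MAX = 0.5


# --------------------------------------------------------------------------
# torsions
# --------------------------------------------------------------------------

def dihedral(p1, p2, p3, p4) -> float:
    """Signed dihedral angle (degrees) of four points, IUPAC convention.

    Positive means the far bond is rotated clockwise when sighting from p2
    toward p3; the result lies in (−180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("three consecutive points are collinear")
    b2h = b2 / np.linalg.norm(b2)
    theta = np.degrees(np.arctan2(np.dot(np.cross(n1, n2), b2h),
                                  np.dot(n1, n2)))
    return 180.0 if np.isclose(theta, -180.0) else float(theta)


def classify_angle(theta: float) -> str:
    """Classify a torsion into C (cis), G (gauche), A (anticlinal), T (trans).

    Symmetric 60°-wide sectors by absolute value:
    |θ| < 30 → C, 30 ≤ |θ| < 90 → G, 90 ≤ |θ| < 150 → A, |θ| ≥ 150 → T.
    """
    if not -180.0 < theta <= 180.0 + 1e-9:
        raise ValidationError(f"angle {theta} outside (-180, 180]")
    a = abs(theta)
    if a < 30.0:
        return "C"
    if a < 90.0:
        return "G"
    if a < 150.0:
        return "A"
    return "T"


@dataclass
class TorsionSet:
    """The informative backbone torsions of a linear peptide.

    ``angles`` holds, N-terminus first: φ_N, ψ1, φ2, ψ2, …, φ_n, ψ_C
    (2·n_residues values for n residues).  ω and χ torsions, when computed,
    are retained in ``metadata``.
    """

    angles: list[float]
    labels: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.angles) != len(self.labels):
            raise ValidationError("angles/labels length mismatch")
        for a in self.angles:
            if not -180.0 < a <= 180.0 + 1e-9:
                raise ValidationError(f"torsion {a} outside (-180, 180]")

    @property
    def n_angles(self) -> int:
        return len(self.angles)


def compute_torsions(s: MolecularStructure,
                     backbone: BackboneAnnotation) -> TorsionSet:
    """Compute the informative φ/ψ torsions of an annotated peptide.

    φ_N extends the backbone to the centroid of the N-terminal amine
    hydrogens; ψ_C extends it to the carboxyl hydroxyl oxygen.
    """
    res = backbone.residues
    n = len(res)
    x = s.coords
    angles: list[float] = []
    labels: list[str] = []

    amine_centroid = x[backbone.n_term_h].mean(axis=0)
    angles.append(dihedral(amine_centroid, x[res[0].n], x[res[0].ca],
                           x[res[0].c]))
    labels.append("phi_N")

    for i in range(n):
        if i > 0:
            angles.append(dihedral(x[res[i - 1].c], x[res[i].n],
                                   x[res[i].ca], x[res[i].c]))
            labels.append(f"phi{i + 1}")
        if i < n - 1:
            angles.append(dihedral(x[res[i].n], x[res[i].ca],
                                   x[res[i].c], x[res[i + 1].n]))
            labels.append(f"psi{i + 1}")

    hydroxyl_o = backbone.c_term[2]
    angles.append(dihedral(x[res[-1].n], x[res[-1].ca], x[res[-1].c],
                           x[hydroxyl_o]))
    labels.append("psi_C")

    omegas = {}
    for i in range(1, n):
        omegas[f"omega{i}"] = dihedral(x[res[i - 1].ca], x[res[i - 1].c],
                                       x[res[i].n], x[res[i].ca])
    return TorsionSet(angles, labels, metadata={"omega": omegas})


# --------------------------------------------------------------------------
# hydrogen bonds
# --------------------------------------------------------------------------

@dataclass
class HBond:
    """A donor–H···acceptor contact.

    ``strength`` is the maximum electron density (nm⁻³) over qualifying NCI
    points (None for geometric detection); ``ring_order`` the size of the
    pseudo-ring closed through the covalent graph (None if no path).
    """

    donor: int
    hydrogen: int
    acceptor: int
    strength: Optional[float] = None
    classification: str = "hbond"        # "hbond" | "weak-interaction"
    ring_order: Optional[int] = None
    donor_residue: Optional[int] = None
    acceptor_residue: Optional[int] = None


def candidate_pairs(s: MolecularStructure,
                    d_candidate: float = 3.5) -> list[tuple[int, int, int]]:
    """(donor, H, acceptor) triplets worth testing: N/O–H with an N/O
    acceptor within ``d_candidate`` Å of the hydrogen."""
    if not s.bonds:
        raise ValidationError("bonds not perceived")
    out = []
    for h in range(s.n_atoms):
        if s.elements[h] != "H":
            continue
        heavies = [j for j in s.neighbors(h) if s.elements[j] in ("N", "O")]
        if len(heavies) != 1:
            continue
        d = heavies[0]
        for a in range(s.n_atoms):
            if a in (d, h) or s.elements[a] not in ("N", "O"):
                continue
            if a in s.neighbors(h) or a in s.neighbors(d):
                continue
            if np.linalg.norm(s.coords[h] - s.coords[a]) <= d_candidate:
                out.append((d, h, a))
    return out


def detect_hbonds_geometric(
    s: MolecularStructure,
    d_max: float = GEOMETRIC_DMAX_ANG,
    theta_min: float = GEOMETRIC_THETA_MIN_DEG,
) -> list[HBond]:
    """Distance/angle H-bond assignment: H···A ≤ d_max and D–H···A ≥ θ_min."""
    bonds = []
    for d, h, a in candidate_pairs(s, d_candidate=max(d_max, 3.5)):
        r_ha = np.linalg.norm(s.coords[h] - s.coords[a])
        if r_ha > d_max:
            continue
        v1 = s.coords[d] - s.coords[h]
        v2 = s.coords[a] - s.coords[h]
        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        if angle >= theta_min:
            hb = HBond(d, h, a)
            hb.ring_order = ring_order(hb, s)
            bonds.append(hb)
    return bonds


def _field_derivative_tables(field: ScalarField):
    """ρ, |∇ρ| and Hessian second-eigenvalue interpolators on the grid.

    Derivatives are central finite differences with one-grid-spacing steps;
    requires orthogonal axes (the reduced gradient and λ₂ are then computed
    in the grid frame, in which both are invariant).
    """
    A = field.axes
    gram = A @ A.T
    if not np.allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8):
        raise ValidationError("NCI analysis requires orthogonal grid axes")
    h = np.linalg.norm(A, axis=1)
    rho = field.values
    g0, g1, g2 = np.gradient(rho, h[0], h[1], h[2])
    h00, h01, h02 = np.gradient(g0, h[0], h[1], h[2])
    _, h11, h12 = np.gradient(g1, h[0], h[1], h[2])
    _, _, h22 = np.gradient(g2, h[0], h[1], h[2])

    axes_idx = tuple(np.arange(n) for n in field.shape)

    def _interp(arr):
        return RegularGridInterpolator(axes_idx, arr, bounds_error=True)

    rho_i = _interp(rho)
    gi = [_interp(g) for g in (g0, g1, g2)]

    def grad_norm_at(frac_pts):
        # interpolate components, then take the norm: the magnitude has a
        # kink at critical points and must not be interpolated directly
        comps = np.stack([f(frac_pts) for f in gi], axis=-1)
        return np.linalg.norm(comps, axis=-1)

    def lam2_at(frac_pts):
        comps = [_interp(arr)(frac_pts)
                 for arr in (h00, h01, h02, h11, h12, h22)]
        H = np.empty((len(frac_pts), 3, 3))
        H[:, 0, 0], H[:, 0, 1], H[:, 0, 2] = comps[0], comps[1], comps[2]
        H[:, 1, 1], H[:, 1, 2], H[:, 2, 2] = comps[3], comps[4], comps[5]
        H[:, 1, 0], H[:, 2, 0], H[:, 2, 1] = comps[1], comps[2], comps[4]
        return np.linalg.eigvalsh(H)[:, 1]

    return rho_i, grad_norm_at, lam2_at


def reduced_density_gradient(rho: np.ndarray, grad_norm: np.ndarray) -> np.ndarray:
    """s = |∇ρ| / (2·(3π²)^{1/3}·ρ^{4/3}); dimensionless for any consistent
    length unit of ρ and ∇ρ (here nm⁻³ and nm⁻⁴ ≡ per-Å scaled)."""
    rho = np.maximum(np.asarray(rho, float), 1e-30)
    return np.asarray(grad_norm) / (2.0 * (3.0 * np.pi ** 2) ** (1.0 / 3.0)
                                    * rho ** (4.0 / 3.0))


def detect_hbonds_nci(
    s: MolecularStructure,
    density: ScalarField,
    rho_hbond: float = NCI_RHO_HBOND_NM3,
    rho_weak: float = NCI_RHO_WEAK_NM3,
    s_max: float = NCI_S_MAX,
    n_corridor: int = 41,
    nuclear_exclusion: float = 0.5,
    pairs: Optional[Sequence[tuple[int, int, int]]] = None,
) -> list[HBond]:
    """NCI-style H-bond assignment from an electron density grid.

    A candidate donor-H/acceptor pair is an H-bond if some point of the
    H···acceptor corridor satisfies ρ ≥ ``rho_hbond`` (nm⁻³), reduced
    density gradient ≤ ``s_max``, and second Hessian eigenvalue λ₂ ≤ 0;
    a weak interaction if the same holds with ``rho_weak`` ≤ ρ <
    ``rho_hbond``.  Strength is the maximum ρ over qualifying points.
    Corridor points within ``nuclear_exclusion`` Å of any nucleus are
    ignored (the NCI criteria characterise interstitial density bridges,
    not the nuclear/covalent high-density regions).
    """
    if pairs is None:
        pairs = candidate_pairs(s)
    rho_i, grad_i, lam2_at = _field_derivative_tables(density)
    # |∇ρ| from the grid is per Å; s uses nm-consistent units → per nm.
    grad_scale = 10.0

    bonds = []
    for d, h, a in pairs:
        t = np.linspace(0.0, 1.0, n_corridor)[:, None]
        seg = s.coords[h] * (1 - t) + s.coords[a] * t
        near = np.linalg.norm(
            seg[:, None, :] - s.coords[None, :, :], axis=-1
        ).min(axis=1) < nuclear_exclusion
        seg = seg[~near]
        if seg.size == 0:
            continue
        frac = density.fractional(seg)
        lo = -1e-9
        hi = np.array(density.shape) - 1 + 1e-9
        if np.any(frac < lo) or np.any(frac > hi):
            raise CoverageError(
                f"grid does not cover the H{h}···A{a} corridor"
            )
        rho = rho_i(frac)
        sval = reduced_density_gradient(rho, grad_i(frac) * grad_scale)
        lam2 = lam2_at(frac)
        ok = (sval <= s_max) & (lam2 <= 0.0)
        strong = ok & (rho >= rho_hbond)
        weak = ok & (rho >= rho_weak) & (rho < rho_hbond)
        if strong.any():
            cls, strength = "hbond", float(rho[strong].max())
        elif weak.any():
            cls, strength = "weak-interaction", float(rho[weak].max())
        else:
            continue
        hb = HBond(d, h, a, strength=strength, classification=cls)
        hb.ring_order = ring_order(hb, s)
        bonds.append(hb)
    return bonds


def ring_order(hb: HBond, s: MolecularStructure) -> Optional[int]:
    """Pseudo-ring order closed by an intramolecular H-bond.

    1 + the number of atoms on the shortest covalent path from the donor
    heavy atom to the acceptor (the +1 counts the bridging hydrogen):
    C5 for the intra-unit NH···O contact, 7 for a γ-turn (residues i, i+2),
    10 for a β-turn (i, i+3).  None if donor and acceptor are not
    covalently connected (intermolecular contact).
    """
    g = nx.Graph(s.bonds)
    g.add_nodes_from(range(s.n_atoms))
    try:
        path = nx.shortest_path(g, hb.donor, hb.acceptor)
    except (nx.NetworkXNoPath, nx.NodeNotFound):
        return None
    return 1 + len(path)


_TURN_BY_RING = {5: "C5", 7: "γ", 10: "β"}


def label_hbond_residues(hbonds: Sequence[HBond],
                         backbone: BackboneAnnotation) -> None:
    """Attach 1-based donor/acceptor residue indices in place."""
    for hb in hbonds:
        hb.donor_residue = backbone.residue_of(hb.donor)
        hb.acceptor_residue = backbone.residue_of(hb.acceptor)


def descriptive_name(torsions: TorsionSet,
                     hbonds: Sequence[HBond] = ()) -> str:
    """Ten-position conformer name, N-terminus leftmost.

    Each informative torsion is classified into C/G/A/T; contiguous
    positions whose central bonds lie on a detected turn's covalent ring
    path are replaced by a single bracketed token ``[β]``, ``[γ]`` or
    ``[C5]``.  Requires the 10 informative angles of a pentapeptide.
    """
    if torsions.n_angles != 10:
        raise ValidationError(
            f"expected 10 informative angles, got {torsions.n_angles}"
        )
    letters: list[str | None] = [classify_angle(a) for a in torsions.angles]

    replacements: list[tuple[int, int, str]] = []  # (start, stop, token)
    for hb in hbonds:
        label = _TURN_BY_RING.get(hb.ring_order or 0)
        if label is None or hb.donor_residue is None \
                or hb.acceptor_residue is None:
            continue
        i = min(hb.donor_residue, hb.acceptor_residue)
        if label == "C5":
            start, stop = 2 * (i - 1), 2 * (i - 1) + 2   # φ_i, ψ_i
        elif label == "γ":
            start, stop = 2 * i, 2 * i + 2               # φ_{i+1}, ψ_{i+1}
        else:  # β
            start, stop = 2 * i, 2 * i + 4               # φ/ψ of i+1, i+2
        replacements.append((start, stop, f"[{label}]"))

    taken = [False] * 10
    for start, stop, token in sorted(replacements):
        if stop > 10 or any(taken[start:stop]) \
                or any(v is None for v in letters[start:stop]):
            continue
        letters[start] = token
        for k in range(start + 1, stop):
            letters[k] = None
        for k in range(start, stop):
            taken[k] = True
    return "".join(v for v in letters if v is not None)


# --------------------------------------------------------------------------
# Boltzmann abundances
# --------------------------------------------------------------------------

@dataclass
class ConformerRecord:
    """A conformer with its Gibbs energy (kcal/mol) and derived attributes."""

    gibbs_kcal: float
    structure: Optional[MolecularStructure] = None
    name: str = ""
    rank: Optional[int] = None
    short_name: str = ""
    descriptive: str = ""
    abundance: Optional[float] = None


def rank_and_weight(records: Sequence[ConformerRecord],
                    temperature: float = 400.0) -> list[ConformerRecord]:
    """Rank conformers by Gibbs energy and assign Boltzmann abundances.

    abundance_i = exp(−(G_i − G_min)/k_BT) / Σ_j exp(−(G_j − G_min)/k_BT);
    ranks ascend with G, short names are "A1", "A2", … in rank order.
    Returns the records sorted by rank.
    """
    if not records:
        raise ValidationError("empty conformer set")
    if temperature <= 0:
        raise ValidationError("temperature must be positive")
    g = np.array([r.gibbs_kcal for r in records], float)
    w = np.exp(-(g - g.min()) / (KB_KCAL_PER_MOL_K * temperature))
    w /= w.sum()
    order = np.argsort(g, kind="stable")
    out = []
    for rank, idx in enumerate(order, start=1):
        r = records[idx]
        r.rank = rank
        r.short_name = f"A{rank}"
        r.abundance = float(w[idx])
        out.append(r)
    return out
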