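"""Conformer distance metric and conformer graphs.

The distance is the minimal root-sum-square of atom displacements
(MRSSAD): the minimum, over proper rigid motions and atom reindexings
within symmetry-equivalent orbits, of sqrt(Σ‖x_i − y_i‖²) = RMSD·√N.
Reflections are excluded so enantiomers stay at nonzero distance; all
atoms carry equal weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .structures import MolecularStructure, perceive_bonds


def rssad(a: MolecularStructure, b: MolecularStructure) -> float:
    """Root-sum-square of atom displacements at fixed correspondence (Å)."""
    if a.n_atoms != b.n_atoms:
        raise ValidationError("atom-count mismatch")
    if sorted(a.elements) != sorted(b.elements):
        raise ValidationError("element multisets differ")
    return float(np.sqrt(((a.coords - b.coords) ** 2).sum()))


def _kabsch_rotation(p: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimising Σ‖p_i − q_i R‖² for centered p, q."""
    h = q.T @ p
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    u[:, -1] *= d
    return u @ vt


def superpose(p: np.ndarray, q: np.ndarray) -> tuple[float, np.ndarray]:
    """Optimal proper-rigid-motion superposition of q onto p.

    Returns (root-sum-square displacement, transformed q).
    """
    p = np.asarray(p, float)
    q = np.asarray(q, float)
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    r = _kabsch_rotation(p - pc, q - qc)
    q_fit = (q - qc) @ r + pc
    return float(np.sqrt(((p - q_fit) ** 2).sum())), q_fit


def element_orbits(s: MolecularStructure) -> list[list[int]]:
    """Equivalence orbits of atoms under graph symmetry, refined by element.

    Iterative neighbourhood-signature (colour) refinement on the covalent
    graph: two atoms can only be exchanged if they have identical element
    and isomorphic covalent environments at every radius.
    """
    if not s.bonds:
        s = perceive_bonds(s)
    colors: list = list(s.elements)
    for _ in range(s.n_atoms + 1):
        new = [
            (colors[i], tuple(sorted(colors[j] for j in s.neighbors(i))))
            for i in range(s.n_atoms)
        ]
        canon = {sig: k for k, sig in enumerate(sorted(set(new)))}
        new_colors = [canon[sig] for sig in new]
        if _same_partition(colors, new_colors) \
                and _same_partition(new_colors, colors):
            break
        colors = new_colors
    orbits: dict = {}
    for i, c in enumerate(colors):
        orbits.setdefault(c, []).append(i)
    return sorted(orbits.values())


def _same_partition(a: Sequence, b: Sequence) -> bool:
    seen: dict = {}
    for x, y in zip(a, b):
        if seen.setdefault(x, y) != y:
            return False
    return True


def mrssad(
    a: MolecularStructure,
    b: MolecularStructure,
    equivalence: Optional[Sequence[Sequence[int]]] = None,
    n_starts: int = 10,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> float:
    """Minimal root-sum-square of atom displacements (Å).

    Alternates optimal proper-rotation superposition (Kabsch) with optimal
    within-orbit assignment (Hungarian) until a fixed point, taking the
    best over ``n_starts`` restarts: the identity correspondence plus
    random initial rotations, each followed by an optimal within-orbit
    assignment to seed the alternation.  ``equivalence`` partitions atom
    indices into interchangeable orbits; by default the orbits of the
    covalent-graph automorphism refinement of structure ``a``.
    """
    if a.n_atoms != b.n_atoms:
        raise ValidationError("atom-count mismatch")
    if sorted(a.elements) != sorted(b.elements):
        raise ValidationError("element multisets differ")
    orbits = [list(o) for o in (equivalence or element_orbits(a))]
    covered = sorted(i for o in orbits for i in o)
    if covered != list(range(a.n_atoms)):
        raise ValidationError("equivalence must partition all atom indices")
    for o in orbits:
        if len({a.elements[i] for i in o}) != 1:
            raise ValidationError("an orbit mixes elements")
        if len({b.elements[i] for i in o}) != 1 \
                or b.elements[o[0]] != a.elements[o[0]]:
            raise ValidationError("orbit elements incompatible between A and B")

    rng = np.random.default_rng(seed)
    p = a.coords - a.coords.mean(axis=0)
    q0 = b.coords - b.coords.mean(axis=0)

    def _assign(q_rot: np.ndarray) -> np.ndarray:
        perm = np.arange(a.n_atoms)
        for o in orbits:
            if len(o) == 1:
                continue
            o = np.asarray(o)
            cost = ((p[o][:, None, :] - q_rot[o][None, :, :]) ** 2).sum(-1)
            rows, cols = linear_sum_assignment(cost)
            perm[o[rows]] = o[cols]
        return perm

    def _random_rotation() -> np.ndarray:
        q = rng.standard_normal(4)
        q /= np.linalg.norm(q)
        w, x_, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x_ * y - w * z), 2 * (x_ * z + w * y)],
            [2 * (x_ * y + w * z), 1 - 2 * (x_ * x_ + z * z), 2 * (y * z - w * x_)],
            [2 * (x_ * z - w * y), 2 * (y * z + w * x_), 1 - 2 * (x_ * x_ + y * y)],
        ])

    best = np.inf
    for start in range(max(1, n_starts)):
        if start == 0:
            perm = np.arange(a.n_atoms)
        else:
            # random orientation, then best within-orbit assignment
            perm = _assign(q0 @ _random_rotation().T)
        prev = np.inf
        for _ in range(max_iter):
            q = q0[perm]
            r = _kabsch_rotation(p, q - q.mean(axis=0))
            q_fit = (q - q.mean(axis=0)) @ r
            val = float(np.sqrt(((p - q_fit) ** 2).sum()))
            # reassign within each orbit against the fitted geometry
            q_all = (q0 - q0[perm].mean(axis=0)) @ r
            new_perm = perm.copy()
            for o in orbits:
                if len(o) == 1:
                    continue
                o = np.asarray(o)
                cost = ((p[o][:, None, :] - q_all[o][None, :, :]) ** 2).sum(-1)
                rows, cols = linear_sum_assignment(cost)
                new_perm[o[rows]] = o[cols]
            if np.array_equal(new_perm, perm) or prev - val < tol:
                break
            perm, prev = new_perm, val
        best = min(best, val)
    return best


@dataclass
class ConformerGraph:
    """Conformer similarity graph with its minimal spanning forest.

    Nodes are conformer names (with abundance attributes); edges connect
    pairs whose MRSSAD is below the threshold, weighted by the distance.
    """

    graph: nx.Graph
    threshold: float
    forest_edges: list[tuple[str, str]] = field(default_factory=list)


def build_graph(
    names: Sequence[str],
    distances: np.ndarray,
    threshold: float = 10.0,
    abundances: Optional[Sequence[float]] = None,
) -> ConformerGraph:
    """Build the conformer graph: an edge wherever distance < threshold (Å)."""
    d = np.asarray(distances, float)
    n = len(names)
    if d.shape != (n, n):
        raise ValidationError("distance matrix shape mismatch")
    if not np.allclose(d, d.T, atol=1e-8):
        raise ValidationError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0, atol=1e-8):
        raise ValidationError("distance matrix diagonal must be zero")
    g = nx.Graph()
    for k, name in enumerate(names):
        g.add_node(name, abundance=(None if abundances is None
                                    else float(abundances[k])))
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < threshold:
                g.add_edge(names[i], names[j], weight=float(d[i, j]))
    cg = ConformerGraph(g, threshold)
    cg.forest_edges = min_spanning_forest(cg)
    return cg


def min_spanning_forest(cg: ConformerGraph) -> list[tuple[str, str]]:
    """Kruskal minimal spanning forest; ties broken by node-pair order."""
    edges = sorted(
        ((data["weight"], *sorted((u, v))) for u, v, data
         in cg.graph.edges(data=True))
    )
    uf = nx.utils.UnionFind(cg.graph.nodes)
    forest = []
    for _, u, v in edges:
        if uf[u] != uf[v]:
            uf.union(u, v)
            forest.append((u, v))
    return forest


def distance_matrix(
    structures: Sequence[MolecularStructure], **kwargs
) -> np.ndarray:
    """Pairwise MRSSAD matrix (symmetric, zero diagonal)."""
    n = len(structures)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = mrssad(structures[i], structures[j], **kwargs)
    return d
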