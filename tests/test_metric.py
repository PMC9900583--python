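import itertools

import numpy as np
import pytest

from pepspec.errors import ValidationError
from pepspec.metric import (
    build_graph,
    distance_matrix,
    element_orbits,
    min_spanning_forest,
    mrssad,
    rssad,
    superpose,
)
from pepspec.structures import MolecularStructure, perceive_bonds

from conftest import random_rotation


def _mol(elements, coords, **kw):
    return MolecularStructure(list(elements), np.asarray(coords, float), **kw)


def brute_force_mrssad(a, b, orbits):
    """Exhaustive minimum over orbit permutations × superpositions."""
    best = np.inf
    perms_per_orbit = [list(itertools.permutations(o)) for o in orbits]
    for combo in itertools.product(*perms_per_orbit):
        perm = np.arange(a.n_atoms)
        for orbit, images in zip(orbits, combo):
            perm[list(orbit)] = list(images)
        val, _ = superpose(a.coords, b.coords[perm])
        best = min(best, val)
    return best


# --------------------------------------------------------------------- #
# rssad
# --------------------------------------------------------------------- #

def test_rssad_reference_values():
    a = _mol("CO", [[0, 0, 0], [1, 0, 0]])
    assert rssad(a, a) == 0.0
    b = _mol("CO", [[0, 0, 3], [1, 0, 0]])
    assert rssad(a, b) == pytest.approx(3.0)
    c = _mol("CO", [[0, 0, 3], [1, 4, 0]])
    assert rssad(a, c) == pytest.approx(5.0)  # 3-4-5 triangle


def test_rssad_atom_count_mismatch():
    with pytest.raises(ValidationError):
        rssad(_mol("C", [[0, 0, 0]]), _mol("CO", [[0, 0, 0], [1, 0, 0]]))


# --------------------------------------------------------------------- #
# mrssad
# --------------------------------------------------------------------- #

def test_rotated_translated_copy_has_zero_distance():
    rng = np.random.default_rng(0)
    coords = rng.standard_normal((6, 3)) * 2
    a = _mol("CCNOHH", coords)
    b = _mol("CCNOHH", coords @ random_rotation(rng).T + [1.0, -2.0, 0.5])
    assert mrssad(a, b, equivalence=[[i] for i in range(6)]) < 1e-8


def test_methyl_hydrogen_permutation_needs_reindexing():
    """Cyclic permutation of equivalent hydrogens: zero with orbit
    reindexing, nonzero at fixed correspondence."""
    # methane-like: C plus 3 symmetric H in a plane (plus one apex H)
    th = np.radians([0, 120, 240])
    h = np.c_[np.cos(th), np.sin(th), -np.ones(3) * 0.4]
    coords = np.vstack([[0, 0, 0], h, [0, 0, 1.09]])
    a = perceive_bonds(_mol("CHHHH", coords))
    permuted = coords[[0, 2, 3, 1, 4]]  # cycle the three basal H
    b = _mol("CHHHH", permuted)
    assert rssad(a, b) > 0.5
    assert mrssad(a, b) < 1e-8


def test_orbit_refinement_separates_inequivalent_atoms():
    # H2O2-like chain H-O-O-H: two equivalent O, two equivalent H
    coords = [[0, 0, 0], [1.4, 0, 0], [-0.4, 0.9, 0], [1.8, -0.9, 0]]
    s = perceive_bonds(_mol("OOHH", coords))
    orbits = element_orbits(s)
    assert sorted(map(sorted, orbits)) == [[0, 1], [2, 3]]


def test_matches_brute_force_on_small_instances():
    rng = np.random.default_rng(42)
    for _ in range(12):
        n = 6
        coords_a = rng.standard_normal((n, 3)) * 1.5
        coords_b = rng.standard_normal((n, 3)) * 1.5
        elements = "OHHCCN"
        orbits = [[0], [1, 2], [3, 4], [5]]
        a, b = _mol(elements, coords_a), _mol(elements, coords_b)
        got = mrssad(a, b, equivalence=orbits)
        want = brute_force_mrssad(a, b, orbits)
        assert got == pytest.approx(want, abs=1e-6)


def test_metric_properties_on_sampled_triples():
    rng = np.random.default_rng(1)
    orbits = [[0], [1, 2], [3]]
    mols = [_mol("OHHC", rng.standard_normal((4, 3)) * 2)
            for _ in range(12)]
    for a, b, c in itertools.islice(itertools.combinations(mols, 3), 40):
        dab = mrssad(a, b, equivalence=orbits)
        dba = mrssad(b, a, equivalence=orbits)
        dbc = mrssad(b, c, equivalence=orbits)
        dac = mrssad(a, c, equivalence=orbits)
        assert dab == pytest.approx(dba, abs=1e-6)
        assert dac <= dab + dbc + 1e-6
    assert mrssad(mols[0], mols[0], equivalence=orbits) < 1e-8


def test_mrssad_never_exceeds_fixed_correspondence():
    rng = np.random.default_rng(5)
    a = _mol("NHHO", rng.standard_normal((4, 3)) * 2)
    b = _mol("NHHO", rng.standard_normal((4, 3)) * 2)
    assert mrssad(a, b, equivalence=[[0], [1, 2], [3]]) <= rssad(a, b) + 1e-9


def test_enantiomers_not_collapsed():
    """Proper rotations only: a chiral mirror image stays at distance > 0."""
    rng = np.random.default_rng(3)
    coords = rng.standard_normal((5, 3)) * 2
    a = _mol("CNOHH", coords)
    mirror = coords.copy()
    mirror[:, 0] *= -1
    b = _mol("CNOHH", mirror)
    assert mrssad(a, b, equivalence=[[0], [1], [2], [3, 4]]) > 0.1


# --------------------------------------------------------------------- #
# graphs
# --------------------------------------------------------------------- #

def test_complete_triangle_below_threshold():
    d = np.full((3, 3), 5.0)
    np.fill_diagonal(d, 0.0)
    cg = build_graph(["A1", "A2", "A3"], d, threshold=10.0)
    assert cg.graph.number_of_edges() == 3
    assert len(cg.forest_edges) == 2


def test_no_edges_above_threshold():
    d = np.full((3, 3), 15.0)
    np.fill_diagonal(d, 0.0)
    cg = build_graph(["A1", "A2", "A3"], d, threshold=10.0)
    assert cg.graph.number_of_edges() == 0
    assert cg.forest_edges == []


def test_mixed_distances_edge_set():
    d = np.array([[0.0, 4.0, 12.0], [4.0, 0.0, 9.0], [12.0, 9.0, 0.0]])
    cg = build_graph(["A1", "A2", "A3"], d, threshold=10.0)
    assert set(map(frozenset, cg.graph.edges())) == {
        frozenset({"A1", "A2"}), frozenset({"A2", "A3"})
    }


def test_asymmetric_matrix_rejected():
    d = np.array([[0.0, 1.0], [2.0, 0.0]])
    with pytest.raises(ValidationError):
        build_graph(["A1", "A2"], d)


def test_spanning_forest_kruskal_by_hand():
    d = np.array([[0.0, 1.0, 3.0], [1.0, 0.0, 2.0], [3.0, 2.0, 0.0]])
    cg = build_graph(["A1", "A2", "A3"], d, threshold=10.0)
    weights = sorted(cg.graph[u][v]["weight"] for u, v in cg.forest_edges)
    assert weights == [1.0, 2.0]


def test_spanning_forest_two_components():
    d = np.full((4, 4), 50.0)
    np.fill_diagonal(d, 0.0)
    d[0, 1] = d[1, 0] = 2.0
    d[2, 3] = d[3, 2] = 3.0
    cg = build_graph(["A1", "A2", "A3", "A4"], d, threshold=10.0)
    assert sorted(cg.forest_edges) == [("A1", "A2"), ("A3", "A4")]


def test_distance_matrix_symmetric_zero_diagonal():
    rng = np.random.default_rng(2)
    mols = [_mol("OHH", rng.standard_normal((3, 3))) for _ in range(3)]
    d = distance_matrix(mols, equivalence=[[0], [1, 2]])
    assert np.allclose(d, d.T)
    assert np.allclose(np.diag(d), 0.0)
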