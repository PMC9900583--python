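import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pepspec.errors import (
    DegenerateGeometryError,
    ValidationError,
)
from pepspec.features import (
    ConformerRecord,
    HBond,
    classify_angle,
    compute_torsions,
    descriptive_name,
    detect_hbonds_geometric,
    detect_hbonds_nci,
    dihedral,
    label_hbond_residues,
    rank_and_weight,
    ring_order,
)
from pepspec.structures import MolecularStructure, annotate_backbone
from pepspec.synthetic import BridgeSpec, gen_density_grid, gen_toy_peptide

from conftest import random_rotation


# --------------------------------------------------------------------- #
# dihedrals and classification
# --------------------------------------------------------------------- #

@pytest.mark.parametrize("p4,expected", [
    ((1, 1, 0), 0.0),      # eclipsed
    ((-1, 1, 0), 180.0),   # anti
    ((0, 1, 1), -90.0),    # perpendicular, sign per convention
])
def test_dihedral_reference_values(p4, expected):
    value = dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), p4)
    assert value == pytest.approx(expected, abs=1e-9)


def test_dihedral_collinear_rejected():
    with pytest.raises(DegenerateGeometryError):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


@given(seed=st.integers(0, 2**31 - 1))
def test_dihedral_invariant_under_rigid_motion(seed):
    rng = np.random.default_rng(seed)
    pts = rng.standard_normal((4, 3)) * 2
    try:
        ref = dihedral(*pts)
    except DegenerateGeometryError:
        return
    moved = pts @ random_rotation(rng).T + rng.standard_normal(3)
    assert dihedral(*moved) == pytest.approx(ref, abs=1e-6)


@pytest.mark.parametrize("theta,letter", [
    (10.0, "C"), (-10.0, "C"), (29.9, "C"),
    (30.0, "G"), (-60.0, "G"), (89.9, "G"),
    (90.0, "A"), (-100.0, "A"), (149.9, "A"),
    (150.0, "T"), (180.0, "T"), (-179.9, "T"),
])
def test_classify_angle_bins(theta, letter):
    assert classify_angle(theta) == letter


@given(theta=st.floats(-179.999, 180.0))
def test_classify_angle_even_and_total(theta):
    assert classify_angle(theta) in "CGAT"
    if -180.0 < -theta <= 180.0:
        assert classify_angle(theta) == classify_angle(-theta)


# --------------------------------------------------------------------- #
# hydrogen bonds
# --------------------------------------------------------------------- #

def _nh_o_fixture(d_ho: float, angle_deg: float) -> MolecularStructure:
    """N–H donor plus a lone O acceptor at given H···O distance/angle."""
    ang = np.radians(180.0 - angle_deg)
    h = np.array([1.01, 0.0, 0.0])
    o = h + d_ho * np.array([np.cos(ang), np.sin(ang), 0.0])
    s = MolecularStructure(["N", "H", "O"], [[0, 0, 0], h, o],
                           bonds=[(0, 1)])
    return s


@pytest.mark.parametrize("d,angle,found", [
    (2.0, 170.0, True),
    (3.5, 170.0, False),
    (2.0, 90.0, False),
])
def test_geometric_hbond_criteria(d, angle, found):
    hbs = detect_hbonds_geometric(_nh_o_fixture(d, angle))
    assert bool(hbs) is found
    if found:
        assert (hbs[0].donor, hbs[0].hydrogen, hbs[0].acceptor) == (0, 1, 2)
        assert hbs[0].strength is None
        assert hbs[0].ring_order is None  # no covalent path


def _c5_pair(structure):
    bb = annotate_backbone(structure)
    r1 = bb.residues[0]
    h = min(bb.n_term_h,
            key=lambda i: np.linalg.norm(structure.coords[i]
                                         - structure.coords[r1.o]))
    return bb, (r1.n, h, r1.o)


@pytest.mark.parametrize("peak,expected_cls", [
    (25.0, "hbond"),
    (16.0, "weak-interaction"),
])
def test_nci_bridge_classification(peak, expected_cls):
    s = gen_toy_peptide(2, motifs=[("c5", 1)])
    _, pair = _c5_pair(s)
    field = gen_density_grid(s, bridges=[BridgeSpec(pair[1], pair[2], peak)])
    hbs = detect_hbonds_nci(s, field, pairs=[pair])
    assert len(hbs) == 1
    assert hbs[0].classification == expected_cls
    assert hbs[0].strength == pytest.approx(peak, rel=0.05)
    assert hbs[0].ring_order == 5


def test_nci_no_bridge_no_bond():
    s = gen_toy_peptide(2, motifs=[("c5", 1)])
    _, pair = _c5_pair(s)
    assert detect_hbonds_nci(s, gen_density_grid(s), pairs=[pair]) == []


def test_nci_and_geometric_agree_on_beta_fixture():
    """Both detectors find the same donor/acceptor pair on a β-turn."""
    s = gen_toy_peptide(5, motifs=[("beta", 1)])
    geo = detect_hbonds_geometric(s)
    assert len(geo) == 1
    pair = (geo[0].donor, geo[0].hydrogen, geo[0].acceptor)
    field = gen_density_grid(s, bridges=[BridgeSpec(pair[1], pair[2], 25.0)])
    nci = detect_hbonds_nci(s, field, pairs=[pair])
    assert [(b.donor, b.hydrogen, b.acceptor) for b in nci] == [pair]


@pytest.mark.parametrize("motif,start,order", [
    ("c5", 1, 5),       # intra-unit NH···O ring
    ("gamma", 1, 7),    # i → i+2 turn
    ("beta", 1, 10),    # i → i+3 turn
])
def test_ring_orders(motif, start, order):
    s = gen_toy_peptide(5, motifs=[(motif, start)])
    bb = annotate_backbone(s)
    if motif == "c5":
        r1 = bb.residues[0]
        h = min(bb.n_term_h,
                key=lambda i: np.linalg.norm(s.coords[i] - s.coords[r1.o]))
        hb = HBond(r1.n, h, r1.o)
    else:
        hbs = detect_hbonds_geometric(s)
        assert hbs, f"no geometric H-bond found for {motif}"
        hb = hbs[0]
    assert ring_order(hb, s) == order


def test_ring_order_invariant_under_rigid_motion_and_reindex():
    s = gen_toy_peptide(5, motifs=[("beta", 1)])
    hb = detect_hbonds_geometric(s)[0]
    order = ring_order(hb, s)
    rng = np.random.default_rng(7)
    perm = rng.permutation(s.n_atoms)
    inv = np.argsort(perm)
    moved = MolecularStructure(
        [s.elements[i] for i in perm],
        (s.coords @ random_rotation(rng).T + 5.0)[perm],
        bonds=[(int(inv[a]), int(inv[b])) for a, b in s.bonds],
    )
    hb2 = HBond(int(inv[hb.donor]), int(inv[hb.hydrogen]),
                int(inv[hb.acceptor]))
    assert ring_order(hb2, moved) == order


# --------------------------------------------------------------------- #
# naming
# --------------------------------------------------------------------- #

def test_all_trans_name(pentapeptide_trans):
    bb = annotate_backbone(pentapeptide_trans)
    tors = compute_torsions(pentapeptide_trans, bb)
    assert descriptive_name(tors, []) == "TTTTTTTTTT"


def test_gamma_turn_replaces_two_positions():
    s = gen_toy_peptide(5, motifs=[("gamma", 2)])
    bb = annotate_backbone(s)
    hbs = detect_hbonds_geometric(s)
    label_hbond_residues(hbs, bb)
    name = descriptive_name(compute_torsions(s, bb), hbs)
    assert name == "TTTT[γ]TTTT"
    assert name.count("T") == 8  # two torsions swallowed by the token


def test_beta_turn_replaces_four_positions():
    s = gen_toy_peptide(5, motifs=[("beta", 1)])
    bb = annotate_backbone(s)
    hbs = detect_hbonds_geometric(s)
    label_hbond_residues(hbs, bb)
    name = descriptive_name(compute_torsions(s, bb), hbs)
    assert name == "TT[β]TTTT"


def test_wrong_angle_count_rejected():
    from pepspec.features import TorsionSet

    tors = TorsionSet([180.0] * 8, [f"a{i}" for i in range(8)])
    with pytest.raises(ValidationError):
        descriptive_name(tors, [])


def test_toy_torsions_match_request():
    rng = np.random.default_rng(0)
    spec = list(rng.uniform(-170, 170, 10))
    s = gen_toy_peptide(5, torsions=spec)
    bb = annotate_backbone(s)
    tors = compute_torsions(s, bb)
    for got, want in zip(tors.angles, spec):
        delta = (got - want + 180) % 360 - 180
        assert abs(delta) < 1.0


# --------------------------------------------------------------------- #
# Boltzmann abundances
# --------------------------------------------------------------------- #

def test_equal_energies_split_evenly():
    recs = rank_and_weight([ConformerRecord(1.0), ConformerRecord(1.0)])
    assert [r.abundance for r in recs] == pytest.approx([0.5, 0.5])


def test_rt_ln2_gap_gives_two_thirds():
    # ΔG = RT·ln 2 at 400 K = 0.5511 kcal/mol
    recs = rank_and_weight(
        [ConformerRecord(0.0), ConformerRecord(0.55114)], temperature=400.0
    )
    assert recs[0].abundance == pytest.approx(2 / 3, abs=1e-4)
    assert recs[1].abundance == pytest.approx(1 / 3, abs=1e-4)
    assert recs[0].short_name == "A1"


def test_huge_gap_winner_takes_all():
    recs = rank_and_weight([ConformerRecord(0.0), ConformerRecord(500.0)])
    assert recs[0].abundance == pytest.approx(1.0)
    assert recs[1].abundance == pytest.approx(0.0, abs=1e-12)


def test_empty_set_rejected():
    with pytest.raises(ValidationError):
        rank_and_weight([])


@given(shift=st.floats(-50, 50), g2=st.floats(0.01, 5.0))
def test_abundance_shift_invariance(shift, g2):
    a = rank_and_weight([ConformerRecord(0.0), ConformerRecord(g2)])
    b = rank_and_weight([ConformerRecord(shift), ConformerRecord(g2 + shift)])
    assert sum(r.abundance for r in a) == pytest.approx(1.0)
    assert a[0].abundance == pytest.approx(b[0].abundance, rel=1e-9)
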