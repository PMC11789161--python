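import numpy as np
import pytest

from cspcompare import crystal as cr
from cspcompare import synth
from cspcompare.synth import FixtureSpec, Placement

from oracles import brute_force_neighbour_rows


# --------------------------------------------------------------------------
# cells and symmetry operations
# --------------------------------------------------------------------------

def test_cell_volume_matches_triclinic_closed_form():
    cell = cr.LatticeCell(6.1, 7.3, 8.9, 85.0, 97.0, 101.0)
    # volume from the orthogonalization matrix must equal the closed form
    assert cell.volume == pytest.approx(abs(np.linalg.det(cell.matrix)), rel=1e-12)
    ca, cb, cg = (np.cos(np.radians(a)) for a in (85.0, 97.0, 101.0))
    closed = 6.1 * 7.3 * 8.9 * np.sqrt(
        1 - ca**2 - cb**2 - cg**2 + 2 * ca * cb * cg)
    assert cell.volume == pytest.approx(closed, rel=1e-12)


@pytest.mark.parametrize("bad", [
    dict(a=-1, b=1, c=1, alpha=90, beta=90, gamma=90),
    dict(a=1, b=1, c=1, alpha=0, beta=90, gamma=90),
    dict(a=1, b=1, c=1, alpha=90, beta=190, gamma=90),
])
def test_degenerate_cells_rejected(bad):
    with pytest.raises(ValueError):
        cr.LatticeCell(**bad)


def test_symop_closure_of_space_group():
    ops = cr.spacegroup_symops("P 21/c")
    assert len(ops) == 4
    triplets = {op.triplet() for op in ops}
    for a in ops:
        for b in ops:
            assert a.compose(b).triplet() in triplets


def test_symop_rotation_determinant_enforced():
    with pytest.raises(ValueError):
        cr.SymOp.from_arrays(np.diag([2, 1, 1]), np.zeros(3))


# --------------------------------------------------------------------------
# CIF I/O
# --------------------------------------------------------------------------

def test_cif_round_trip(toy_p21c, tmp_path):
    path = tmp_path / "s.cif"
    cr.write_cif(toy_p21c, path)
    back = cr.read_cif(path)[0]
    for k in ("a", "b", "c", "alpha", "beta", "gamma"):
        assert getattr(back.cell, k) == pytest.approx(
            getattr(toy_p21c.cell, k), rel=1e-6)
    assert {op.triplet() for op in back.symops} == \
        {op.triplet() for op in toy_p21c.symops}
    for s1, s2 in zip(back.sites, toy_p21c.sites):
        assert np.allclose(s1.frac, s2.frac, atol=1e-6)
        assert s1.element == s2.element
        assert s1.occupancy == pytest.approx(s2.occupancy)


def test_cif_multi_block_and_disorder_round_trip(disorder_trio, tmp_path):
    disordered, comp_a, _ = disorder_trio
    path = tmp_path / "multi.cif"
    cr.write_cif([disordered, comp_a], path)
    back = cr.read_cif(path)
    assert len(back) == 2
    groups = {s.disorder_group for s in back[0].sites}
    assert groups == {None, "1", "2"}
    occ = [s.occupancy for s in back[0].sites if s.disorder_group == "2"]
    assert occ and all(o == pytest.approx(0.4) for o in occ)


def test_cif_explicit_symop_loop_and_p1(tmp_path):
    text = """data_explicit
_cell_length_a 5.0
_cell_length_b 6.0
_cell_length_c 7.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_symmetry_equiv_pos_as_xyz
'x,y,z'
'-x,y+1/2,-z+1/2'
'-x,-y,-z'
'x,-y+1/2,z+1/2'
loop_
_atom_site_label
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 0.1 0.2 0.3

data_p1
_cell_length_a 4.0
_cell_length_b 4.0
_cell_length_c 4.0
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
_symmetry_space_group_name_H-M 'P 1'
loop_
_atom_site_label
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 0.0 0.0 0.0
"""
    path = tmp_path / "two.cif"
    path.write_text(text)
    blocks = cr.read_cif(path)
    assert len(blocks[0].symops) == 4
    assert len(blocks[1].symops) == 1
    assert len(blocks[1].sites) == 1
    assert blocks[0].sites[0].occupancy == 1.0  # missing occupancy defaults


def test_cif_errors(tmp_path):
    bad = tmp_path / "bad.cif"
    bad.write_text("data_x\n_cell_length_a 5\n")
    with pytest.raises(cr.CifParseError, match="x"):
        cr.read_cif(bad)
    nosym = tmp_path / "nosym.cif"
    nosym.write_text("""data_y
_cell_length_a 5
_cell_length_b 5
_cell_length_c 5
_cell_angle_alpha 90
_cell_angle_beta 90
_cell_angle_gamma 90
loop_
_atom_site_label
_atom_site_fract_x
_atom_site_fract_y
_atom_site_fract_z
C1 0 0 0
""")
    with pytest.raises(cr.CifParseError, match="symmetry"):
        cr.read_cif(nosym)


# --------------------------------------------------------------------------
# expansion
# --------------------------------------------------------------------------

def test_expand_general_position_p21c(toy_p21c):
    atoms = cr.expand_to_cell(toy_p21c)
    assert len(atoms) == 4 * len(toy_p21c.sites)


def test_expand_special_position_merges():
    # atom on the inversion centre of P-1: both images coincide
    s = cr.CrystalStructure(
        cr.LatticeCell(6, 6, 6, 90, 90, 90), cr.spacegroup_symops("P -1"),
        [cr.AtomSite("C1", "C", (0.0, 0.0, 0.0)),
         cr.AtomSite("N1", "N", (0.1, 0.2, 0.3))])
    atoms = cr.expand_to_cell(s)
    labels = [a.site_label for a in atoms]
    assert labels.count("C1") == 1
    assert labels.count("N1") == 2


def test_expand_matches_brute_force_dedup(toy_p21c):
    atoms = cr.expand_to_cell(toy_p21c)
    # O(n^2) oracle: expand every site by every op, dedup by pairwise
    # Cartesian distance under periodic boundary conditions
    mat = toy_p21c.cell.matrix
    count = 0
    for site in toy_p21c.sites:
        images = []
        for op in toy_p21c.symops:
            f = np.mod(op.apply(site.frac), 1.0)
            if not any(np.linalg.norm(
                    mat @ (f - g - np.round(f - g))) < 0.3 for g in images):
                images.append(f)
        count += len(images)
    assert len(atoms) == count


# --------------------------------------------------------------------------
# molecule perception
# --------------------------------------------------------------------------

def test_perceive_ring_molecule(toy_p1):
    mols = cr.perceive_molecules(toy_p1)
    assert len(mols) == 1
    m = mols[0]
    assert m.formula() == "C5N1O1"
    assert len(m.bonds) == 7  # six ring bonds + one C-O
    assert np.allclose(m.centroid, m.coords.mean(axis=0))


def test_perceive_cocrystal_two_species(cocrystal_p1):
    mols = cr.perceive_molecules(cocrystal_p1)
    assert sorted(m.formula() for m in mols) == ["C2N2", "C5N1O1"]


def test_perceive_unwraps_across_boundaries():
    s = synth.make_toy_crystal(FixtureSpec(
        placements=[Placement(position=(0.02, 0.03, 0.5))]))
    mols = cr.perceive_molecules(s)
    assert len(mols) == 1
    # unwrapped: max intramolecular extent stays molecular (< 6 A)
    ext = np.ptp(mols[0].coords, axis=0).max()
    assert ext < 6.0
    assert len(mols[0].bonds) == 7


def test_perception_invariant_under_origin_shift(toy_p21c):
    shifted = toy_p21c.copy()
    for site in shifted.sites:
        site.frac = tuple(np.mod(np.array(site.frac) + (0.31, 0.77, 0.13), 1))
    # same molecules up to translation: same bond graphs and formulas
    a = sorted(m.species_key() for m in cr.perceive_molecules(toy_p21c))
    b = sorted(m.species_key() for m in cr.perceive_molecules(shifted))
    assert a == b


def test_jittered_crystal_same_bond_graph(toy_p21c):
    jittered, _ = synth.perturb(toy_p21c, jitter=0.05, seed=7)
    a = sorted(m.species_key() for m in cr.perceive_molecules(toy_p21c))
    b = sorted(m.species_key() for m in cr.perceive_molecules(jittered))
    assert a == b


def test_polymer_detection_raises():
    # a chain of carbons bonded to its own translate
    s = cr.CrystalStructure(
        cr.LatticeCell(1.5, 8, 8, 90, 90, 90), [cr.SymOp.identity()],
        [cr.AtomSite("C1", "C", (0.0, 0.0, 0.0))])
    with pytest.raises(cr.NonMolecularSolidError):
        cr.perceive_molecules(s)


# --------------------------------------------------------------------------
# Z'
# --------------------------------------------------------------------------

def test_z_prime_values(toy_p1, toy_p21c, cocrystal_p1):
    from fractions import Fraction
    assert cr.z_prime(toy_p1) == {"C5N1O1": Fraction(1)}
    assert cr.z_prime(toy_p21c) == {"C1N1O1S1": Fraction(1)}
    assert cr.z_prime(cocrystal_p1) == {"C5N1O1": Fraction(1),
                                        "C2N2": Fraction(1)}


def test_z_prime_special_position_half():
    # the centrosymmetric diamine on the inversion centre of P-1
    from fractions import Fraction
    s = synth.make_toy_crystal(FixtureSpec(
        template="diamine", spacegroup="P -1",
        cell=(8, 8, 8, 90, 90, 90),
        placements=[Placement(position=(0.0, 0.0, 0.0))]), validate=False)
    assert cr.z_prime(s) == {"C2N2": Fraction(1, 2)}


def test_supercell_doubles_molecules_keeps_volume_ratio(toy_p21c):
    sc = cr.make_supercell(toy_p21c, 2, 1, 1)
    assert sc.cell.volume == pytest.approx(2 * toy_p21c.cell.volume, rel=1e-9)
    assert len(cr.perceive_molecules(sc)) == \
        2 * len(cr.perceive_molecules(toy_p21c))
    # in P1 the Z' equals the molecule count in the cell
    from fractions import Fraction
    assert cr.z_prime(sc) == {"C1N1O1S1": Fraction(8)}


# --------------------------------------------------------------------------
# disorder splitting
# --------------------------------------------------------------------------

def test_split_disorder_recovers_planted_components(disorder_trio):
    disordered, comp_a, comp_b = disorder_trio
    comps = cr.split_disorder(disordered)
    assert len(comps) == 2
    for comp, planted in zip(comps, (comp_a, comp_b)):
        assert all(s.occupancy == 1.0 for s in comp.sites)
        got = sorted(tuple(np.round(s.frac, 9)) for s in comp.sites)
        want = sorted(tuple(np.round(s.frac, 9)) for s in planted.sites)
        assert got == want


def test_split_disorder_ordered_is_identity(toy_p1):
    assert cr.split_disorder(toy_p1) == [toy_p1]


# --------------------------------------------------------------------------
# stripping
# --------------------------------------------------------------------------

def test_strip_elements(toy_p1):
    stripped = cr.strip_atoms(toy_p1, "O")
    assert len(stripped.sites) == len(toy_p1.sites) - 1
    with pytest.raises(ValueError):
        cr.strip_atoms(toy_p1, {"C", "N", "O"})


def test_strip_fragment_removes_substituent(conformer_pair):
    a, _ = conformer_pair
    stripped = cr.strip_fragment(a, synth.CORE_SUB_CHAIN)
    mols = cr.perceive_molecules(stripped)
    assert mols[0].formula() == "C5N1O1"  # the pendant chain is gone


def test_strip_molecule_rederives_bonds(toy_p1):
    m = cr.perceive_molecules(toy_p1)[0]
    sm = cr.strip_atoms(m, "O")
    assert sm.n_atoms == m.n_atoms - 1
    assert len(sm.bonds) == len(m.bonds) - 1


# --------------------------------------------------------------------------
# clusters
# --------------------------------------------------------------------------

def test_cluster_cardinality_and_identity(toy_p21c):
    assert len(cr.build_cluster(toy_p21c, 1)) == 1
    assert len(cr.build_cluster(toy_p21c, 30)) == 30


def test_cluster_distances_match_supercell_enumeration():
    s = synth.make_toy_crystal(FixtureSpec(
        template="tiny4", cell=(7, 7, 7, 90, 90, 90)))
    cluster = cr.build_cluster(s, 15)
    c0 = cluster[0].centroid
    got = sorted(np.linalg.norm(m.centroid - c0) for m in cluster[1:])
    # oracle: enumerate a 5^3 supercell of centroids directly
    base = cr.perceive_molecules(s)[0].centroid
    mat = s.cell.matrix
    dists = sorted(
        np.linalg.norm(base + np.array([i, j, k]) @ mat.T - c0)
        for i in range(-2, 3) for j in range(-2, 3) for k in range(-2, 3)
        if (i, j, k) != (0, 0, 0))
    assert np.allclose(got, dists[:14], atol=1e-9)
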