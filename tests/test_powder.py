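import math

import numpy as np
import pytest

from cspcompare import powder as pw
from cspcompare import synth
from cspcompare.crystal import (AtomSite, CrystalStructure, LatticeCell,
                                SymOp, expand_to_cell, make_supercell,
                                spacegroup_symops)
from cspcompare.synth import FixtureSpec, Placement


@pytest.fixture(scope="module")
def cubic_one_atom():
    return CrystalStructure(LatticeCell(10, 10, 10, 90, 90, 90),
                            [SymOp.identity()],
                            [AtomSite("C1", "C", (0, 0, 0))])


# --------------------------------------------------------------------------
# reflection generation
# --------------------------------------------------------------------------

def test_bragg_position_cubic(cubic_one_atom):
    r = pw.reflections(cubic_one_atom, pw.CU_KALPHA1, 40)
    want = math.degrees(2 * math.asin(pw.CU_KALPHA1 / 20.0))
    mask = (np.abs(r.hkl) == [1, 0, 0]).all(axis=1)
    assert mask.any()
    assert r.two_theta[mask][0] == pytest.approx(want, abs=1e-9)


def test_single_atom_F2_equals_f2(cubic_one_atom):
    r = pw.reflections(cubic_one_atom, pw.CU_KALPHA1, 40)
    theta = np.radians(r.two_theta / 2)
    lp = (1 + np.cos(2 * theta) ** 2) / (np.sin(theta) ** 2 * np.cos(theta))
    f = pw._scattering_factor("C", 1.0 / (2.0 * r.d))
    assert np.allclose(r.intensity, r.multiplicity * lp * f**2, rtol=1e-9)


def test_structure_factor_matches_direct_sum(toy_p21c):
    r = pw.reflections(toy_p21c, pw.CU_KALPHA1, 30)
    atoms = expand_to_cell(toy_p21c)
    frac = np.array([a.frac for a in atoms])
    for i in range(0, len(r), 7):  # spot check a spread of reflections
        hkl = r.hkl[i]
        stol = 1.0 / (2.0 * r.d[i])
        F = 0j
        for a, f in zip(atoms, frac):
            F += pw._scattering_factor(a.element, np.array([stol]))[0] \
                * a.occupancy * np.exp(2j * np.pi * f @ hkl)
        theta = math.radians(r.two_theta[i] / 2)
        lp = (1 + math.cos(2 * theta) ** 2) / (math.sin(theta) ** 2
                                               * math.cos(theta))
        want = r.multiplicity[i] * lp * abs(F) ** 2
        assert r.intensity[i] == pytest.approx(want, rel=1e-9, abs=1e-6)


def test_screw_axis_absences_emerge(toy_p21c):
    # P2(1)/c: (0k0) absent for odd k, present for even k
    r = pw.reflections(toy_p21c, pw.CU_KALPHA1, 40)
    scale = r.intensity.max()
    for k in (1, 3):
        mask = (np.abs(r.hkl) == [0, k, 0]).all(axis=1)
        assert r.intensity[mask].max(initial=0.0) < 1e-12 * scale
    mask = (np.abs(r.hkl) == [0, 2, 0]).all(axis=1)
    assert r.intensity[mask].max() > 1e-6 * scale


def test_centrosymmetric_structure_factor_real():
    s = CrystalStructure(LatticeCell(7, 8, 9, 90, 90, 90),
                         spacegroup_symops("P -1"),
                         [AtomSite("C1", "C", (0.12, 0.23, 0.31)),
                          AtomSite("N1", "N", (0.41, 0.05, 0.17))])
    atoms = expand_to_cell(s)
    frac = np.array([a.frac for a in atoms])
    for hkl in ([1, 0, 0], [2, 1, 3], [1, 1, 1]):
        F = sum(np.exp(2j * np.pi * f @ np.array(hkl)) for f in frac)
        assert abs(F.imag) < 1e-10


def test_wavelength_validation(cubic_one_atom):
    with pytest.raises(ValueError):
        pw.reflections(cubic_one_atom, -1.0, 40)


# --------------------------------------------------------------------------
# pattern simulation
# --------------------------------------------------------------------------

def test_occupancy_scaling_leaves_normalized_pattern(toy_p1):
    half = toy_p1.copy()
    for site in half.sites:
        site.occupancy = 0.5
    p1 = pw.simulate_pattern(toy_p1)
    p2 = pw.simulate_pattern(half)
    assert np.allclose(p1.intensity, p2.intensity, atol=1e-12)


def test_peak_area_proportional_to_intensity(cubic_one_atom):
    r = pw.reflections(cubic_one_atom, pw.CU_KALPHA1, 20)
    pat = pw.simulate_pattern(cubic_one_atom, two_theta_range=(3, 20))
    # isolated (100)/(110) peaks: quadrature area ratio = intensity ratio
    def area(center):
        mask = np.abs(pat.two_theta - center) < 0.8
        return np.trapezoid(pat.intensity[mask], pat.two_theta[mask])
    i100 = np.where((np.abs(r.hkl) == [1, 0, 0]).all(axis=1))[0][0]
    i110 = np.where((np.sort(np.abs(r.hkl), axis=1) == [0, 1, 1]).all(axis=1))[0][0]
    got = area(r.two_theta[i110]) / area(r.two_theta[i100])
    # several distinct orbits can share one 2-theta; a peak's area is the
    # sum of their intensities
    def total(tt):
        return r.intensity[np.abs(r.two_theta - tt) < 1e-9].sum()
    want = total(r.two_theta[i110]) / total(r.two_theta[i100])
    assert got == pytest.approx(want, rel=5e-3)


def test_supercell_pattern_identical(toy_p21c):
    p1 = pw.simulate_pattern(toy_p21c)
    p2 = pw.simulate_pattern(make_supercell(toy_p21c, 2, 1, 1))
    assert np.allclose(p1.intensity, p2.intensity, atol=1e-8)


def test_empty_range_raises(cubic_one_atom):
    with pytest.raises(ValueError):
        pw.simulate_pattern(cubic_one_atom, two_theta_range=(3.0, 4.0))


# --------------------------------------------------------------------------
# de Gelder similarity
# --------------------------------------------------------------------------

def _gaussian_pattern(center, width=0.15, lo=3.0, hi=40.0, step=0.017):
    grid = np.arange(lo, hi + step / 2, step)
    return pw.PowderPattern(pw.CU_KALPHA1, grid,
                            np.exp(-0.5 * ((grid - center) / width) ** 2))


def _oracle_degelder(p, q, window):
    """Direct double-loop evaluation of the weighted correlation overlap."""
    step = p.step
    m = int(round(window / step))
    f, g = p.intensity, q.intensity

    def corr(a, b):
        total = 0.0
        n = len(a)
        for lag in range(-m, m + 1):
            w = 1.0 - abs(lag) / m
            if lag >= 0:
                c = float(np.dot(a[:n - lag], b[lag:]))
            else:
                c = float(np.dot(a[-lag:], b[:n + lag]))
            total += w * c * step
        return total

    return corr(f, g) / math.sqrt(corr(f, f) * corr(g, g))


def test_self_and_scale_invariance(toy_p1):
    p = pw.simulate_pattern(toy_p1)
    assert pw.degelder_similarity(p, p) == pytest.approx(1.0, abs=1e-12)
    p3 = pw.PowderPattern(p.wavelength, p.two_theta, 3.0 * p.intensity)
    assert pw.degelder_similarity(p, p3) == pytest.approx(1.0, abs=1e-12)


@pytest.mark.parametrize("delta", [0.0, 0.75, 3.0])  # 0, l/2, 2l
def test_offset_gaussians_match_integration_oracle(delta):
    p = _gaussian_pattern(15.0)
    q = _gaussian_pattern(15.0 + delta)
    got = pw.degelder_similarity(p, q, window=1.5)
    want = _oracle_degelder(p, q, window=1.5)
    assert got == pytest.approx(want, abs=1e-8)


def test_similarity_symmetric(toy_p1, toy_p21c):
    p = pw.simulate_pattern(toy_p1)
    q = pw.simulate_pattern(toy_p21c)
    assert pw.degelder_similarity(p, q) == pytest.approx(
        pw.degelder_similarity(q, p), abs=1e-12)


def test_shift_monotonicity():
    p = _gaussian_pattern(15.0)
    window = 1.5
    sims = [pw.degelder_similarity(p, _gaussian_pattern(15.0 + d), window)
            for d in np.linspace(0, 2 * window, 9)]
    assert all(a >= b - 1e-12 for a, b in zip(sims, sims[1:]))
    assert sims[0] == pytest.approx(1.0, abs=1e-12)


def test_all_zero_pattern_rejected():
    grid = np.arange(3, 40, 0.017)
    z = pw.PowderPattern(pw.CU_KALPHA1, grid, np.zeros_like(grid))
    with pytest.raises(ValueError):
        pw.degelder_similarity(z, z)


# --------------------------------------------------------------------------
# preferred orientation
# --------------------------------------------------------------------------

def test_march_dollase_identity_and_sphere_average(cubic_one_atom):
    cell = cubic_one_atom.cell
    assert pw.march_dollase_factor([1, 0, 0], [0, 0, 1], 1.0, cell) == \
        pytest.approx(1.0, abs=1e-12)
    for r in (0.6, 1.4):
        # average of the correction over a uniform sphere of orientations
        c = np.polynomial.legendre.leggauss(200)
        x, w = c
        vals = (r**2 * x**2 + (1 - x**2) / r) ** -1.5
        assert float((vals * w).sum() / 2.0) == pytest.approx(1.0, abs=1e-6)


def test_march_dollase_plate_suppression(cubic_one_atom):
    cell = cubic_one_atom.cell
    refl = pw.reflections(cubic_one_atom, pw.CU_KALPHA1, 30)
    corr = pw.preferred_orientation(refl, [0, 0, 1], 0.5, cell)
    # reflections along the plate axis are enhanced for r < 1
    on_axis = (np.abs(corr.hkl[:, :2]).sum(axis=1) == 0)
    ratios = corr.intensity / refl.intensity
    assert (ratios[on_axis] > 1.0).all()
    in_plane = (corr.hkl[:, 2] == 0)
    assert (ratios[in_plane] < 1.0).all()


# --------------------------------------------------------------------------
# cell refinement
# --------------------------------------------------------------------------

def test_refine_identity_is_noop(toy_p1):
    target = pw.simulate_pattern(toy_p1)
    refined, sim = pw.refine_cell(toy_p1, target)
    assert sim == pytest.approx(1.0, abs=1e-6)
    for k in ("a", "b", "c"):
        assert getattr(refined.cell, k) == pytest.approx(
            getattr(toy_p1.cell, k), rel=2e-4)


def test_refine_recovers_isotropic_strain(toy_p21c):
    target = pw.simulate_pattern(toy_p21c)
    strained, _ = synth.perturb(toy_p21c, strain=0.02)
    refined, sim = pw.refine_cell(strained, target)
    assert sim >= 0.999
    for k in ("a", "b", "c"):
        err = abs(getattr(refined.cell, k) - getattr(toy_p21c.cell, k)) \
            / getattr(toy_p21c.cell, k)
        assert err < 1e-3


def test_refine_never_decreases_similarity(toy_p21c, decoy):
    target = pw.simulate_pattern(decoy)
    start = pw.degelder_similarity(pw.simulate_pattern(toy_p21c), target)
    _, sim = pw.refine_cell(toy_p21c, target)
    assert sim >= start - 1e-12


def test_crystal_system_detection(toy_p21c, toy_p1):
    assert pw.crystal_system(toy_p21c) == "monoclinic"
    assert pw.crystal_system(toy_p1) == "triclinic"


# --------------------------------------------------------------------------
# .xy files
# --------------------------------------------------------------------------

def test_xy_round_trip(toy_p1, tmp_path):
    p = pw.simulate_pattern(toy_p1)
    path = tmp_path / "pattern.xy"
    pw.write_xy(p, path)
    back = pw.read_xy(path)
    assert back.wavelength == pytest.approx(p.wavelength)
    assert np.allclose(back.two_theta, p.two_theta, atol=1e-5)
    assert np.allclose(back.intensity, p.intensity, rtol=1e-6)
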