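import itertools

import numpy as np
import pytest

from cspcompare import crystal as cr
from cspcompare import packing as pk
from cspcompare import synth
from cspcompare.synth import FixtureSpec, Placement

from oracles import oracle_compare_clusters

SMALL = pk.ToleranceSpec(n_molecules=4)


# --------------------------------------------------------------------------
# molecular equivalence
# --------------------------------------------------------------------------

def test_molecule_vs_itself_identity_mapping(toy_p1):
    m = cr.perceive_molecules(toy_p1)[0]
    maps = pk.molecules_equivalent(m, m, ignore_hydrogen=True)
    assert {i: i for i in range(m.n_atoms)} in maps


def test_distinct_species_no_mapping(cocrystal_p1):
    a, b = cr.perceive_molecules(cocrystal_p1)
    assert pk.molecules_equivalent(a, b) == []


def test_automorphism_count_matches_brute_force():
    s = synth.make_toy_crystal(FixtureSpec(
        template="diamine", cell=(9, 9, 6, 90, 90, 90)), validate=False)
    m = cr.perceive_molecules(s)[0]
    maps = pk.molecules_equivalent(m, m)
    # brute force: all permutations preserving elements and bonds
    els = m.elements
    bonds = {frozenset(b) for b in m.bonds}
    count = 0
    for perm in itertools.permutations(range(m.n_atoms)):
        if any(els[i] != els[perm[i]] for i in range(m.n_atoms)):
            continue
        if {frozenset((perm[i], perm[j])) for i, j in m.bonds} == bonds:
            count += 1
    assert count == 2  # the N-C-C-N chain reversal
    assert len(maps) == count


# --------------------------------------------------------------------------
# rigid superposition
# --------------------------------------------------------------------------

def test_kabsch_recovers_planted_rotation():
    rng = np.random.default_rng(5)
    P = rng.normal(size=(7, 3))
    R0 = synth.rotation_matrix((31, 57, -12))
    Q = P @ R0.T + np.array([1.0, -2.0, 0.5])
    R, t, rmsd = pk.kabsch(P, Q, proper=True)
    assert rmsd < 1e-12
    assert np.allclose(R, R0, atol=1e-10)


def test_kabsch_improper_needed_for_mirror():
    rng = np.random.default_rng(6)
    P = rng.normal(size=(7, 3))
    Q = P * np.array([1, 1, -1])  # reflected
    _, _, rmsd_proper = pk.kabsch(P, Q, proper=True)
    _, _, rmsd_any = pk.kabsch(P, Q, proper=None)
    assert rmsd_any < 1e-12 < rmsd_proper


# --------------------------------------------------------------------------
# oracle equivalence on small clusters
# --------------------------------------------------------------------------

def _cluster_pairs(toy_p1, toy_p21c, decoy):
    jittered, _ = synth.perturb(toy_p1, jitter=0.04, seed=3)
    strained, _ = synth.perturb(toy_p21c, strain=0.015, jitter=0.02, seed=4)
    return [
        ("identity", toy_p1, toy_p1),
        ("jittered", toy_p1, jittered),
        ("decoy", toy_p1, decoy),
        ("p21c_strained", toy_p21c, strained),
    ]


def test_small_cluster_results_equal_exhaustive_oracle(toy_p1, toy_p21c,
                                                       decoy):
    for name, ref, probe in _cluster_pairs(toy_p1, toy_p21c, decoy):
        ref_cluster = cr.build_cluster(ref, 4)
        probe_cluster = cr.build_cluster(probe, 4)
        got = pk.compare_clusters(ref_cluster, probe_cluster, SMALL)
        n_want, rmsd_want = oracle_compare_clusters(ref_cluster,
                                                    probe_cluster, SMALL)
        assert got.n_matched == n_want, name
        if n_want >= 1:
            assert got.rmsd == pytest.approx(rmsd_want, abs=1e-8), name


def test_crystal_level_identity_small_shell(toy_p21c):
    m = pk.compare_packing(toy_p21c, toy_p21c, SMALL)
    assert (m.n_matched, m.rmsd) == (4, pytest.approx(0.0, abs=1e-10))


# --------------------------------------------------------------------------
# full-shell behaviour
# --------------------------------------------------------------------------

def test_identity_full_shell(toy_p1):
    m = pk.compare_packing(toy_p1, toy_p1, pk.ToleranceSpec(n_molecules=30))
    assert m.n_matched == 30
    assert m.rmsd == pytest.approx(0.0, abs=1e-10)


def test_jitter_continuity(toy_p1):
    sigma = 0.03
    probe, _ = synth.perturb(toy_p1, jitter=sigma, seed=9)
    m = pk.compare_packing(toy_p1, probe, pk.ToleranceSpec(n_molecules=15))
    assert m.n_matched == 15
    assert m.rmsd <= 3.0 * sigma  # empirical continuity constant


def test_tolerance_monotonicity(toy_p1, decoy):
    tight = pk.ToleranceSpec(0.10, 10.0, 10)
    loose = pk.ToleranceSpec(0.35, 35.0, 10)
    for probe in (toy_p1, decoy):
        n_tight = pk.compare_packing(toy_p1, probe, tight).n_matched
        n_loose = pk.compare_packing(toy_p1, probe, loose).n_matched
        assert n_tight <= n_loose


def test_supercell_invariance(toy_p21c):
    tol = pk.ToleranceSpec(n_molecules=8)
    base = pk.compare_packing(toy_p21c, toy_p21c, tol)
    sc = cr.make_supercell(toy_p21c, 2, 1, 1)
    m = pk.compare_packing(toy_p21c, sc, tol)
    assert m.n_matched == base.n_matched == 8
    assert m.rmsd == pytest.approx(base.rmsd, abs=1e-8)


def test_unrelated_pair_stays_partial(toy_p1, decoy):
    scan = pk.cluster_size_scan(toy_p1, decoy, [4, 8, 12],
                                pk.ToleranceSpec(n_molecules=4))
    fractions = [m.n_matched / n for n, m in scan]
    # an unrelated packing never approaches a full match: the matched
    # fraction stagnates at a small value as the cluster grows
    assert all(f <= 0.5 for f in fractions)
    counts = [m.n_matched for _, m in scan]
    assert counts == sorted(counts)  # n_matched itself is non-decreasing


def test_conformer_pair_no_full_match(conformer_pair):
    a, b = conformer_pair
    tol = pk.ToleranceSpec(n_molecules=10)
    m = pk.compare_packing(a, b, tol)
    assert m.n_matched < 10
    assert pk.compare_packing(a, a, tol).n_matched == 10


def test_trial_cap_raises_loudly(toy_p1):
    with pytest.raises(pk.ComparisonLimitError):
        pk.compare_packing(toy_p1, toy_p1,
                           pk.ToleranceSpec(n_molecules=10, trial_cap=3))


def test_cluster_size_scan_identity_and_horizon(toy_p1):
    scan = pk.cluster_size_scan(toy_p1, toy_p1, [5, 10, 20])
    assert all(m.n_matched == n for n, m in scan)
    assert pk.full_match_horizon(scan) == 20
    with pytest.raises(ValueError):
        pk.cluster_size_scan(toy_p1, toy_p1, [10, 5])


# --------------------------------------------------------------------------
# deduplication
# --------------------------------------------------------------------------

def test_dedupe_jittered_copies_form_one_cluster(toy_p1):
    landscape = [toy_p1]
    for seed in range(4):
        s, _ = synth.perturb(toy_p1, jitter=0.01, seed=seed)
        landscape.append(s)
    ids = pk.dedupe_landscape(landscape, pk.ToleranceSpec(n_molecules=10),
                              rmsd_threshold=0.5)
    assert len(set(ids)) == 1


def test_dedupe_recovers_planted_partition():
    _, landscape, truth = synth.make_landscape(
        10, seed=21, n_matches=0, decoy_clusters=[3, 2])
    ids = pk.dedupe_landscape(landscape, pk.ToleranceSpec(n_molecules=8),
                              rmsd_threshold=0.8)
    got = sorted(sorted(i for i, c in enumerate(ids) if c == cid)
                 for cid in set(ids))
    assert got == truth["clusters"]


def test_invalid_tolerances_rejected():
    with pytest.raises(ValueError):
        pk.ToleranceSpec(dist_tol=1.5)
    with pytest.raises(ValueError):
        pk.ToleranceSpec(angle_tol=0.0)
    with pytest.raises(ValueError):
        pk.ToleranceSpec(n_molecules=0)
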