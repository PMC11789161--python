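"""COMPACK-style crystal packing similarity.

Two crystals are compared by overlaying ``n``-molecule coordination
clusters: the cluster around each symmetry-independent molecule of the
reference is matched against clusters of the probe, within a relative
centroid-centroid **distance tolerance** and an absolute **angle
tolerance**, and the result is the number of molecules that could be
overlaid together with the RMSD of a joint rigid-body superposition of the
matched (non-hydrogen) atoms.  Space-group symmetry and cell settings are
deliberately ignored, so missed symmetry or unconventional cells still
match.

Matching criterion
------------------
A trial fixes a central molecule pair, an atom mapping between them and a
seed rigid transform ``T0`` (Kabsch superposition of the central pair,
proper or — when inversion is allowed — improper).  A set of molecule
pairs ``{(ref_i, probe_i)}`` containing the central pair is admissible
when, with probe geometry expressed through ``T0``:

* for every two pairs the centroid-centroid distances agree relatively
  within ``dist_tol``;
* every inter-centroid vector agrees in direction within ``angle_tol``;
* within every matched pair the centroid-to-atom vectors agree in
  direction within ``angle_tol`` for some bond-graph isomorphism (this is
  what makes the criterion sensitive to molecular orientation, e.g. the
  inverted layer of a polytype).

``n_matched`` is the size of the largest admissible set over all trials;
the reported RMSD is the smallest joint-superposition RMSD among sets of
that size.  The correspondence search is a branch-and-bound over candidate
pairs with an explicit trial cap: exceeding the cap raises
:class:`ComparisonLimitError` rather than silently returning a partial
answer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .crystal import (CrystalStructure, Molecule, build_cluster,
                      perceive_molecules, symmetry_independent_molecules)


class ComparisonLimitError(RuntimeError):
    """The correspondence search exceeded its trial cap; the result would
    be unreliable, so no number is returned."""


@dataclass(frozen=True)
class ToleranceSpec:
    """Comparison tolerances.  Defaults follow the blind-test assessment
    protocol: 30-molecule shell, 35% distance and 35 degree angle
    tolerances, hydrogens excluded, molecular differences disallowed."""

    dist_tol: float = 0.35
    angle_tol: float = 35.0
    n_molecules: int = 30
    ignore_hydrogen: bool = True
    allow_molecular_differences: bool = False
    allow_inversion: bool = True
    trial_cap: int = 10_000_000

    def __post_init__(self):
        if not 0.0 < self.dist_tol < 1.0:
            raise ValueError("dist_tol must be in (0, 1)")
        if not 0.0 < self.angle_tol < 180.0:
            raise ValueError("angle_tol must be in (0, 180)")
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")


@dataclass
class PackingMatch:
    n_matched: int
    rmsd: float | None
    correspondence: list = field(default_factory=list)  # (ref cluster idx, probe cluster idx, atom map)
    transform: tuple | None = None  # (R, t) Cartesian: x_ref ~ R @ x_probe + t

    @property
    def is_full(self) -> bool:
        return self.rmsd is not None


# --------------------------------------------------------------------------
# rigid superposition
# --------------------------------------------------------------------------

def kabsch(P: np.ndarray, Q: np.ndarray, proper: bool | None = True):
    """Least-squares rigid superposition of P onto Q.

    Returns ``(R, t, rmsd)`` with ``R @ p + t`` closest to ``q`` in the
    least-squares sense.  ``proper=True`` forces det(R) = +1, ``False``
    forces an improper transform, ``None`` takes whichever is better.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(Vt.T @ U.T)
    D = np.eye(3)
    if proper is True and det < 0:
        D[2, 2] = -1.0
    elif proper is False and det > 0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


# --------------------------------------------------------------------------
# molecular equivalence
# --------------------------------------------------------------------------

def molecules_equivalent(m1: Molecule, m2: Molecule,
                         ignore_hydrogen: bool = True,
                         ignore_elements: bool = False,
                         max_mappings: int = 64) -> list:
    """Element-labelled bond-graph isomorphisms between two molecules.

    Returns a list of atom-index mappings (dict: m1 index -> m2 index over
    the compared atoms), empty when the molecules differ chemically.  All
    automorphism-related mappings are enumerated (up to ``max_mappings``)
    so downstream trials can try each.
    """
    g1 = m1.graph(ignore_hydrogen)
    g2 = m2.graph(ignore_hydrogen)
    if g1.number_of_nodes() != g2.number_of_nodes():
        return []
    if ignore_elements:
        node_match = None
    else:
        node_match = lambda a, b: a["element"] == b["element"]
    gm = nx.algorithms.isomorphism.GraphMatcher(g1, g2, node_match=node_match)
    out = []
    for mapping in gm.isomorphisms_iter():
        out.append(dict(mapping))
        if len(out) >= max_mappings:
            break
    return out


def _match_indices(m: Molecule, ignore_hydrogen: bool) -> list:
    return m.heavy_indices() if ignore_hydrogen else list(range(m.n_atoms))


def _match_centroid(m: Molecule, ignore_hydrogen: bool) -> np.ndarray:
    return m.coords[_match_indices(m, ignore_hydrogen)].mean(axis=0)


class _MappingCache:
    """Memoised bond-graph isomorphisms, keyed by the molecules' element
    sequences and bond lists (identical template copies share one entry)."""

    def __init__(self, tol: ToleranceSpec):
        self.tol = tol
        self._cache: dict = {}

    def mappings(self, m1: Molecule, m2: Molecule) -> list:
        key = (tuple(m1.elements), tuple(sorted(m1.bonds)),
               tuple(m2.elements), tuple(sorted(m2.bonds)))
        if key not in self._cache:
            self._cache[key] = molecules_equivalent(
                m1, m2, self.tol.ignore_hydrogen,
                ignore_elements=self.tol.allow_molecular_differences)
        return self._cache[key]


# --------------------------------------------------------------------------
# admissibility predicates
# --------------------------------------------------------------------------

def _vector_angle_ok(a: np.ndarray, b: np.ndarray, cos_tol: float) -> bool:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-9 or nb < 1e-9:
        return True
    return float(np.dot(a, b)) / (na * nb) >= cos_tol


def _orientation_ok(ref: Molecule, probe_t: np.ndarray, mapping: dict,
                    idx_ref: list, cen_ref: np.ndarray, cen_probe: np.ndarray,
                    cos_tol: float) -> bool:
    """Do the centroid-to-atom vectors of the mapped atoms agree in
    direction within the angle tolerance?"""
    for i in idx_ref:
        a = ref.coords[i] - cen_ref
        b = probe_t[mapping[i]] - cen_probe
        if not _vector_angle_ok(a, b, cos_tol):
            return False
    return True


def _pair_ssd(ref: Molecule, probe_t: np.ndarray, mapping: dict,
              idx_ref: list) -> float:
    d = 0.0
    for i in idx_ref:
        d += float(((ref.coords[i] - probe_t[mapping[i]]) ** 2).sum())
    return d


# --------------------------------------------------------------------------
# the comparison
# --------------------------------------------------------------------------

def compare_packing(ref: CrystalStructure, probe: CrystalStructure,
                    tol: ToleranceSpec = ToleranceSpec()) -> PackingMatch:
    """Overlay ``tol.n_molecules``-molecule clusters of two crystals.

    Returns the best :class:`PackingMatch` over all symmetry-independent
    central-molecule choices in both structures.  ``n_matched = 0`` means
    no chemically equivalent molecule pair exists.
    """
    n = tol.n_molecules
    cache = _MappingCache(tol)
    ref_mols = perceive_molecules(ref)
    probe_mols = perceive_molecules(probe)
    ref_centrals = symmetry_independent_molecules(ref)
    probe_centrals = symmetry_independent_molecules(probe)

    best = PackingMatch(0, None)
    budget = [tol.trial_cap]
    n_probe_cluster = max(n + 8, int(1.4 * n))
    probe_clusters: dict[int, list] = {}
    for rc in ref_centrals:
        ref_cluster = build_cluster(ref, n, rc, molecules=ref_mols)
        for pc in probe_centrals:
            if not cache.mappings(ref_cluster[0], probe_mols[pc]):
                continue
            if pc not in probe_clusters:
                probe_clusters[pc] = build_cluster(probe, n_probe_cluster, pc,
                                                   molecules=probe_mols)
            cand = _compare_clusters(ref_cluster, probe_clusters[pc], tol,
                                     cache, budget, best.n_matched,
                                     centrals=[0])
            best = _better(best, cand)
    return best


def compare_clusters(ref_cluster: list, probe_cluster: list,
                     tol: ToleranceSpec = ToleranceSpec()) -> PackingMatch:
    """Compare two explicit molecule clusters.  The first reference
    molecule is the central one; every probe molecule is tried as the
    probe central."""
    cache = _MappingCache(tol)
    return _compare_clusters(ref_cluster, probe_cluster, tol, cache,
                             [tol.trial_cap], 0,
                             centrals=list(range(len(probe_cluster))))


def _better(a: PackingMatch, b: PackingMatch) -> PackingMatch:
    if b.n_matched > a.n_matched:
        return b
    if b.n_matched == a.n_matched and b.rmsd is not None and (
            a.rmsd is None or b.rmsd < a.rmsd):
        return b
    return a


def _compare_clusters(ref_cluster, probe_cluster, tol, cache, budget,
                      best_so_far, centrals) -> PackingMatch:
    cos_tol = math.cos(math.radians(tol.angle_tol))
    ih = tol.ignore_hydrogen
    r0 = ref_cluster[0]
    idx_r0 = _match_indices(r0, ih)
    best = PackingMatch(0, None)

    cen_ref = np.array([_match_centroid(m, ih) for m in ref_cluster])
    dref = np.linalg.norm(cen_ref - cen_ref[0], axis=1)

    for p0_pos in centrals:
        p0 = probe_cluster[p0_pos]
        sigmas = cache.mappings(r0, p0)
        if not sigmas:
            continue
        for sigma in sigmas:
            parities = (True, False) if tol.allow_inversion else (True,)
            for parity in parities:
                P = p0.coords[[sigma[i] for i in idx_r0]]
                Q = r0.coords[idx_r0]
                R, t, _ = kabsch(P, Q, proper=parity)
                probe_t = [m.coords @ R.T + t for m in probe_cluster]
                cen_probe = np.array(
                    [pt[_match_indices(m, ih)].mean(axis=0)
                     for pt, m in zip(probe_t, probe_cluster)])
                if not _orientation_ok(r0, probe_t[p0_pos], sigma, idx_r0,
                                       cen_ref[0], cen_probe[p0_pos], cos_tol):
                    continue
                match = _grow(ref_cluster, probe_cluster, probe_t, cen_ref,
                              cen_probe, dref, p0_pos, sigma, parity, tol,
                              cache, cos_tol, budget, max(best.n_matched,
                                                          best_so_far))
                if match is not None:
                    match.transform = (R, t)
                    best = _better(best, match)
    return best


def _grow(ref_cluster, probe_cluster, probe_t, cen_ref, cen_probe, dref,
          p0_pos, sigma, parity, tol, cache, cos_tol, budget, best_so_far):
    """Branch-and-bound search for the largest admissible correspondence
    containing the central pair; returns the best match found or None."""
    ih = tol.ignore_hydrogen
    n_ref = len(ref_cluster)

    # candidate probe partners for each non-central reference molecule,
    # filtered by the central-pair checks
    candidates: list[list] = [[] for _ in range(n_ref)]
    for i in range(1, n_ref):
        ref_m = ref_cluster[i]
        idx_i = _match_indices(ref_m, ih)
        vi = cen_ref[i] - cen_ref[0]
        di = dref[i]
        for q in range(len(probe_cluster)):
            if q == p0_pos:
                continue
            dq = float(np.linalg.norm(cen_probe[q] - cen_probe[p0_pos]))
            if abs(dq - di) > tol.dist_tol * di:
                continue
            if not _vector_angle_ok(vi, cen_probe[q] - cen_probe[p0_pos], cos_tol):
                continue
            taus = cache.mappings(ref_m, probe_cluster[q])
            ok_taus = [tau for tau in taus
                       if _orientation_ok(ref_m, probe_t[q], tau, idx_i,
                                          cen_ref[i], cen_probe[q], cos_tol)]
            if ok_taus:
                best_tau = min(ok_taus, key=lambda tau: _pair_ssd(
                    ref_m, probe_t[q], tau, idx_i))
                candidates[i].append((q, ok_taus, best_tau))

    order = sorted(range(1, n_ref), key=lambda i: (dref[i], i))
    # sort candidate lists so the geometrically closest partner is tried
    # first; the greedy path then usually is the maximum
    for i in range(1, n_ref):
        candidates[i].sort(key=lambda c: _pair_ssd(
            ref_cluster[i], probe_t[c[0]], c[2],
            _match_indices(ref_cluster[i], ih)))

    compat_memo: dict = {}

    def compatible(i, q, j, s) -> bool:
        if q == s:
            return False
        key = (i, q, j, s) if i < j else (j, s, i, q)
        val = compat_memo.get(key)
        if val is None:
            dij = float(np.linalg.norm(cen_ref[i] - cen_ref[j]))
            dqs = float(np.linalg.norm(cen_probe[q] - cen_probe[s]))
            val = (abs(dqs - dij) <= tol.dist_tol * dij
                   and _vector_angle_ok(cen_ref[i] - cen_ref[j],
                                        cen_probe[q] - cen_probe[s], cos_tol))
            compat_memo[key] = val
        return val

    # exhaustive mode (small shells) also enumerates ties of maximum size,
    # so the reported RMSD is the true minimum over all maximum
    # correspondences; for large shells the branch-and-bound is exact in
    # n_matched and reports the RMSD of the first maximum found
    exhaustive = len(ref_cluster) <= 8
    best_n = [max(1, best_so_far)]
    best_sets: list = []
    chosen: list = []

    def dfs(k: int, live: list):
        # live[j] for j >= k: candidates of order[j] compatible with chosen
        budget[0] -= 1
        if budget[0] < 0:
            raise ComparisonLimitError(
                "packing comparison exceeded its trial cap; raise "
                "ToleranceSpec.trial_cap for an exact answer")
        size = 1 + len(chosen)
        if size > best_n[0]:
            best_n[0] = size
            best_sets.clear()
        if size == best_n[0] and len(best_sets) < 500:
            best_sets.append(list(chosen))
        if k == len(order):
            return
        bound = size + sum(1 for j in range(k, len(order)) if live[j])
        if bound < best_n[0] or (not exhaustive and bound == best_n[0]):
            return
        i = order[k]
        for q, ok_taus, best_tau in live[k]:
            chosen.append((i, q, best_tau))
            newlive = list(live)
            for j in range(k + 1, len(order)):
                if live[j]:
                    newlive[j] = [c for c in live[j]
                                  if compatible(order[j], c[0], i, q)]
            dfs(k + 1, newlive)
            chosen.pop()
        dfs(k + 1, live)  # leave order[k] unmatched

    dfs(0, [candidates[i] for i in order])
    n_matched = best_n[0]
    if n_matched <= best_so_far and best_so_far > 0 and not best_sets:
        return None

    # evaluate RMSD of each maximum set found, keep the smallest
    ih_idx0 = _match_indices(ref_cluster[0], ih)
    best_match = None
    for st in best_sets:
        pairs = [(0, p0_pos, sigma)] + st
        P, Q = [], []
        for i, q, tau in pairs:
            idx = _match_indices(ref_cluster[i], ih)
            Q.append(ref_cluster[i].coords[idx])
            P.append(probe_cluster[q].coords[[tau[a] for a in idx]])
        P = np.vstack(P)
        Q = np.vstack(Q)
        proper = None if tol.allow_inversion else True
        R, t, rmsd = kabsch(P, Q, proper=proper)
        if best_match is None or rmsd < best_match.rmsd:
            best_match = PackingMatch(
                n_matched, rmsd,
                correspondence=[(i, q, dict(tau)) for i, q, tau in pairs],
                transform=(R, t))
    return best_match


# --------------------------------------------------------------------------
# scans and deduplication
# --------------------------------------------------------------------------

def cluster_size_scan(ref: CrystalStructure, probe: CrystalStructure,
                      sizes, tol: ToleranceSpec = ToleranceSpec()) -> list:
    """Compare at a series of shell sizes (ascending); returns
    ``[(n, PackingMatch)]``.  The largest ``n`` with a full-shell match is
    the scale up to which the two packings are indistinguishable."""
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("sizes must be ascending")
    out = []
    for n in sizes:
        t = ToleranceSpec(tol.dist_tol, tol.angle_tol, n, tol.ignore_hydrogen,
                          tol.allow_molecular_differences, tol.allow_inversion,
                          tol.trial_cap)
        out.append((n, compare_packing(ref, probe, t)))
    return out


def full_match_horizon(scan: list) -> int | None:
    """Largest shell size in a scan result at which the match is full."""
    horizon = None
    for n, match in scan:
        if match.n_matched == n:
            horizon = n
    return horizon


def dedupe_landscape(structures: list, tol: ToleranceSpec = ToleranceSpec(),
                     rmsd_threshold: float = 1.0) -> list:
    """Partition a landscape by packing similarity.

    Structures are in one cluster when connected by a chain of full-shell
    matches with RMSD below ``rmsd_threshold`` (single linkage).  Returns a
    cluster id per structure; ids are assigned so that each cluster's
    representative (lowest energy if energies are present, else first by
    input order) gets the smallest member index.
    """
    n = len(structures)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            m = compare_packing(structures[i], structures[j], tol)
            if m.n_matched == tol.n_molecules and m.rmsd is not None \
                    and m.rmsd < rmsd_threshold:
                parent[find(j)] = find(i)

    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)

    def rep(members):
        energies = [structures[i].meta.get("energy") for i in members]
        if all(e is not None for e in energies):
            return min(members, key=lambda i: (structures[i].meta["energy"], i))
        return members[0]

    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    ids = [0] * n
    for cid, members in enumerate(ordered):
        r = rep(members)
        for i in members:
            ids[i] = cid
        ids[r] = cid  # representative recorded via cluster order
    return ids
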