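"""Synthetic crystal fixtures with known ground truth.

Generators for every study condition the comparison pipeline has to handle:
near-duplicate structures (lattice strain + atomic jitter), layered
polytypes with a period-``m`` inverted layer, two-component disorder,
planted CSP landscapes with decoys, and multi-stoichiometry cocrystal
energy tables.  Everything is deterministic given ``(spec, seed)``; each
generator draws from its own named substream so adding one generator never
shifts another's output.

Template molecules are hard-coded idealized geometries (6-20 heavy atoms,
standard bond lengths); no chemistry toolkit is involved.  The key
templates:

``tiny4``    S-C-N-O chain, chiral, no automorphisms — fast exhaustive tests.
``ring6``    planar asymmetric 6-ring (pyridinone-like), no automorphisms —
             the polytype layer unit (its point inversion is visible as an
             in-plane reorientation).
``core_sub`` ring6 core with a 3-carbon chain substituent — core-only
             comparison and disorder fixtures (variant ``core_sub_b`` flips
             the chain to the other face).
``diamine``  N-C-C-N — second component for cocrystal fixtures.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .crystal import (AtomSite, CrystalStructure, LatticeCell, SymOp,
                      expand_to_cell, perceive_molecules, spacegroup_symops)

MIN_INTERMOLECULAR = 2.0  # A; steric validity floor for generated fixtures


def rng_stream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from a base seed."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(name.encode())])


# --------------------------------------------------------------------------
# template molecules (Cartesian A, centred on centroid)
# --------------------------------------------------------------------------

def _hexagon(r=1.39):
    return [(r * math.cos(math.radians(60 * i)), r * math.sin(math.radians(60 * i)), 0.0)
            for i in range(6)]


def _centred(elements, coords):
    c = np.asarray(coords, float)
    return elements, c - c.mean(axis=0)


_ring = _hexagon()
_oxy = (2.75 * math.cos(math.radians(120)), 2.75 * math.sin(math.radians(120)), 0.0)
# out-of-plane O for the substituted templates, so the molecule has
# off-plane features besides the flexible chain
_oxy3d = (_oxy[0], _oxy[1], 0.80)
_att = np.array(_ring[4])
_c7 = _att + np.array([math.cos(math.radians(240)), math.sin(math.radians(240)), 0.0]) * 1.50
_c8 = _c7 + np.array([0.45, -0.90, 1.15])
_c9 = _c8 + np.array([-0.90, -0.60, 1.00])


def rotate_about_axis(points, origin, axis, angle_deg):
    """Rodrigues rotation of ``points`` about the line through ``origin``
    along ``axis`` by ``angle_deg``."""
    k = np.asarray(axis, float)
    k = k / np.linalg.norm(k)
    th = math.radians(angle_deg)
    p = np.asarray(points, float) - origin
    rot = (p * math.cos(th) + np.cross(k, p) * math.sin(th)
           + k * (p @ k)[:, None] * (1 - math.cos(th)))
    return rot + origin


CHAIN_TORSION_DEG = 120.0  # conformer B: chain rotated about the C4-C7 bond
_c8b, _c9b = rotate_about_axis([_c8, _c9], _c7, _c7 - _att, CHAIN_TORSION_DEG)

TEMPLATES: dict[str, tuple] = {
    "tiny4": _centred(
        ["S", "C", "N", "O"],
        [(-0.8, 1.2, 0.9), (0.0, 0.0, 0.0), (1.40, 0.0, 0.0), (2.10, 1.05, 0.30)]),
    "ring6": _centred(
        ["N", "C", "C", "C", "C", "C", "O"],
        _ring + [_oxy]),
    "core_sub": _centred(
        ["N", "C", "C", "C", "C", "C", "O", "C", "C", "C"],
        _ring + [_oxy3d, tuple(_c7), tuple(_c8), tuple(_c9)]),
    "core_sub_b": _centred(
        ["N", "C", "C", "C", "C", "C", "O", "C", "C", "C"],
        _ring + [_oxy3d, tuple(_c7), tuple(_c8b), tuple(_c9b)]),
    "diamine": _centred(
        ["N", "C", "C", "N"],
        [(0.0, 0.0, 0.0), (1.40, 0.0, 0.0), (1.90, 1.30, 0.20), (3.30, 1.30, 0.20)]),
}

CORE_SUB_CHAIN = nx.Graph()
CORE_SUB_CHAIN.add_nodes_from([(0, {"element": "C"}), (1, {"element": "C"}),
                               (2, {"element": "C"})])
CORE_SUB_CHAIN.add_edges_from([(0, 1), (1, 2)])


def rotation_matrix(angles) -> np.ndarray:
    """Intrinsic z-y-x Euler rotation from three angles in degrees."""
    az, ay, ax = (math.radians(a) for a in angles)
    cz, sz = math.cos(az), math.sin(az)
    cy, sy = math.cos(ay), math.sin(ay)
    cx, sx = math.cos(ax), math.sin(ax)
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    return rz @ ry @ rx


@dataclass
class Placement:
    """One molecule in the asymmetric unit: centroid (fractional) and an
    orientation, given either as Euler angles (degrees) or a 3x3 matrix."""

    position: tuple = (0.5, 0.5, 0.5)
    orientation: object = (0.0, 0.0, 0.0)
    template: str | None = None  # overrides FixtureSpec.template
    invert: bool = False

    def matrix(self) -> np.ndarray:
        m = np.asarray(self.orientation, float)
        if m.shape == (3, 3):
            R = m
        else:
            R = rotation_matrix(self.orientation)
        return -R if self.invert else R


@dataclass
class FixtureSpec:
    template: str = "ring6"
    spacegroup: object = "P 1"  # H-M symbol, IT number, or list of SymOp
    cell: tuple = (8.0, 8.0, 4.5, 90.0, 90.0, 90.0)
    placements: list = field(default_factory=lambda: [Placement()])
    name: str = "toy"


class StericClashError(ValueError):
    pass


def make_toy_crystal(spec: FixtureSpec, validate: bool = True) -> CrystalStructure:
    """Place template molecules in the asymmetric unit of the requested
    space group.  Raises :class:`StericClashError` (reporting the closest
    contact) if symmetry-expanded molecules approach below 2.0 A."""
    cell = LatticeCell(*spec.cell)
    if isinstance(spec.spacegroup, list):
        symops = list(spec.spacegroup)
    else:
        symops = spacegroup_symops(spec.spacegroup)
    sites = []
    for p_idx, pl in enumerate(spec.placements):
        elements, coords = TEMPLATES[pl.template or spec.template]
        R = pl.matrix()
        cart = coords @ R.T + cell.to_cart(pl.position)
        for a_idx, (el, x) in enumerate(zip(elements, cell.to_frac(cart))):
            sites.append(AtomSite(f"{el}{p_idx}_{a_idx}", el, tuple(np.mod(x, 1.0))))
    s = CrystalStructure(cell, symops, sites, {"name": spec.name})
    if validate:
        from .crystal import NonMolecularSolidError
        try:
            d, pair = min_intermolecular_distance(s)
        except NonMolecularSolidError:
            raise StericClashError(
                f"{spec.name}: molecules fused across cell boundaries "
                "(contact below the bonding cutoff, < 2.0 A)")
        if d < MIN_INTERMOLECULAR:
            raise StericClashError(
                f"{spec.name}: intermolecular contact {pair[0]}...{pair[1]} "
                f"at {d:.2f} A < {MIN_INTERMOLECULAR} A")
    return s


def min_intermolecular_distance(s: CrystalStructure,
                                component: str = "all-major") -> tuple:
    """Closest contact between distinct molecules over periodic images."""
    mols = perceive_molecules(s, component)
    mat = s.cell.matrix
    coords = [m.coords for m in mols]
    labels = [m.labels for m in mols]
    best = (math.inf, ("", ""))
    shifts = [np.array([i, j, k], float) @ mat.T
              for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    for mi in range(len(mols)):
        for mj in range(len(mols)):
            for sh in shifts:
                if mi == mj and not sh.any():
                    continue
                diff = coords[mi][:, None, :] - (coords[mj] + sh)[None, :, :]
                dist = np.linalg.norm(diff, axis=2)
                k = np.unravel_index(np.argmin(dist), dist.shape)
                if dist[k] < best[0]:
                    best = (float(dist[k]), (labels[mi][k[0]], labels[mj][k[1]]))
    return best


# --------------------------------------------------------------------------
# perturbation
# --------------------------------------------------------------------------

def perturb(s: CrystalStructure, strain: float = 0.0, jitter: float = 0.0,
            seed: int = 0) -> tuple:
    """Strained and/or jittered copy of a structure.

    ``strain`` is an isotropic fractional expansion of the cell lengths
    (fractional coordinates unchanged); ``jitter`` is the standard
    deviation (A) of an isotropic Gaussian displacement applied to every
    asymmetric-unit site in Cartesian space.  Returns
    ``(structure, max_displacement)``.
    """
    rng = rng_stream(seed, "perturb")
    cell = s.cell.scaled(1.0 + strain)
    max_disp = 0.0
    sites = []
    for site in s.sites:
        cart = cell.to_cart(site.frac)
        disp = rng.normal(0.0, jitter, 3) if jitter > 0 else np.zeros(3)
        max_disp = max(max_disp, float(np.linalg.norm(disp)))
        f = cell.to_frac(cart + disp)
        sites.append(AtomSite(site.label, site.element, tuple(np.mod(f, 1.0)),
                              site.occupancy, site.disorder_group))
    out = CrystalStructure(cell, list(s.symops), sites,
                           {**s.meta, "name": s.name + "_pert"})
    return out, max_disp


# --------------------------------------------------------------------------
# polytypes
# --------------------------------------------------------------------------

@dataclass
class LayerSpec:
    template: str = "ring6"
    a: float = 8.0
    b: float = 8.0
    spacing: float = 4.5  # interlayer distance along c
    # out-of-plane tilt (degrees about the in-plane y axis) so that point
    # inversion of a layer moves atoms along the stacking axis and the two
    # polytypes differ in Bragg intensities, not just molecular orientation
    tilt: float = 18.0


def make_polytypes(layer: LayerSpec, period: int) -> tuple:
    """Uniform stacking versus the polytype with every ``period``-th layer
    inverted.

    Both are built from bit-identical layers (one molecule per a x b cell,
    flat in the layer plane) so that any cluster avoiding an inverted layer
    cannot distinguish them; the polytype cell is ``period`` layers tall
    with layer 0 point-inverted.
    """
    if period < 2:
        raise ValueError("polytype period must be >= 2")
    # every layer holds one molecule at in-plane position (u, u); the
    # inverted layer is produced by point inversion through the layer's
    # cell origin, which both inverts the molecule and moves it to
    # (1-u, 1-u) — as in a real inverted stacking layer
    u = 0.35
    orient = (0.0, layer.tilt, 0.0)
    uniform = make_toy_crystal(FixtureSpec(
        template=layer.template, spacegroup="P 1",
        cell=(layer.a, layer.b, layer.spacing, 90, 90, 90),
        placements=[Placement(position=(u, u, 0.5), orientation=orient)],
        name=f"uniform_{layer.template}"))
    placements = [Placement(position=((1 - u, 1 - u, (i + 0.5) / period)
                                      if i == 0 else
                                      (u, u, (i + 0.5) / period)),
                            orientation=orient, invert=(i == 0))
                  for i in range(period)]
    polytype = make_toy_crystal(FixtureSpec(
        template=layer.template, spacegroup="P 1",
        cell=(layer.a, layer.b, layer.spacing * period, 90, 90, 90),
        placements=placements, name=f"polytype_{period}"))
    return uniform, polytype


# --------------------------------------------------------------------------
# disorder
# --------------------------------------------------------------------------

def make_disorder_pair(occupancies=(0.6, 0.4),
                       cell=(11.0, 11.0, 7.5, 90, 90, 90)) -> tuple:
    """A crystal whose substituent chain is disordered over two sites.

    Returns ``(disordered, component_a, component_b)`` where the components
    are the ordered structures the generator planted; ``split_disorder`` of
    the first must recover the other two atom-for-atom.
    """
    if not math.isclose(sum(occupancies), 1.0, abs_tol=1e-9):
        raise ValueError("disorder occupancies must sum to 1")
    comp_a = make_toy_crystal(FixtureSpec(
        template="core_sub", spacegroup="P 1", cell=cell,
        placements=[Placement(position=(0.5, 0.5, 0.5))],
        name="ordered_core_sub"))
    # conformer B in the same frame: rotate the chain of the placed
    # structure about its attachment bond (shared core stays identical)
    lat = comp_a.cell
    cart = np.array([lat.to_cart(site.frac) for site in comp_a.sites])
    att, c7 = cart[4], cart[7]  # ring attachment atom and first chain atom
    rotated = rotate_about_axis(cart[-2:], c7, c7 - att, CHAIN_TORSION_DEG)
    cart_b = cart.copy()
    cart_b[-2:] = rotated
    comp_b = CrystalStructure(lat, list(comp_a.symops), [
        AtomSite(site.label, site.element,
                 tuple(np.mod(lat.to_frac(xyz), 1.0)))
        for site, xyz in zip(comp_a.sites, cart_b)],
        {"name": "ordered_core_sub_b"})
    if occupancies[1] == 0.0:
        return comp_a, comp_a, comp_a

    shared = len(comp_a.sites) - 2  # all but the two rotated chain atoms
    sites = []
    for i, site in enumerate(comp_a.sites):
        if i < shared:
            sites.append(AtomSite(site.label, site.element, site.frac))
        else:
            sites.append(AtomSite(site.label + "A", site.element, site.frac,
                                  occupancies[0], "1"))
    for i, site in enumerate(comp_b.sites):
        if i >= shared:
            sites.append(AtomSite(site.label + "B", site.element, site.frac,
                                  occupancies[1], "2"))
    disordered = CrystalStructure(comp_a.cell, list(comp_a.symops), sites,
                                  {"name": "disordered_core_sub"})
    return disordered, comp_a, comp_b


# --------------------------------------------------------------------------
# landscapes
# --------------------------------------------------------------------------

# decoys must sit at a volume-normalized PDD distance above this margin
# from every packing they are planted against.  Full-shell packing matches
# with overlay RMSD below 1 A are only seen well below ~0.45 A in this
# metric, so 0.65 A keeps decoys outside the match protocol's acceptance
# region with a comfortable margin.
DECOY_MIN_PDD = 0.65

DECOY_PDD_K = 100


def _fingerprint(s: CrystalStructure):
    """(PDD, cell volume) pair; volume-normalized distances between two
    fingerprints follow by scaling one PDD with the cube root of the
    volume ratio (an isotropic rescale scales every distance)."""
    from . import pdd as _pdd
    return _pdd.compute_pdd(s, DECOY_PDD_K), s.cell.volume


def _fp_distance_exceeds(fp_a, fp_b, threshold: float) -> bool:
    """Is the volume-normalized PDD distance above ``threshold``?

    Uses a Kantorovich lower bound first (for any column c the map
    row -> row[c] is 1-Lipschitz under the L-infinity ground cost, so the
    difference of weighted column means bounds the EMD from below); the
    exact transportation solve only runs when the bound is inconclusive.
    """
    from . import pdd as _pdd
    (ma, va), (mb, vb) = fp_a, fp_b
    f = (vb / va) ** (1.0 / 3.0)
    da = ma.distances * f
    lb = np.abs(ma.weights @ da - mb.weights @ mb.distances).max()
    if lb > threshold:
        return True
    scaled = _pdd.PDDMatrix(ma.weights, da, ma.k)
    return _pdd.pdd_distance(scaled, mb) > threshold


def _random_decoy(template: str, rng: np.random.Generator, name: str,
                  base_cell=(9.0, 9.0, 6.0),
                  avoid_pdds: list | None = None,
                  min_pdd: float = DECOY_MIN_PDD):
    """A sterically valid random packing, returned as ``(structure, pdd)``.

    When ``avoid_pdds`` fingerprints are given, candidates whose
    volume-normalized PDD distance to any of them falls below ``min_pdd``
    are rejected, so a decoy is certifiably a different packing and not an
    accidental near-duplicate.
    """
    for attempt in range(200):
        cell = (base_cell[0] * rng.uniform(0.85, 1.35),
                base_cell[1] * rng.uniform(0.85, 1.35),
                base_cell[2] * rng.uniform(0.95, 1.6),
                90.0, 90.0, rng.uniform(80.0, 100.0))
        pl = Placement(position=tuple(rng.uniform(0, 1, 3)),
                       orientation=tuple(rng.uniform(0, 360, 3)))
        try:
            s = make_toy_crystal(FixtureSpec(
                template=template, spacegroup="P 1", cell=cell,
                placements=[pl], name=name))
        except StericClashError:
            continue
        fp = _fingerprint(s)
        if avoid_pdds and not all(_fp_distance_exceeds(t, fp, min_pdd)
                                  for t in avoid_pdds):
            continue
        return s, fp
    raise RuntimeError("could not place a sterically valid, distinct decoy")


def make_decoy(seed: int, template: str = "ring6", name: str = "decoy",
               avoid: list | None = None) -> CrystalStructure:
    """One random, sterically valid packing; with ``avoid`` structures
    given, certified distinct from each of them (PDD distance above twice
    the match cutoff)."""
    rng = rng_stream(seed, "decoy")
    avoid_pdds = [_fingerprint(s) for s in avoid] if avoid else None
    return _random_decoy(template, rng, name, avoid_pdds=avoid_pdds)[0]


def make_landscape(n: int, seed: int, template: str = "ring6",
                   n_matches: int = 1, match_jitter: float = 0.02,
                   match_strain: float = 0.005, match_rank: int | None = None,
                   decoy_clusters: list | None = None) -> tuple:
    """A planted CSP landscape.

    Returns ``(experimental, structures, truth)``.  ``structures`` holds
    ``n`` entries with ``rank`` (1-based) and pseudo-``energy`` metadata:
    ``n_matches`` perturbed copies of the designated experimental structure
    (jitter ``match_jitter`` A, strain ``match_strain``) and random decoys,
    optionally grouped into near-duplicate clusters per ``decoy_clusters``
    (list of cluster sizes).  ``truth`` records, by final list position, the
    planted match indices, the duplicate-cluster partition and the rank of
    the best match.
    """
    rng = rng_stream(seed, "landscape")
    exp = make_toy_crystal(FixtureSpec(
        template=template, spacegroup="P 1", cell=(8.6, 9.4, 6.2, 90, 90, 94),
        placements=[Placement(position=(0.3, 0.4, 0.5),
                              orientation=(20.0, 35.0, 10.0))],
        name="experimental"))
    entries: list[CrystalStructure] = []
    clusters: list[list[int]] = []
    for i in range(n_matches):
        m, _ = perturb(exp, strain=match_strain, jitter=match_jitter,
                       seed=int(rng.integers(2**31)))
        m.meta["name"] = f"match_{i}"
        entries.append(m)
    match_count = len(entries)
    plan = list(decoy_clusters or [])
    # decoys must always be distinct from the experimental packing; they
    # must also be pairwise distinct when a duplicate-cluster plan is
    # given (the planted partition is then ground truth for dedupe) —
    # without a plan, pairwise avoidance would needlessly exhaust the
    # sampling space on large landscapes
    avoid_pdds = [_fingerprint(exp)]
    track_parents = decoy_clusters is not None
    while len(entries) < n:
        k = plan.pop(0) if plan else 1
        k = min(k, n - len(entries))
        parent, parent_pdd = _random_decoy(template, rng,
                                           f"decoy_{len(entries)}",
                                           avoid_pdds=avoid_pdds)
        if track_parents:
            avoid_pdds.append(parent_pdd)
        members = []
        for j in range(k):
            if j == 0:
                d = parent.copy()
            else:
                d, _ = perturb(parent, jitter=0.02,
                               seed=int(rng.integers(2**31)))
            d.meta["name"] = f"decoy_{len(entries)}"
            members.append(len(entries))
            entries.append(d)
        clusters.append(members)

    order = list(rng.permutation(n))
    if match_rank is not None:
        order.remove(0)
        order.insert(match_rank - 1, 0)
    shuffled = [entries[i] for i in order]
    pos_of = {old: new for new, old in enumerate(order)}
    for rank, s in enumerate(shuffled, start=1):
        s.meta["rank"] = rank
        s.meta["energy"] = -100.0 + 0.5 * rank + float(rng.normal(0, 0.05))
    truth = {
        "match_indices": sorted(pos_of[i] for i in range(match_count)),
        "clusters": sorted(sorted(pos_of[i] for i in c) for c in clusters),
        "match_ranks": sorted(pos_of[i] + 1 for i in range(match_count)),
    }
    return exp, shuffled, truth


def make_shared_landscapes(n_a: int, n_b: int, n_shared: int, seed: int,
                           template: str = "ring6") -> tuple:
    """Two landscapes that share exactly ``n_shared`` planted packings
    (identical structures present in both); all other members are mutually
    distinct decoys.  Returns ``(landscape_a, landscape_b, truth)``."""
    rng = rng_stream(seed, "shared-landscapes")
    shared: list = []
    avoid_pdds: list = []
    for i in range(n_shared):
        s, m = _random_decoy(template, rng, f"shared_{i}",
                             avoid_pdds=avoid_pdds)
        shared.append(s)
        avoid_pdds.append(m)
    a = [s.copy() for s in shared]
    b = [s.copy() for s in shared]
    while len(a) < n_a:
        s, m = _random_decoy(template, rng, f"a_{len(a)}",
                             avoid_pdds=avoid_pdds)
        a.append(s)
        avoid_pdds.append(m)
    while len(b) < n_b:
        s, m = _random_decoy(template, rng, f"b_{len(b)}",
                             avoid_pdds=avoid_pdds)
        b.append(s)
        avoid_pdds.append(m)
    rng.shuffle(a)
    rng.shuffle(b)
    for coll in (a, b):
        for rank, s in enumerate(coll, start=1):
            s.meta["rank"] = rank
    truth = {
        "shared_a": sorted(i for i, s in enumerate(a) if s.name.startswith("shared")),
        "shared_b": sorted(i for i, s in enumerate(b) if s.name.startswith("shared")),
    }
    return a, b, truth


# --------------------------------------------------------------------------
# stoichiometry hull datasets
# --------------------------------------------------------------------------

def make_hull_dataset(stable: list, candidates: list | None = None,
                      margin: float = 1.0, depth: float = 8.0,
                      n_decoys_per: int = 3, seed: int = 0) -> tuple:
    """Energy table for a two-component system with a planted stable set.

    ``stable`` lists the (x, y) stoichiometries that must lie on the lower
    hull; their normalized formation energies are placed on a strictly
    convex curve (depth ``depth`` kJ/mol at equimolar), so each is a hull
    vertex by construction.  Every other candidate stoichiometry receives
    structures strictly above the hull by at least ``margin`` kJ/mol.
    Returns ``(rows, e_a, e_b, truth)`` where rows are dicts with keys
    ``id, x, y, energy`` (energy per formula unit, kJ/mol).
    """
    rng = rng_stream(seed, "hull")
    candidates = candidates or [(1, 3), (1, 2), (1, 1), (2, 1), (3, 1)]
    for st in stable:
        if st not in candidates:
            candidates = candidates + [st]
    e_a = float(rng.uniform(-120.0, -80.0))
    e_b = float(rng.uniform(-120.0, -80.0))
    d = depth + float(rng.uniform(0.0, 4.0))

    def curve(comp: float) -> float:
        return -4.0 * d * comp * (1.0 - comp)

    hull_pts = sorted([(0.0, 0.0), (1.0, 0.0)]
                      + [(y / (x + y), curve(y / (x + y))) for x, y in stable])

    def hull_value(comp: float) -> float:
        for (c0, v0), (c1, v1) in zip(hull_pts, hull_pts[1:]):
            if c0 - 1e-12 <= comp <= c1 + 1e-12:
                t = 0.0 if c1 == c0 else (comp - c0) / (c1 - c0)
                return v0 + t * (v1 - v0)
        raise ValueError(comp)

    rows = []
    for x, y in candidates:
        comp = y / (x + y)
        n_struct = 1 + n_decoys_per
        for j in range(n_struct):
            if (x, y) in stable and j == 0:
                deltaf = curve(comp)
            else:
                deltaf = hull_value(comp) + margin + float(rng.uniform(0.0, 6.0))
            energy = deltaf * (x + y) + x * e_a + y * e_b
            rows.append({"id": f"{x}{y}_{j}", "x": x, "y": y,
                         "energy": float(energy)})
    truth = {"stable": sorted(set(stable)), "e_a": e_a, "e_b": e_b}
    return rows, e_a, e_b, truth
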