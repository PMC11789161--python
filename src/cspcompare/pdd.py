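"""Pointwise distance distributions (PDD) and Earth Mover's Distance.

The PDD of a crystal is a weighted ``N x k`` matrix: one row per atomic
environment in the unit cell, holding the ordered distances to the ``k``
nearest neighbours in the infinite crystal; identical rows are collapsed
with summed weights.  It is invariant under any change of unit-cell
setting (isometry invariant), which makes it a cheap, reliable structure
fingerprint.  Two PDDs are compared with the Earth Mover's Distance using
the L-infinity metric between rows as ground cost; an isotropic volume
normalization of the reference cell absorbs thermal expansion before the
comparison.  The match cutoff used for landscape coverage is 0.225 A at
``k = 100``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import cKDTree

from .crystal import CrystalStructure, LatticeCell, expand_to_cell

DEFAULT_K = 100
DEFAULT_CUTOFF = 0.225  # A
ROW_COLLAPSE_TOL = 1e-4  # A, L-infinity; below CIF coordinate precision


@dataclass
class PDDMatrix:
    weights: np.ndarray  # (m,), sums to 1
    distances: np.ndarray  # (m, k), each row non-decreasing
    k: int

    def __post_init__(self):
        self.weights = np.asarray(self.weights, float)
        self.distances = np.asarray(self.distances, float)
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("PDD weights must sum to 1")
        if (np.diff(self.distances, axis=1) < -1e-12).any():
            raise ValueError("PDD rows must be non-decreasing")

    @property
    def n_rows(self) -> int:
        return len(self.weights)


def compute_pdd(s: CrystalStructure, k: int = DEFAULT_K,
                heavy_only: bool = False,
                collapse_tol: float = ROW_COLLAPSE_TOL) -> PDDMatrix:
    """PDD of a crystal: per unit-cell atom, the ``k`` nearest-neighbour
    distances in the infinite crystal.

    The periodic search radius is grown until the k-th neighbour of every
    atom is provably inside the searched region.  Occupancies weight the
    rows (for ordered structures all weights are equal); rows equal within
    ``collapse_tol`` (L-infinity) are merged.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    atoms = expand_to_cell(s)
    if heavy_only:
        atoms = [a for a in atoms if not a.is_hydrogen]
    if not atoms:
        raise ValueError("no atoms to fingerprint")
    frac = np.array([a.frac for a in atoms])
    w = np.array([a.occupancy for a in atoms])
    mat = s.cell.matrix
    hmin = float(s.cell.heights().min())
    home = frac @ mat.T

    radius = 1
    while True:
        shifts = np.array([(i, j, l)
                           for i in range(-radius, radius + 1)
                           for j in range(-radius, radius + 1)
                           for l in range(-radius, radius + 1)])
        pts = (frac[None, :, :] + shifts[:, None, :]).reshape(-1, 3) @ mat.T
        tree = cKDTree(pts)
        dist, _ = tree.query(home, k=k + 1)
        kth = dist[:, -1].max()
        if kth < radius * hmin - 1e-9:
            break
        radius += 1
        if radius > 40:
            raise RuntimeError("periodic neighbour search failed to converge")
    rows = dist[:, 1:]  # drop the zero self-distance

    # collapse equal rows (single linkage within the L-infinity tolerance;
    # equivalent rows need not be adjacent in any sort order)
    n = len(rows)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    if collapse_tol > 0:
        linf = np.abs(rows[:, None, :] - rows[None, :, :]).max(axis=2)
        for i, j in zip(*np.where(linf <= collapse_tol)):
            if i < j:
                parent[find(j)] = find(i)
    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    merged_rows = [rows[members].mean(axis=0) for members in groups.values()]
    merged_w = [w[members].sum() for members in groups.values()]

    order = np.lexsort(np.array(merged_rows).T[::-1])
    weights = np.array(merged_w)[order]
    return PDDMatrix(weights / weights.sum(),
                     np.array(merged_rows)[order], k)


def pdd_distance(p: PDDMatrix, q: PDDMatrix) -> float:
    """Earth Mover's Distance between two PDDs (exact transportation LP,
    L-infinity ground cost between rows)."""
    if p.k != q.k:
        raise ValueError("PDDs have different k")
    cost = np.abs(p.distances[:, None, :] - q.distances[None, :, :]).max(axis=2)
    return emd(p.weights, q.weights, cost)


def emd(wp: np.ndarray, wq: np.ndarray, cost: np.ndarray) -> float:
    """Exact Earth Mover's Distance between weighted point sets.

    Solves the transportation linear program with HiGHS; both weight
    vectors must sum to the same total (they are normalized here).
    """
    wp = np.asarray(wp, float)
    wq = np.asarray(wq, float)
    wp = wp / wp.sum()
    wq = wq / wq.sum()
    n, m = len(wp), len(wq)
    if n == 1:
        return float(cost[0] @ wq)
    if m == 1:
        return float(wp @ cost[:, 0])
    c = cost.reshape(-1)
    # row sums = wp, column sums = wq (one redundant constraint dropped)
    a_eq = []
    b_eq = []
    for i in range(n):
        row = np.zeros((n, m))
        row[i, :] = 1.0
        a_eq.append(row.reshape(-1))
        b_eq.append(wp[i])
    for j in range(m - 1):
        col = np.zeros((n, m))
        col[:, j] = 1.0
        a_eq.append(col.reshape(-1))
        b_eq.append(wq[j])
    res = linprog(c, A_eq=np.array(a_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transportation LP failed: {res.message}")
    return float(res.fun)


def volume_normalize(ref: CrystalStructure,
                     probe: CrystalStructure) -> CrystalStructure:
    """Isotropically expand (or shrink) the reference cell so its volume
    equals the probe's; angles and fractional coordinates unchanged.  This
    absorbs the thermal-expansion difference between an experimental
    structure and a lattice-energy-minimized prediction."""
    factor = (probe.cell.volume / ref.cell.volume) ** (1.0 / 3.0)
    return CrystalStructure(ref.cell.scaled(factor), list(ref.symops),
                            list(ref.sites), dict(ref.meta))


def is_pdd_match(ref: CrystalStructure, probe: CrystalStructure,
                 k: int = DEFAULT_K, cutoff: float = DEFAULT_CUTOFF,
                 heavy_only: bool = False,
                 volume_normalized: bool = True) -> bool:
    """Volume-normalize the reference, compute both PDDs at ``k`` and
    compare: match when the EMD does not exceed ``cutoff`` (default
    0.225 A, the strict landscape-coverage threshold)."""
    r = volume_normalize(ref, probe) if volume_normalized else ref
    return pdd_distance(compute_pdd(r, k, heavy_only),
                        compute_pdd(probe, k, heavy_only)) <= cutoff
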