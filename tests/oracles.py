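"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle recomputes a quantity by direct enumeration or a closed form,
sharing no search/solver code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np

from cspcompare.packing import ToleranceSpec, kabsch


# --------------------------------------------------------------------------
# exhaustive packing-correspondence oracle
# --------------------------------------------------------------------------

def _isomorphisms(m1, m2, ignore_h):
    g1, g2 = m1.graph(ignore_h), m2.graph(ignore_h)
    gm = nx.algorithms.isomorphism.GraphMatcher(
        g1, g2, node_match=lambda a, b: a["element"] == b["element"])
    return [dict(m) for m in gm.isomorphisms_iter()]


def oracle_compare_clusters(ref_cluster, probe_cluster, tol: ToleranceSpec):
    """Exhaustive correspondence search over all central pairs, atom
    mappings, seed parities and injective molecule assignments; returns
    ``(n_matched, best_rmsd)``.  Only usable for clusters of ~5 molecules."""
    cos_tol = math.cos(math.radians(tol.angle_tol))
    ih = tol.ignore_hydrogen

    def idx(m):
        return m.heavy_indices() if ih else list(range(m.n_atoms))

    def cen(coords, m):
        return coords[idx(m)].mean(axis=0)

    best_n = 0
    best_rmsd = None
    n_ref = len(ref_cluster)
    n_probe = len(probe_cluster)
    parities = (True, False) if tol.allow_inversion else (True,)

    for p0 in range(n_probe):
        for sigma in _isomorphisms(ref_cluster[0], probe_cluster[p0], ih):
            for parity in parities:
                r0 = ref_cluster[0]
                P = probe_cluster[p0].coords[[sigma[i] for i in idx(r0)]]
                Q = r0.coords[idx(r0)]
                R, t, _ = kabsch(P, Q, proper=parity)
                pt = [m.coords @ R.T + t for m in probe_cluster]
                cen_r = [cen(m.coords, m) for m in ref_cluster]
                cen_p = [cen(pt[q], probe_cluster[q]) for q in range(n_probe)]

                def ang_ok(a, b):
                    na, nb = np.linalg.norm(a), np.linalg.norm(b)
                    if na < 1e-9 or nb < 1e-9:
                        return True
                    return np.dot(a, b) / (na * nb) >= cos_tol

                def orient(i, q, tau):
                    for a in idx(ref_cluster[i]):
                        if not ang_ok(ref_cluster[i].coords[a] - cen_r[i],
                                      pt[q][tau[a]] - cen_p[q]):
                            return False
                    return True

                if not orient(0, p0, sigma):
                    continue

                # all per-pair feasible (q, tau) options for each ref mol
                options = []
                for i in range(1, n_ref):
                    opts = []
                    for q in range(n_probe):
                        if q == p0:
                            continue
                        for tau in _isomorphisms(ref_cluster[i],
                                                 probe_cluster[q], ih):
                            if orient(i, q, tau):
                                opts.append((q, tau))
                    options.append(opts)

                def pair_ok(i, q, j, s):
                    dij = np.linalg.norm(np.array(cen_r[i]) - cen_r[j])
                    dqs = np.linalg.norm(np.array(cen_p[q]) - cen_p[s])
                    return (abs(dqs - dij) <= tol.dist_tol * dij
                            and ang_ok(np.array(cen_r[i]) - cen_r[j],
                                       np.array(cen_p[q]) - cen_p[s]))

                refs = list(range(1, n_ref))
                for size in range(len(refs), -1, -1):
                    if best_n > size + 1:
                        break
                    for subset in itertools.combinations(refs, size):
                        pools = [options[i - 1] for i in subset]
                        for combo in itertools.product(*pools):
                            qs = [c[0] for c in combo]
                            if len(set(qs)) != len(qs):
                                continue
                            pairs = [(0, p0, sigma)] + [
                                (i, q, tau) for i, (q, tau)
                                in zip(subset, combo)]
                            ok = all(
                                pair_ok(pairs[a][0], pairs[a][1],
                                        pairs[b][0], pairs[b][1])
                                for a in range(len(pairs))
                                for b in range(a + 1, len(pairs)))
                            if not ok:
                                continue
                            Pj = np.vstack([
                                probe_cluster[q].coords[
                                    [tau[x] for x in idx(ref_cluster[i])]]
                                for i, q, tau in pairs])
                            Qj = np.vstack([ref_cluster[i].coords[
                                idx(ref_cluster[i])] for i, q, tau in pairs])
                            proper = None if tol.allow_inversion else True
                            _, _, rmsd = kabsch(Pj, Qj, proper=proper)
                            n = len(pairs)
                            if n > best_n or (n == best_n and
                                              (best_rmsd is None
                                               or rmsd < best_rmsd)):
                                if n > best_n:
                                    best_rmsd = rmsd
                                    best_n = n
                                else:
                                    best_rmsd = min(best_rmsd, rmsd)
    return best_n, best_rmsd


# --------------------------------------------------------------------------
# brute-force periodic neighbour distances (PDD rows)
# --------------------------------------------------------------------------

def brute_force_neighbour_rows(cell_matrix, frac_coords, k, reach=5):
    """k nearest-neighbour distances for every atom, by enumerating a
    (2*reach+1)^3 supercell directly."""
    frac = np.asarray(frac_coords, float)
    shifts = [np.array(s) for s in itertools.product(
        range(-reach, reach + 1), repeat=3)]
    pts = np.array([(f + s) @ np.asarray(cell_matrix).T
                    for s in shifts for f in frac])
    rows = []
    for f in frac:
        home = f @ np.asarray(cell_matrix).T
        d = np.linalg.norm(pts - home, axis=1)
        d = np.sort(d)
        rows.append(d[1:k + 1])  # drop self
    return np.array(rows)


# --------------------------------------------------------------------------
# exact transportation-problem oracle (EMD)
# --------------------------------------------------------------------------

def oracle_emd(wp, wq, cost):
    """EMD by enumerating basic feasible solutions of the transportation
    polytope (all spanning bases of size n+m-1).  Exponential; for tiny
    instances only."""
    wp = np.asarray(wp, float)
    wq = np.asarray(wq, float)
    wp = wp / wp.sum()
    wq = wq / wq.sum()
    n, m = len(wp), len(wq)
    cells = [(i, j) for i in range(n) for j in range(m)]
    nvar = n + m - 1
    best = None
    b = np.concatenate([wp, wq[:-1]])
    for basis in itertools.combinations(cells, nvar):
        A = np.zeros((nvar, nvar))
        for col, (i, j) in enumerate(basis):
            A[i, col] = 1.0
            if j < m - 1:
                A[n + j, col] = 1.0
        try:
            x = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            continue
        if (x < -1e-12).any():
            continue
        val = sum(cost[i][j] * xi for (i, j), xi in zip(basis, x))
        if best is None or val < best:
            best = val
    return best


# --------------------------------------------------------------------------
# O(n^2) lower-hull line test
# --------------------------------------------------------------------------

def oracle_lower_hull(xy, tol=1e-9):
    """Indices of lower-hull vertices by the pairwise line test: a point is
    a vertex iff no segment between two other points passes strictly below
    or through it, except at its own abscissa endpoints."""
    pts = np.asarray(xy, float)
    n = len(pts)
    out = []
    for i in range(n):
        xi, yi = pts[i]
        dominated = False
        # strictly lower duplicate-abscissa point dominates
        for j in range(n):
            if j != i and abs(pts[j, 0] - xi) <= tol and pts[j, 1] < yi - tol:
                dominated = True
        for j in range(n):
            for l in range(n):
                if i in (j, l) or j >= l:
                    continue
                x1, y1 = pts[j]
                x2, y2 = pts[l]
                if not (x1 - tol <= xi <= x2 + tol or
                        x2 - tol <= xi <= x1 + tol):
                    continue
                if abs(x2 - x1) <= tol:
                    continue
                t = (xi - x1) / (x2 - x1)
                if t < -tol or t > 1 + tol:
                    continue
                y_line = y1 + t * (y2 - y1)
                interior = tol < t < 1 - tol
                if y_line < yi - tol or (interior and y_line <= yi + tol):
                    dominated = True
        if not dominated:
            out.append(i)
    return out
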