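"""Cross-group landscape overlap and landscape deduplication.

Different structure-prediction groups submit ranked landscapes; the
question "how much of group i's landscape did group j also find" is
answered with a PDD coverage matrix: a query structure counts as covered
when any target structure is a PDD match (EMD at ``k = 100`` within
0.225 A after volume normalization).  Two modes: query top-100 vs target
top-100, or query top-100 vs the target's entire list.  The matrix is
generally asymmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import packing, pdd
from .crystal import CrystalStructure


@dataclass
class OverlapMatrix:
    groups: list
    mode: str  # "100v100" or "100vAll"
    values: np.ndarray  # percentages, entry (i, j) = % of i's queries in j
    cutoff: float
    k: int

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.groups, columns=self.groups)

    def plot(self, path=None, ax=None):
        """Heat-map rendering of the coverage matrix; a thin presentation
        layer — the numbers, not the picture, are the contract."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(1 + 0.5 * len(self.groups),) * 2)
        im = ax.imshow(self.values, vmin=0, vmax=100, cmap="viridis")
        ax.set_xticks(range(len(self.groups)), self.groups, rotation=90)
        ax.set_yticks(range(len(self.groups)), self.groups)
        ax.set_xlabel("target set")
        ax.set_ylabel("query set")
        ax.figure.colorbar(im, ax=ax, label="% of queries covered")
        ax.set_title(f"landscape coverage ({self.mode}, "
                     f"cutoff {self.cutoff} A)")
        if path is not None:
            ax.figure.savefig(path, bbox_inches="tight", dpi=150)
            plt.close(ax.figure)
        return ax


def _ranked(structures: list, group: str, need_ranks: bool) -> list:
    ranks = [s.meta.get("rank") for s in structures]
    if any(r is None for r in ranks):
        if need_ranks:
            raise ValueError(f"group {group!r}: missing rank metadata")
        return list(structures)
    return [s for _, s in sorted(zip(ranks, structures),
                                 key=lambda t: t[0])]


def overlap_matrix(landscapes: dict, mode: str = "100v100",
                   top: int = 100, k: int = pdd.DEFAULT_K,
                   cutoff: float = pdd.DEFAULT_CUTOFF,
                   heavy_only: bool = False) -> OverlapMatrix:
    """Pairwise landscape coverage.

    ``landscapes`` maps group label -> list of structures with ``rank``
    metadata.  Query set: the top-``top`` structures by rank (all of them
    when a group submitted fewer — the percentage denominator is the
    actual query size).  Target set: top-``top`` (mode ``100v100``) or the
    full list (mode ``100vAll``).
    """
    if mode not in ("100v100", "100vAll"):
        raise ValueError(f"unknown mode {mode!r}")
    groups = list(landscapes)
    ranked = {g: _ranked(landscapes[g], g, need_ranks=True) for g in groups}
    queries = {g: ranked[g][:top] for g in groups}
    targets = {g: (ranked[g][:top] if mode == "100v100" else ranked[g])
               for g in groups}

    # PDDs are cached per structure id; the query side is volume-normalized
    # against each target, so those are recomputed per pair
    target_pdds: dict = {}

    def target_pdd(s):
        key = id(s)
        if key not in target_pdds:
            target_pdds[key] = pdd.compute_pdd(s, k, heavy_only)
        return target_pdds[key]

    n = len(groups)
    values = np.zeros((n, n))
    for i, gi in enumerate(groups):
        for j, gj in enumerate(groups):
            q = queries[gi]
            hits = 0
            for s in q:
                for t in targets[gj]:
                    ref = pdd.volume_normalize(s, t)
                    dist = pdd.pdd_distance(
                        pdd.compute_pdd(ref, k, heavy_only), target_pdd(t))
                    if dist <= cutoff:
                        hits += 1
                        break
            values[i, j] = 100.0 * hits / len(q) if q else 0.0
    return OverlapMatrix(groups, mode, values, cutoff, k)


def dedupe(landscape: list, method: str = "pdd", threshold: float = None,
           tol: packing.ToleranceSpec = packing.ToleranceSpec(n_molecules=15),
           k: int = pdd.DEFAULT_K) -> dict:
    """Single-linkage duplicate clustering of one landscape.

    ``method="pdd"``: link structures whose PDD distance (after volume
    normalization) is below ``threshold`` (default 0.225 A).
    ``method="packing"``: link on full-shell packing match with RMSD below
    ``threshold`` (default 1.0 A).  Returns ``{"labels": cluster id per
    structure, "representatives": id -> index, "sizes": histogram}``;
    representatives are the lowest-energy members when energies exist.
    """
    n = len(landscape)
    if method == "pdd":
        threshold = pdd.DEFAULT_CUTOFF if threshold is None else threshold
        if threshold <= 0:
            raise ValueError("threshold must be positive")
        pdds = [pdd.compute_pdd(s, k) for s in landscape]
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
                ref = pdd.volume_normalize(landscape[i], landscape[j])
                d = pdd.pdd_distance(pdd.compute_pdd(ref, k), pdds[j])
                if d <= threshold:
                    parent[find(j)] = find(i)
        labels_raw = [find(i) for i in range(n)]
        remap: dict = {}
        labels = []
        for r in labels_raw:
            if r not in remap:
                remap[r] = len(remap)
            labels.append(remap[r])
    elif method == "packing":
        threshold = 1.0 if threshold is None else threshold
        labels = packing.dedupe_landscape(landscape, tol, threshold)
    else:
        raise ValueError(f"unknown dedupe method {method!r}")

    clusters: dict = {}
    for i, c in enumerate(labels):
        clusters.setdefault(c, []).append(i)
    reps = {}
    for c, members in clusters.items():
        energies = [landscape[i].meta.get("energy") for i in members]
        if all(e is not None for e in energies):
            reps[c] = min(members, key=lambda i: (landscape[i].meta["energy"], i))
        else:
            reps[c] = members[0]
    sizes: dict = {}
    for members in clusters.values():
        sizes[len(members)] = sizes.get(len(members), 0) + 1
    return {"labels": labels, "representatives": reps, "sizes": sizes}
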