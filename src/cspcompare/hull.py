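"""Convex-hull stability analysis for two-component (cocrystal) systems.

For candidate compounds A_x B_y the normalized formation energy

    deltaf = (E(AxBy) - x*E(A) - y*E(B)) / (x + y)

is plotted against the composition ``y / (x + y)``; the thermodynamically
stable stoichiometries are the vertices of the lower convex hull of these
points (a compound is stable iff its energy is below every isochemical
mixture of other phases).  Lattice energies stand in for free energies.
Energies are kJ/mol; ``deltaf`` is per molecule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

HULL_TOL = 1e-9  # kJ/mol; below this a point counts as on the hull


@dataclass
class CompositionPoint:
    x: float  # molecules of component A per formula unit
    y: float  # molecules of component B
    energy: float  # kJ/mol per formula unit
    deltaf: float  # normalized formation energy, kJ/mol per molecule
    label: str = ""

    @property
    def composition(self) -> float:
        return self.y / (self.x + self.y)

    @property
    def stoichiometry(self) -> str:
        def fmt(v):
            return str(int(v)) if float(v).is_integer() else f"{v:g}"
        return f"{fmt(self.x)}:{fmt(self.y)}"


def formation_energy(e_axby: float, e_a: float, e_b: float,
                     x: float, y: float) -> float:
    """Normalized formation energy per molecule.  ``e_a``/``e_b`` are the
    energies per molecule of the pure components."""
    if x == 0 and y == 0:
        raise ValueError("x and y cannot both be zero")
    return (e_axby - x * e_a - y * e_b) / (x + y)


def composition_point(e_axby: float, e_a: float, e_b: float,
                      x: float, y: float, label: str = "") -> CompositionPoint:
    return CompositionPoint(x, y, e_axby,
                            formation_energy(e_axby, e_a, e_b, x, y), label)


def _lower_hull(points: list) -> list:
    """Vertices of the lower convex hull of (composition, deltaf) points,
    left to right (monotone chain).  ``points`` must be sorted by
    composition with one point per composition."""
    hull: list = []
    for p in points:
        while len(hull) >= 2:
            (x1, y1), (x2, y2) = ((hull[-2].composition, hull[-2].deltaf),
                                  (hull[-1].composition, hull[-1].deltaf))
            x3, y3 = p.composition, p.deltaf
            # drop hull[-1] unless it turns strictly downward (left turn
            # keeps the chain convex from below); collinear points are
            # dropped, so interior edge points are not vertices
            cross = (x2 - x1) * (y3 - y1) - (y2 - y1) * (x3 - x1)
            if cross > HULL_TOL * max(1.0, abs(x3 - x1)):
                break
            hull.pop()
        hull.append(p)
    return hull


def _prepare(points: list) -> list:
    """Add missing pure-component endpoints (deltaf = 0 by construction)
    and keep the minimum-deltaf point per composition, sorted."""
    best: dict = {}
    for p in points:
        c = round(p.composition, 12)
        if c not in best or p.deltaf < best[c].deltaf:
            best[c] = p
    for c, x, y in ((0.0, 1.0, 0.0), (1.0, 0.0, 1.0)):
        if c not in best or best[c].deltaf > 0:
            best[c] = CompositionPoint(x, y, 0.0, 0.0, "pure-A" if c == 0 else "pure-B")
    return [best[c] for c in sorted(best)]


def stable_set(points: list) -> list:
    """Points on the lower convex hull of (composition, deltaf): the
    predicted stable phases.  Pure-component endpoints are always included
    (added at deltaf = 0 if absent); per composition only the lowest-energy
    point can be stable."""
    return _lower_hull(_prepare(points))


def energy_above_hull(p: CompositionPoint, hull: list) -> float:
    """Vertical distance (kJ/mol per molecule) of a point above the lower
    hull; zero exactly for stable points."""
    xs = [h.composition for h in hull]
    ys = [h.deltaf for h in hull]
    base = float(np.interp(p.composition, xs, ys))
    return max(0.0, p.deltaf - base)


@dataclass
class HullReport:
    points: list  # all CompositionPoints (min-energy per stoichiometry)
    hull: list  # the stable set
    above_hull: dict  # label -> energy above hull

    @property
    def stable_stoichiometries(self) -> list:
        return [p.stoichiometry for p in self.hull
                if p.x > 0 and p.y > 0]

    def boundary_cases(self, tol: float = 1e-6) -> list:
        """Non-vertex points lying within ``tol`` of the hull (degenerate:
        on a hull edge, so marginally stable)."""
        verts = {id(p) for p in self.hull}
        return [p.label for p in self.points
                if id(p) not in verts and self.above_hull[p.label] <= tol]


def hull_report(entries: list, e_a: float, e_b: float) -> HullReport:
    """Stability analysis of a cocrystal landscape.

    ``entries`` are dicts with keys ``id, x, y, energy`` (per formula
    unit); per stoichiometry only the minimum-energy structure defines the
    composition point.  ``e_a``/``e_b`` are the pure-component reference
    energies per molecule; they define the hull endpoints and must be
    supplied.
    """
    if e_a is None or e_b is None:
        raise ValueError("pure-component energies are required")
    best: dict = {}
    for row in entries:
        x, y = float(row["x"]), float(row["y"])
        if x == 0 and y == 0:
            raise ValueError(f"entry {row.get('id')}: empty stoichiometry")
        key = (x, y)
        if key not in best or row["energy"] < best[key]["energy"]:
            best[key] = row
    points = [composition_point(r["energy"], e_a, e_b, float(r["x"]),
                                float(r["y"]), str(r.get("id", "")))
              for r in best.values()]
    hull = stable_set(points)
    above = {p.label: energy_above_hull(p, hull) for p in points}
    return HullReport(sorted(points, key=lambda p: p.composition), hull, above)


def plot_hull(report: HullReport, path=None, ax=None):
    """Formation energy vs composition with the lower hull drawn through
    the stable phases."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter([p.composition for p in report.points],
               [p.deltaf for p in report.points], zorder=3,
               label="candidate structures")
    hx = [p.composition for p in report.hull]
    hy = [p.deltaf for p in report.hull]
    ax.plot(hx, hy, "-o", color="grey", zorder=2, label="convex hull")
    for p in report.hull:
        ax.annotate(p.stoichiometry, (p.composition, p.deltaf),
                    textcoords="offset points", xytext=(0, -12),
                    ha="center", fontsize=8)
    ax.set_xlabel("composition y/(x+y)")
    ax.set_ylabel(r"$\Delta_f$ (kJ/mol per molecule)")
    ax.legend()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


# --------------------------------------------------------------------------
# simpler literature criteria for cocrystal stability
# --------------------------------------------------------------------------

def additive_stability(e_axby: float, e_a: float, e_b: float,
                       x: float, y: float) -> float:
    """Energy of cocrystallization relative to the stoichiometric sum of
    the pure components (negative = favourable), per molecule.  Identical
    in value to :func:`formation_energy`; kept as the named single-compound
    criterion."""
    return formation_energy(e_axby, e_a, e_b, x, y)


def reaction_energy(e_product: float, x_p: float, y_p: float,
                    reactants: list) -> float:
    """Energy per molecule of forming a compound from an isochemical
    assemblage ``reactants = [(E, x, y, moles), ...]``; negative means the
    product is more stable than that particular mixture."""
    e_mix = sum(e * n for e, _, _, n in reactants)
    x_mix = sum(x * n for _, x, _, n in reactants)
    y_mix = sum(y * n for _, _, y, n in reactants)
    if not (np.isclose(x_mix, x_p) and np.isclose(y_mix, y_p)):
        raise ValueError("reactants are not isochemical with the product")
    return (e_product - e_mix) / (x_p + y_p)
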