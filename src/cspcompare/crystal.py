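"""Crystal data model: unit cells, symmetry operations, atom sites, CIF I/O,
symmetry expansion, periodic molecule perception and cluster construction.

Conventions shared by every module in the package:

* fractional coordinates live in ``[0, 1)``,
* Cartesian coordinates are in angstroms, right-handed, with **a** along
  ``x`` and **b** in the ``xy`` plane (the standard crystallographic
  orthogonalization),
* energies in ``meta`` are kJ/mol per formula unit.

Bond perception uses covalent radii (from gemmi's element table) plus a
0.4 A margin, the common crystallographic criterion.  Symmetry-equivalent
atom images closer than 0.3 A (Cartesian) are merged as special positions.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Callable, Iterable, Sequence

import gemmi
import networkx as nx
import numpy as np

BOND_MARGIN = 0.4  # A added to summed covalent radii
MERGE_TOL = 0.3  # A; special-position merge tolerance after expansion


class CifParseError(ValueError):
    """Raised when a CIF block lacks cell, coordinates or usable symmetry."""


class NonMolecularSolidError(ValueError):
    """Raised when a bonded network spans a lattice translation (polymer)."""


def covalent_radius(element: str) -> float:
    r = gemmi.Element(element).covalent_r
    if r <= 0:
        raise ValueError(f"no covalent radius for element {element!r}")
    return r


# --------------------------------------------------------------------------
# lattice
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeCell:
    """Unit-cell lengths (A) and angles (degrees)."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must be in (0, 180)")
        if self.volume <= 0 or not np.isfinite(self.volume):
            raise ValueError("cell is degenerate (non positive definite)")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 orthogonalization matrix; columns are the cell vectors, so
        ``cart = matrix @ frac``."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = math.sqrt(max(1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg, 0.0))
        return np.array(
            [
                [self.a, self.b * cg, self.c * cb],
                [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
                [0.0, 0.0, self.c * v / sg],
            ]
        )

    @property
    def inv_matrix(self) -> np.ndarray:
        return np.linalg.inv(self.matrix)

    def to_cart(self, frac) -> np.ndarray:
        return np.asarray(frac, float) @ self.matrix.T

    def to_frac(self, cart) -> np.ndarray:
        return np.asarray(cart, float) @ self.inv_matrix.T

    def heights(self) -> np.ndarray:
        """Perpendicular distances between the three families of lattice
        planes bounding the cell (used for safe periodic search radii)."""
        return 1.0 / np.linalg.norm(self.inv_matrix, axis=0)

    def scaled(self, factor: float) -> "LatticeCell":
        return LatticeCell(self.a * factor, self.b * factor, self.c * factor,
                           self.alpha, self.beta, self.gamma)


# --------------------------------------------------------------------------
# symmetry
# --------------------------------------------------------------------------

def _mod1(x: np.ndarray) -> np.ndarray:
    return np.mod(np.mod(np.asarray(x, float), 1.0), 1.0)


@dataclass(frozen=True)
class SymOp:
    """Space-group operation on fractional coordinates: x' = R x + t."""

    rot: tuple
    trans: tuple

    @classmethod
    def from_arrays(cls, rot, trans) -> "SymOp":
        rot = np.asarray(rot)
        if not np.allclose(rot, np.round(rot)):
            raise ValueError("rotation part must be integral")
        rot = np.round(rot).astype(int)
        if abs(round(np.linalg.det(rot))) != 1:
            raise ValueError("rotation determinant must be +/-1")
        trans = _mod1(np.asarray(trans, float))
        # snap to nearest 1/24 (all space-group translations are n/24 in
        # conventional settings); keeps composition closure exact
        trans = np.round(trans * 24.0) / 24.0
        trans = np.mod(trans, 1.0)
        return cls(tuple(map(tuple, rot.tolist())), tuple(trans.tolist()))

    @classmethod
    def identity(cls) -> "SymOp":
        return cls.from_arrays(np.eye(3, dtype=int), np.zeros(3))

    @classmethod
    def from_xyz(cls, triplet: str) -> "SymOp":
        op = gemmi.Op(triplet)
        return cls.from_arrays(np.array(op.rot) / 24.0, np.array(op.tran) / 24.0)

    @property
    def rotation(self) -> np.ndarray:
        return np.array(self.rot, dtype=int)

    @property
    def translation(self) -> np.ndarray:
        return np.array(self.trans, dtype=float)

    def apply(self, frac) -> np.ndarray:
        return np.asarray(frac, float) @ self.rotation.T + self.translation

    def compose(self, other: "SymOp") -> "SymOp":
        """self after other: x -> R1 (R2 x + t2) + t1."""
        return SymOp.from_arrays(self.rotation @ other.rotation,
                                 self.rotation @ other.translation + self.translation)

    def triplet(self) -> str:
        rot24 = (self.rotation * 24).tolist()
        tran24 = [int(round(t * 24)) for t in self.trans]
        op = gemmi.Op()
        op.rot = rot24
        op.tran = tran24
        return op.triplet()


def spacegroup_symops(name_or_number) -> list[SymOp]:
    """Look up a space group by Hermann-Mauguin symbol or IT number and
    return its operations (including centring translations)."""
    if isinstance(name_or_number, int):
        sg = gemmi.find_spacegroup_by_number(name_or_number)
    else:
        sg = gemmi.find_spacegroup_by_name(str(name_or_number))
    if sg is None:
        raise CifParseError(f"unrecognized space group: {name_or_number!r}")
    return [SymOp.from_xyz(op.triplet()) for op in sg.operations()]


# --------------------------------------------------------------------------
# sites and structures
# --------------------------------------------------------------------------

@dataclass
class AtomSite:
    label: str
    element: str
    frac: tuple
    occupancy: float = 1.0
    disorder_group: str | None = None

    def __post_init__(self):
        if not 0.0 < self.occupancy <= 1.0 + 1e-9:
            raise ValueError(f"occupancy of {self.label} outside (0, 1]")
        covalent_radius(self.element)  # validates the symbol
        self.frac = tuple(float(x) for x in self.frac)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


@dataclass
class CrystalStructure:
    """A crystal: cell, space-group operations and the asymmetric unit.

    ``meta`` may carry ``group`` (submitting group id), ``rank``, ``energy``
    (kJ/mol per formula unit), ``temperature`` (K), ``stoichiometry`` and
    ``name``.
    """

    cell: LatticeCell
    symops: list
    sites: list
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.symops:
            self.symops = [SymOp.identity()]

    def copy(self) -> "CrystalStructure":
        return CrystalStructure(self.cell, list(self.symops),
                                [replace(s) for s in self.sites], dict(self.meta))

    @property
    def name(self) -> str:
        return str(self.meta.get("name", "structure"))


# --------------------------------------------------------------------------
# CIF I/O
# --------------------------------------------------------------------------

_SYMOP_TAGS = ("_symmetry_equiv_pos_as_xyz", "_space_group_symop_operation_xyz")
_HM_TAGS = ("_symmetry_space_group_name_H-M", "_space_group_name_H-M_alt")
_IT_TAGS = ("_symmetry_Int_Tables_number", "_space_group_IT_number")


def _strip_su(text: str) -> float:
    """Parse a CIF number, dropping a parenthesised standard uncertainty."""
    return float(re.sub(r"\(\d+\)$", "", text.strip()))


def read_cif(path) -> list[CrystalStructure]:
    """Read every data block of a CIF file into :class:`CrystalStructure`.

    Symmetry is taken from an explicit operator loop when present, otherwise
    generated from the Hermann-Mauguin symbol or IT number.  Missing
    occupancies default to 1; ``_atom_site_disorder_group`` (prefixed by the
    assembly tag when one is given) populates ``disorder_group``.
    """
    doc = gemmi.cif.read_file(str(path))
    structures = []
    for block in doc:
        structures.append(_block_to_structure(block))
    if not structures:
        raise CifParseError(f"{path}: no data blocks")
    return structures


def _block_to_structure(block) -> CrystalStructure:
    def need(tag):
        val = block.find_value(tag)
        if val is None:
            raise CifParseError(f"block {block.name!r}: missing {tag}")
        return val

    cell = LatticeCell(*(_strip_su(need(f"_cell_{t}"))
                         for t in ("length_a", "length_b", "length_c",
                                   "angle_alpha", "angle_beta", "angle_gamma")))

    symops = None
    for tag in _SYMOP_TAGS:
        col = block.find_loop(tag)
        triplets = list(col)
        if triplets:
            symops = [SymOp.from_xyz(gemmi.cif.as_string(t)) for t in triplets]
            break
    if symops is None:
        for tag in _HM_TAGS + _IT_TAGS:
            val = block.find_value(tag)
            if val is not None:
                key = gemmi.cif.as_string(val)
                if tag in _IT_TAGS:
                    key = int(key)
                symops = spacegroup_symops(key)
                break
    if symops is None:
        raise CifParseError(f"block {block.name!r}: no symmetry loop, H-M symbol "
                            "or IT number")

    table = block.find("_atom_site_", ["label", "fract_x", "fract_y", "fract_z"])
    if len(table) == 0:
        raise CifParseError(f"block {block.name!r}: no atom site loop")
    # optional columns fetched row-wise via a second lookup
    opt = block.find("_atom_site_", ["label"])
    tags = [t for t in ("type_symbol", "occupancy", "disorder_group",
                        "disorder_assembly")
            if block.find_loop("_atom_site_" + t)]
    opt_table = block.find("_atom_site_", ["label"] + list(tags)) if tags else None

    sites = []
    rows_opt = {row.str(0): row for row in opt_table} if opt_table is not None else {}
    for row in table:
        label = row.str(0)
        frac = tuple(_strip_su(row[i + 1]) for i in range(3))
        element = _element_from_label(label)
        occ = 1.0
        group = None
        if label in rows_opt:
            orow = rows_opt[label]
            vals = {tag: orow.str(i + 1) for i, tag in enumerate(tags)}
            if vals.get("type_symbol"):
                element = _normalize_element(vals["type_symbol"])
            if vals.get("occupancy") not in (None, "", ".", "?"):
                occ = _strip_su(vals["occupancy"])
            g = vals.get("disorder_group")
            if g not in (None, "", ".", "?", "0"):
                asm = vals.get("disorder_assembly")
                group = f"{asm}.{g}" if asm not in (None, "", ".", "?") else g
        sites.append(AtomSite(label, element, _mod1(frac), occ, group))

    meta = {"name": block.name}
    for tag, key, conv in (("_cspcompare_group", "group", str),
                           ("_cspcompare_rank", "rank", int),
                           ("_cspcompare_energy", "energy", float),
                           ("_cspcompare_stoichiometry", "stoichiometry", str)):
        val = block.find_value(tag)
        if val is not None:
            meta[key] = conv(gemmi.cif.as_string(val))
    return CrystalStructure(cell, symops, sites, meta)


def _normalize_element(symbol: str) -> str:
    m = re.match(r"([A-Za-z]{1,2})", symbol.strip())
    if not m:
        raise CifParseError(f"bad element symbol {symbol!r}")
    s = m.group(1)
    return s[0].upper() + s[1:].lower()


def _element_from_label(label: str) -> str:
    m = re.match(r"([A-Za-z]{1,2})", label)
    if not m:
        raise CifParseError(f"cannot infer element from label {label!r}")
    cand = m.group(1)
    cand = cand[0].upper() + cand[1:].lower()
    if len(cand) == 2 and gemmi.Element(cand).covalent_r > 0 and cand not in ("Cn",):
        return cand
    return cand[0]


def write_cif(structures, path) -> None:
    """Write one or more structures as a multi-block CIF (core subset)."""
    if isinstance(structures, CrystalStructure):
        structures = [structures]
    lines = []
    for i, s in enumerate(structures):
        name = re.sub(r"\s+", "_", s.name) or f"block{i}"
        lines.append(f"data_{name}")
        c = s.cell
        for tag, val in (("length_a", c.a), ("length_b", c.b), ("length_c", c.c),
                         ("angle_alpha", c.alpha), ("angle_beta", c.beta),
                         ("angle_gamma", c.gamma)):
            lines.append(f"_cell_{tag} {val:.9f}")
        for tag, key in (("_cspcompare_group", "group"), ("_cspcompare_rank", "rank"),
                         ("_cspcompare_energy", "energy"),
                         ("_cspcompare_stoichiometry", "stoichiometry")):
            if key in s.meta:
                lines.append(f"{tag} {s.meta[key]}")
        lines.append("loop_")
        lines.append("_symmetry_equiv_pos_as_xyz")
        for op in s.symops:
            lines.append(f"'{op.triplet()}'")
        lines.append("loop_")
        for t in ("label", "type_symbol", "fract_x", "fract_y", "fract_z",
                  "occupancy", "disorder_group"):
            lines.append(f"_atom_site_{t}")
        for site in s.sites:
            g = site.disorder_group if site.disorder_group is not None else "."
            x, y, z = site.frac
            lines.append(f"{site.label} {site.element} {x:.9f} {y:.9f} {z:.9f} "
                         f"{site.occupancy:.6f} {g}")
        lines.append("")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))


# --------------------------------------------------------------------------
# symmetry expansion
# --------------------------------------------------------------------------

@dataclass
class ExpandedAtom:
    element: str
    frac: np.ndarray
    occupancy: float
    disorder_group: str | None
    site_label: str
    site_index: int

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


def expand_to_cell(s: CrystalStructure, merge_tol: float = MERGE_TOL) -> list[ExpandedAtom]:
    """Apply every symmetry operation to every site, reduce into [0,1) and
    merge coincident images within ``merge_tol`` A.

    The merge is global over images of the same element and disorder
    group: a molecule on a special position maps onto itself with atoms
    landing on images of *other* sites, and those duplicates must collapse
    too.
    """
    out: list[ExpandedAtom] = []
    mat = s.cell.matrix
    for idx, site in enumerate(s.sites):
        for op in s.symops:
            f = _mod1(op.apply(site.frac))
            dup = False
            for prev in out:
                if (prev.element != site.element
                        or prev.disorder_group != site.disorder_group):
                    continue
                d = f - prev.frac
                d -= np.round(d)
                if np.linalg.norm(mat @ d) < merge_tol:
                    dup = True
                    break
            if not dup:
                out.append(ExpandedAtom(site.element, f, site.occupancy,
                                        site.disorder_group, site.label, idx))
    return out


# --------------------------------------------------------------------------
# molecule perception
# --------------------------------------------------------------------------

@dataclass
class Molecule:
    """A connected, unwrapped molecule in Cartesian coordinates (A)."""

    elements: list
    coords: np.ndarray  # (n, 3) Cartesian
    labels: list  # source site labels
    bonds: list  # index pairs

    @property
    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def graph(self, ignore_hydrogen: bool = False) -> nx.Graph:
        g = nx.Graph()
        for i, el in enumerate(self.elements):
            if ignore_hydrogen and el in ("H", "D"):
                continue
            g.add_node(i, element=el)
        for i, j in self.bonds:
            if g.has_node(i) and g.has_node(j):
                g.add_edge(i, j)
        return g

    def formula(self) -> str:
        from collections import Counter
        cnt = Counter(self.elements)
        return "".join(f"{el}{cnt[el]}" for el in sorted(cnt))

    def species_key(self) -> str:
        """Hash identifying the chemical species (element-labelled graph)."""
        return self.formula() + ":" + nx.weisfeiler_lehman_graph_hash(
            self.graph(), node_attr="element")

    def heavy_indices(self) -> list:
        return [i for i, el in enumerate(self.elements) if el not in ("H", "D")]

    def translated(self, vec) -> "Molecule":
        return Molecule(list(self.elements), self.coords + np.asarray(vec, float),
                        list(self.labels), list(self.bonds))


def _select_component(atoms: Sequence[ExpandedAtom], component) -> list[ExpandedAtom]:
    groups = sorted({a.disorder_group for a in atoms if a.disorder_group is not None})
    if not groups or component == "all":
        return list(atoms)
    if component == "all-major":
        # keep untagged atoms plus, per assembly, the highest-occupancy group
        by_asm: dict[str, dict[str, float]] = {}
        for a in atoms:
            if a.disorder_group is None:
                continue
            asm = a.disorder_group.split(".")[0] if "." in a.disorder_group else ""
            by_asm.setdefault(asm, {})
            occ = by_asm[asm].setdefault(a.disorder_group, 0.0)
            by_asm[asm][a.disorder_group] = max(occ, a.occupancy)
        keep = set()
        for asm, occs in by_asm.items():
            best = max(sorted(occs), key=lambda g: occs[g])
            keep.add(best)
        return [a for a in atoms if a.disorder_group is None or a.disorder_group in keep]
    return [a for a in atoms if a.disorder_group is None or a.disorder_group == component]


def perceive_molecules(s: CrystalStructure, component: str = "all-major",
                       bond_margin: float = BOND_MARGIN) -> list[Molecule]:
    """Find the molecules of the crystal.

    Bonds join atoms whose minimum-image distance does not exceed the sum of
    covalent radii plus ``bond_margin``.  Each connected component of the
    periodic bond graph is unwrapped into a contiguous Cartesian object; the
    returned set contains one copy of each molecule per unit cell, shifted so
    its centroid lies in [0,1)^3 fractional.

    Raises :class:`NonMolecularSolidError` if a component is bonded to its
    own lattice translate (a polymer or framework).
    """
    atoms = _select_component(expand_to_cell(s), component)
    if not atoms:
        raise ValueError("expanded cell is empty")
    n = len(atoms)
    frac = np.array([a.frac for a in atoms])
    mat = s.cell.matrix
    radii = np.array([covalent_radius(a.element) for a in atoms])

    # periodic bond search over neighbouring cells
    shifts = np.array([(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
                       for k in (-1, 0, 1)])
    # edges: (i, j, shift) meaning atom j in cell `shift` bonds to atom i in cell 0
    edges = []
    cart0 = frac @ mat.T
    for sh in shifts:
        cart_sh = (frac + sh) @ mat.T
        diff = cart0[:, None, :] - cart_sh[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        cut = radii[:, None] + radii[None, :] + bond_margin
        ii, jj = np.where((dist <= cut) & (dist > 1e-6))
        for i, j in zip(ii.tolist(), jj.tolist()):
            edges.append((i, j, tuple(sh.tolist())))

    # connected components of the quotient graph, with integer cell shifts
    adj: dict[int, list] = {i: [] for i in range(n)}
    for i, j, sh in edges:
        adj[i].append((j, np.array(sh)))

    seen = np.full(n, -1)  # component id
    offsets = np.zeros((n, 3))  # integer cell shift assigned during unwrap
    comps = []
    for start in range(n):
        if seen[start] >= 0:
            continue
        cid = len(comps)
        stack = [start]
        seen[start] = cid
        offsets[start] = 0
        members = [start]
        while stack:
            i = stack.pop()
            for j, sh in adj[i]:
                want = offsets[i] + sh
                if seen[j] < 0:
                    seen[j] = cid
                    offsets[j] = want
                    members.append(j)
                    stack.append(j)
                elif seen[j] == cid and not np.allclose(offsets[j], want):
                    raise NonMolecularSolidError(
                        "bonded network spans a lattice translation; "
                        "not a molecular solid")
        comps.append(members)

    mols = []
    for members in comps:
        members = sorted(members)
        f = np.array([frac[i] + offsets[i] for i in members])
        cart = f @ mat.T
        # shift so the centroid is inside the home cell
        cen_frac = s.cell.to_frac(cart.mean(axis=0))
        shift = np.floor(cen_frac)
        cart = cart - (shift @ mat.T)
        local = {g: k for k, g in enumerate(members)}
        bonds = sorted({(min(local[i], local[j]), max(local[i], local[j]))
                        for i, j, sh in edges
                        if i in local and j in local
                        and np.allclose(offsets[j] + np.array(sh), offsets[i])
                        # bond is internal when shift-consistent
                        })
        # recompute bonds from unwrapped geometry (simpler and exact)
        bonds = []
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                d = np.linalg.norm(cart[a] - cart[b])
                ra = covalent_radius(atoms[members[a]].element)
                rb = covalent_radius(atoms[members[b]].element)
                if d <= ra + rb + bond_margin:
                    bonds.append((a, b))
        mols.append(Molecule([atoms[i].element for i in members], cart,
                             [atoms[i].site_label for i in members], bonds))
    mols.sort(key=lambda m: (m.species_key(), tuple(np.round(m.centroid, 6))))
    return mols


def z_prime(s: CrystalStructure, component: str = "all-major") -> dict:
    """Z' per chemical species: molecules in the unit cell divided by the
    space-group order.  Fractional for molecules on special positions."""
    mols = perceive_molecules(s, component)
    nsym = len(s.symops)
    counts: dict[str, int] = {}
    formulas: dict[str, str] = {}
    for m in mols:
        k = m.species_key()
        counts[k] = counts.get(k, 0) + 1
        formulas[k] = m.formula()
    return {formulas[k]: Fraction(c, nsym) for k, c in counts.items()}


# --------------------------------------------------------------------------
# disorder
# --------------------------------------------------------------------------

def split_disorder(s: CrystalStructure) -> list[CrystalStructure]:
    """Split a disordered structure into one fully ordered structure per
    disorder component; shared (untagged) atoms appear in every component
    and all occupancies are reset to 1."""
    groups = sorted({site.disorder_group for site in s.sites
                     if site.disorder_group is not None})
    if len(groups) < 2:
        return [s]
    out = []
    for g in groups:
        sites = [replace(site, occupancy=1.0)
                 for site in s.sites
                 if site.disorder_group is None or site.disorder_group == g]
        comp = CrystalStructure(s.cell, list(s.symops), sites,
                                {**s.meta, "name": f"{s.name}_{g}",
                                 "disorder_component": g})
        _check_component_complete(comp)
        out.append(comp)
    return out


def _check_component_complete(s: CrystalStructure) -> None:
    try:
        mols = perceive_molecules(s, component="all")
    except NonMolecularSolidError:
        raise
    for m in mols:
        if m.n_atoms == 1 and len(s.sites) > 1 and m.elements[0] not in ("H", "D"):
            raise ValueError(
                f"disorder component {s.meta.get('disorder_component')!r} leaves "
                "an isolated heavy atom: chemically incomplete")


# --------------------------------------------------------------------------
# atom stripping
# --------------------------------------------------------------------------

def strip_atoms(obj, predicate):
    """Remove atoms matched by ``predicate`` from a structure or molecule.

    ``predicate`` may be an element symbol (``"H"``), a set of symbols, or a
    callable taking ``(element, label)``.  Raises if it would remove
    everything or matches nothing meaningful (must be a proper subset).
    """
    if isinstance(predicate, str):
        elements = {predicate}
        pred = lambda el, lab: el in elements
    elif isinstance(predicate, (set, frozenset, list, tuple)):
        elements = set(predicate)
        pred = lambda el, lab: el in elements
    else:
        pred = predicate

    if isinstance(obj, CrystalStructure):
        keep = [site for site in obj.sites if not pred(site.element, site.label)]
        if not keep:
            raise ValueError("predicate removes all atoms")
        if len(keep) == len(obj.sites):
            return obj.copy()
        return CrystalStructure(obj.cell, list(obj.symops),
                                [replace(site) for site in keep], dict(obj.meta))
    if isinstance(obj, Molecule):
        idx = [i for i in range(obj.n_atoms)
               if not pred(obj.elements[i], obj.labels[i])]
        if not idx:
            raise ValueError("predicate removes all atoms")
        remap = {old: new for new, old in enumerate(idx)}
        bonds = [(remap[i], remap[j]) for i, j in obj.bonds
                 if i in remap and j in remap]
        return Molecule([obj.elements[i] for i in idx], obj.coords[idx],
                        [obj.labels[i] for i in idx], bonds)
    raise TypeError(f"cannot strip atoms from {type(obj)!r}")


def strip_fragment(s: CrystalStructure, fragment: nx.Graph,
                   component: str = "all-major") -> CrystalStructure:
    """Remove every connected fragment of the structure's molecules matching
    ``fragment`` (an element-labelled graph) by subgraph isomorphism.

    The matched fragments' source site labels are removed from the
    asymmetric unit, so symmetry-equivalent copies vanish consistently.
    """
    mols = perceive_molecules(s, component)
    doomed: set[str] = set()
    for m in mols:
        g = m.graph()
        gm = nx.algorithms.isomorphism.GraphMatcher(
            g, fragment, node_match=lambda a, b: a["element"] == b["element"])
        used: set[int] = set()
        for mapping in gm.subgraph_isomorphisms_iter():
            atoms = set(mapping.keys())
            if atoms & used:
                continue
            # only remove fragments attached to the rest by a single bond
            boundary = sum(1 for i, j in m.bonds
                           if (i in atoms) != (j in atoms))
            if boundary <= 1:
                used |= atoms
        doomed |= {m.labels[i] for i in used}
    if not doomed:
        return s.copy()
    keep = [site for site in s.sites if site.label not in doomed]
    if not keep:
        raise ValueError("fragment removal leaves no atoms")
    return CrystalStructure(s.cell, list(s.symops), [replace(x) for x in keep],
                            dict(s.meta))


# --------------------------------------------------------------------------
# clusters
# --------------------------------------------------------------------------

def build_cluster(s: CrystalStructure, n: int, central: int = 0,
                  molecules: list | None = None,
                  component: str = "all-major") -> list[Molecule]:
    """The central molecule plus its ``n - 1`` nearest neighbours by
    centroid-centroid distance over all periodic images.

    Ties in distance are broken by (species hash, lattice image vector) so
    the cluster is deterministic across platforms.
    """
    if n < 1:
        raise ValueError("cluster size must be >= 1")
    mols = perceive_molecules(s, component) if molecules is None else molecules
    if central >= len(mols):
        raise IndexError("central molecule index out of range")
    c0 = mols[central].centroid
    mat = s.cell.matrix
    heights = s.cell.heights()
    hmin = float(heights.min())

    radius = 1
    while True:
        cand = []
        rng = range(-radius, radius + 1)
        for m_idx, m in enumerate(mols):
            for i in rng:
                for j in rng:
                    for k in rng:
                        if m_idx == central and i == j == k == 0:
                            continue
                        vec = np.array([i, j, k], float) @ mat.T
                        d = float(np.linalg.norm(m.centroid + vec - c0))
                        cand.append((d, m.species_key(), (i, j, k), m_idx))
        cand.sort(key=lambda t: (round(t[0], 9), t[1], t[2]))
        if len(cand) >= n - 1:
            dmax = cand[n - 2][0] if n > 1 else 0.0
            if dmax <= radius * hmin - 1e-9 or radius >= 12:
                break
        radius += 1

    cluster = [mols[central]]
    for d, key, (i, j, k), m_idx in cand[: n - 1]:
        vec = np.array([i, j, k], float) @ mat.T
        cluster.append(mols[m_idx].translated(vec))
    return cluster


def symmetry_independent_molecules(s: CrystalStructure,
                                   component: str = "all-major") -> list[int]:
    """Indices (into ``perceive_molecules`` output) of one molecule per
    symmetry orbit, identified by the multiset of source site labels."""
    mols = perceive_molecules(s, component)
    seen: set[tuple] = set()
    out = []
    for i, m in enumerate(mols):
        key = tuple(sorted(m.labels))
        if key not in seen:
            seen.add(key)
            out.append(i)
    return out


def make_supercell(s: CrystalStructure, na: int, nb: int, nc: int) -> CrystalStructure:
    """Re-express the structure in an (na x nb x nc) supercell in P1."""
    atoms = expand_to_cell(s)
    cell = LatticeCell(s.cell.a * na, s.cell.b * nb, s.cell.c * nc,
                       s.cell.alpha, s.cell.beta, s.cell.gamma)
    scale = np.array([na, nb, nc], float)
    sites = []
    for idx, a in enumerate(atoms):
        for i in range(na):
            for j in range(nb):
                for k in range(nc):
                    f = (np.asarray(a.frac) + (i, j, k)) / scale
                    sites.append(AtomSite(f"{a.site_label}_{idx}_{i}{j}{k}",
                                          a.element, tuple(f), a.occupancy,
                                          a.disorder_group))
    return CrystalStructure(cell, [SymOp.identity()], sites,
                            {**s.meta, "name": f"{s.name}_super{na}{nb}{nc}"})
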