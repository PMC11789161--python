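"""The structure-assessment decision pipeline.

A predicted structure matches an experimental form when

(a) the de Gelder similarity of their simulated powder patterns exceeds a
    gate (default 0.70) — a cheap geometric filter;
(b) a packing comparison overlays the full molecule shell (default 30
    molecules, 35%/35 degree tolerances, no hydrogens, no molecular
    differences); and
(c) the overlay RMSD is below a threshold (default 1.0 A).

Disordered experimental structures are split into ordered components and
each component is assessed separately.  A core-only mode strips a
substituent fragment from both structures first (the powder gate is
skipped there: the pattern of a stripped structure is not physical).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

from . import packing, powder
from .crystal import CrystalStructure, split_disorder, strip_atoms, strip_fragment
from .packing import ComparisonLimitError, PackingMatch, ToleranceSpec


@dataclass(frozen=True)
class ProtocolParams:
    gate: float = 0.70  # de Gelder similarity gate
    rmsd_threshold: float = 1.0  # A
    tolerances: ToleranceSpec = field(default_factory=ToleranceSpec)
    window: float = powder.DEFAULT_WINDOW
    two_theta_range: tuple = powder.DEFAULT_RANGE
    step: float = powder.DEFAULT_STEP
    # gate on as-given cells (False) or volume-normalized cells (True);
    # thermal expansion between experiment and prediction can otherwise
    # shift every peak
    normalize_cells: bool = False


@dataclass
class MatchReport:
    gate_similarity: float | None
    packing: PackingMatch | None
    verdict: str  # match | no-match | gate-fail | limit-error
    component: str | None = None
    mode: str = "all-atoms"

    @property
    def is_match(self) -> bool:
        return self.verdict == "match"


def _gate(pred: CrystalStructure, exp: CrystalStructure,
          params: ProtocolParams) -> float:
    a, b = pred, exp
    if params.normalize_cells:
        from .pdd import volume_normalize
        b = volume_normalize(exp, pred)
    kw = dict(two_theta_range=params.two_theta_range, step=params.step)
    return powder.degelder_similarity(powder.simulate_pattern(a, **kw),
                                      powder.simulate_pattern(b, **kw),
                                      params.window)


def _assess_one(pred: CrystalStructure, exp: CrystalStructure,
                params: ProtocolParams, component: str | None,
                skip_gate: bool, mode: str) -> MatchReport:
    sim = None
    if not skip_gate:
        sim = _gate(pred, exp, params)
        if sim < params.gate:
            return MatchReport(sim, None, "gate-fail", component, mode)
    try:
        match = packing.compare_packing(exp, pred, params.tolerances)
    except ComparisonLimitError:
        return MatchReport(sim, None, "limit-error", component, mode)
    full = (match.n_matched == params.tolerances.n_molecules
            and match.rmsd is not None
            and match.rmsd < params.rmsd_threshold)
    return MatchReport(sim, match, "match" if full else "no-match",
                       component, mode)


def assess_match(pred: CrystalStructure, exp: CrystalStructure,
                 params: ProtocolParams = ProtocolParams(),
                 skip_gate: bool = False) -> list:
    """Assess one prediction against one experimental form.

    Returns one :class:`MatchReport` per disorder component of the
    experimental structure (a single report for ordered structures).
    """
    components = split_disorder(exp)
    out = []
    for comp in components:
        tag = comp.meta.get("disorder_component")
        out.append(_assess_one(pred, comp, params, tag, skip_gate,
                               "all-atoms"))
    return out


def best_report(reports: list) -> MatchReport:
    """The most favourable report (match beats no-match beats gate-fail;
    ties by lower RMSD)."""
    rank = {"match": 0, "no-match": 1, "limit-error": 2, "gate-fail": 3}

    def key(r):
        rmsd = r.packing.rmsd if r.packing and r.packing.rmsd is not None \
            else float("inf")
        return (rank[r.verdict], rmsd)

    return min(reports, key=key)


def core_only_assess(pred: CrystalStructure, exp: CrystalStructure,
                     core_selector,
                     params: ProtocolParams = ProtocolParams()) -> list:
    """Strip a substituent from both structures, then assess the packing of
    the cores.  ``core_selector`` is an element predicate (as accepted by
    ``strip_atoms``) or a fragment graph (removed by subgraph match); the
    powder gate is skipped."""
    if isinstance(core_selector, nx.Graph):
        pred_s = strip_fragment(pred, core_selector)
        exp_s = strip_fragment(exp, core_selector)
    else:
        pred_s = strip_atoms(pred, core_selector)
        exp_s = strip_atoms(exp, core_selector)
    reports = assess_match(pred_s, exp_s, params, skip_gate=True)
    return [replace(r, mode="core-only") for r in reports]


@dataclass
class LandscapeRow:
    form: str
    component: str | None
    matched_index: int | None  # index into the landscape list
    matched_rank: int | None
    rmsd: float | None
    n_gate_pass: int
    n_matches: int


def assess_landscape(landscape: list, forms: list,
                     params: ProtocolParams = ProtocolParams(),
                     stop_at_first: bool = False) -> list:
    """Assess a full landscape against experimental forms.

    Structures are tried in submitted-rank order when ``rank`` metadata is
    present (input order otherwise).  Per (form, disorder component) the
    table row holds the first matching structure, its rank and RMSD, and
    summary counts.  The experimental pattern per component is simulated
    once and reused.
    """
    if len(landscape) > 1500:
        import warnings
        warnings.warn(f"landscape has {len(landscape)} structures "
                      "(assessment protocols typically cap lists at 1500)")
    order = sorted(range(len(landscape)),
                   key=lambda i: (landscape[i].meta.get("rank", i + 1), i))
    kw = dict(two_theta_range=params.two_theta_range, step=params.step)
    rows = []
    for form in forms:
        for comp in split_disorder(form):
            tag = comp.meta.get("disorder_component")
            exp_pat = powder.simulate_pattern(comp, **kw)
            first_idx = first_rank = first_rmsd = None
            n_gate = n_match = 0
            for i in order:
                pred = landscape[i]
                sim = powder.degelder_similarity(
                    powder.simulate_pattern(pred, **kw), exp_pat,
                    params.window)
                if sim < params.gate:
                    continue
                n_gate += 1
                try:
                    match = packing.compare_packing(comp, pred,
                                                    params.tolerances)
                except ComparisonLimitError:
                    continue
                if (match.n_matched == params.tolerances.n_molecules
                        and match.rmsd is not None
                        and match.rmsd < params.rmsd_threshold):
                    n_match += 1
                    if first_idx is None:
                        first_idx = i
                        first_rank = landscape[i].meta.get("rank")
                        first_rmsd = match.rmsd
                        if stop_at_first:
                            break
            rows.append(LandscapeRow(form.name, tag, first_idx, first_rank,
                                     first_rmsd, n_gate, n_match))
    return rows
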