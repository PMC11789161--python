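# Methods

`cspcompare` decides whether predicted molecular crystal structures match
experimental forms, quantifies the overlap between predicted-structure
landscapes, matches structures against powder diffraction data, and
predicts stable cocrystal stoichiometries.  This note records the models,
the parameters that matter, the numerical choices, and what the synthetic
test conditions do and do not demonstrate.

## Crystal model

A structure is a unit cell (`a, b, c` in Å, angles in degrees), a list of
space-group operations on fractional coordinates, and the asymmetric-unit
atom sites (element, fractional position, occupancy, optional disorder
group).  Conventions shared by all modules:

* right-handed Cartesian frame with **a** along x and **b** in the xy
  plane; fractional coordinates reduced to [0, 1);
* space-group operations either read verbatim from a CIF operator loop or
  generated from the Hermann–Mauguin symbol / IT number via gemmi's
  space-group table; operation translations are snapped to n/24, which
  keeps group closure exact;
* symmetry expansion merges images closer than **0.3 Å** (Cartesian) of
  equal element and disorder group.  The merge is global, not per site: a
  molecule on a special position maps onto itself with atoms landing on
  images of *other* sites.  0.3 Å is far above numerical noise and far
  below any bond length;
* bonds join atoms within `r_cov(i) + r_cov(j) + 0.4 Å` under periodic
  boundary conditions (covalent radii from gemmi's element table, pinned
  by the dependency version).  Molecules are connected components of the
  periodic bond graph, unwrapped into contiguous Cartesian objects; a
  component bonded to its own lattice translate raises an error (polymers
  and frameworks are out of scope);
* Z′ per chemical species is (molecules of that species in the cell) /
  (space-group order), kept as an exact `Fraction` so special positions
  give 1/2, 1/3, …

Disordered structures split into one fully ordered structure per disorder
group; shared (untagged) atoms appear in every component and occupancies
reset to 1.  Absent disorder tags with sub-unit occupancies are grouped by
occupancy value with a warning.

## Packing similarity

Two crystals are compared COMPACK-style by overlaying n-molecule
coordination clusters; cells and space-group settings are deliberately
ignored, so missed symmetry and unconventional settings still match.
Defaults follow the blind-test assessment protocol: a 30-molecule shell,
35 % relative distance tolerance, 35° angle tolerance, hydrogens excluded,
bond-graph identity ("molecular differences") required, inversion allowed.

The published descriptions of COMPACK leave the exact descriptor semantics
open, so this implementation declares its own admissibility criterion and
versions it.  A trial fixes a central molecule pair, a bond-graph atom
mapping between them, and a seed transform `T0` (Kabsch superposition of
the central pair; proper and, when inversion is allowed, improper seeds
are both tried).  A correspondence (set of molecule pairs containing the
central pair) is admissible when, with the probe expressed through `T0`:

1. centroid–centroid distances agree pairwise: `|d_probe − d_ref| ≤
   dist_tol · d_ref`;
2. inter-centroid vectors agree in direction within `angle_tol`;
3. within each pair, centroid-to-atom vectors agree in direction within
   `angle_tol` for some bond-graph isomorphism.

Check 3 is what makes the criterion orientation-sensitive — an inverted
molecule at the right centroid position fails it — which is essential for
polytype discrimination.  Centroids are taken over the compared atoms
(non-hydrogen when hydrogens are excluded).  An earlier design using
per-molecule inertial axes was rejected: inertial frames are ill-defined
for planar and near-symmetric molecules, while atom-vector angles are
always defined and reduce to the same notion for generic molecules.

`n_matched` is the size of the largest admissible correspondence over all
trials (all symmetry-independent central molecules of both structures);
the RMSD is the joint least-squares superposition of all matched
non-hydrogen atoms in a single rigid fit (improper allowed when inversion
is allowed), minimized over correspondences of maximum size.

The search is a branch-and-bound over candidate pairs ordered by distance
from the centre, with forward-checking (candidate lists filtered against
each accepted pair) and a suffix bound.  For shells of ≤ 8 molecules the
search also enumerates ties of maximum size, so the reported RMSD is the
exact minimum (this is the regime the exhaustive test oracle covers); for
larger shells it is exact in `n_matched` and reports the RMSD of the first
maximum found.  The search is capped (default 10⁷ nodes) and *raises* on
cap exhaustion rather than returning a silent partial answer — silent
internal limits in comparison tools have historically produced false
negatives in exactly this setting.  A legitimate 70-molecule polytype
comparison needs ~1.5 × 10⁶ nodes; the default cap leaves an order of
magnitude of headroom.

The probe cluster is built larger than the reference shell (n + 40 %) so
that tolerance-stretched correspondences near the shell boundary are not
cut off.

## Powder diffraction

Patterns are simulated kinematically: all symmetry-unique reflections to
the 2θ limit (uniqueness over the Laue group derived from the structure's
own operations), structure factors summed over the expanded cell with IT92
four-Gaussian scattering factors, occupancy weighting, optional isotropic
Debye–Waller factor (default B = 0: simulation-vs-simulation comparisons
need consistency, not thermal realism), Lorentz–polarization correction
`(1 + cos² 2θ)/(sin² θ cos θ)`, and a pseudo-Voigt profile (FWHM 0.1° 2θ,
Gaussian fraction 0.5).  Systematic absences emerge from the phase sum,
never from tables.  Defaults: Cu Kα₁ = 1.54056 Å, 0.017° steps, 3–40° 2θ.

Similarity uses the de Gelder weighted cross-correlation

    S(f,g) = ∫ w(r) c_fg(r) dr / sqrt(∫ w c_ff · ∫ w c_gg)

with a triangular weight of half-width `l` (default 1.5° 2θ; the value the
blind-test organizers used is not published, so it is exposed as a
parameter).  S is 1 for identical or rescaled patterns and decays smoothly
with peak shifts, which is what makes a 70 % gate meaningful under small
cell differences.  Patterns are resampled to the coarser common grid by
linear interpolation before comparison.

Variable-cell refinement (FIDEL/VC-PWDF-style) maximizes S over the cell
parameters left free by the crystal system (triclinic 6, monoclinic
a,b,c,β, …, cubic 1), holding fractional coordinates fixed: first a
bounded 1-D search over an isotropic scale factor (robust against the
dominant thermal-expansion mode), then Nelder–Mead over the free
parameters, both bounded to ±10 % strain and valid cells.  The refinement
is accept-only: the returned similarity never falls below the starting
one.

March–Dollase preferred-orientation corrections are available for forward
simulation; the correction averages over symmetry-equivalent reflections
and integrates to 1 over a random powder.

## PDD fingerprints

The pointwise distance distribution at `k` is computed per unit-cell atom
(all atoms by default; a heavy-atom mode exists because some predicted
structures omit hydrogens): the k nearest-neighbour distances in the
infinite crystal, found by growing the periodic search region until the
k-th distance is provably inside it.  Rows equal within 1e-4 Å (L∞, below
CIF coordinate precision) are collapsed by single linkage with summed
weights — equivalent rows are *not* generally adjacent in lexicographic
order, so adjacent-only merging is wrong.  PDDs are compared with the
exact Earth Mover's Distance (transportation LP, HiGHS) under the L∞
ground cost between rows.  Before comparison the reference cell is
expanded isotropically to the probe's volume, absorbing thermal expansion.
The match cutoff is 0.225 Å at k = 100 (the strict landscape-coverage
threshold; protocol-confirmed matches sit below ~0.375 Å).

An element-partitioned variant (separate transport per element class) is
deliberately not the default: the plain PDD is chemically blind, and the
default reproduces that behaviour.

## Match protocol and landscape assessment

A prediction matches an experimental form when (a) the de Gelder
similarity of the simulated patterns exceeds 0.70, (b) the packing
comparison overlays the full 30-molecule shell at 35 %/35°, and (c) the
overlay RMSD is below 1.0 Å.  Both patterns are simulated with identical
profile settings so the gate tests geometry, not profile; whether the gate
should see volume-normalized cells is exposed as a flag (off by default).
Disordered experimental forms are assessed per ordered component.
Core-only mode strips a named substituent fragment (by subgraph match,
removed only when attached by a single bond) from both structures and
skips the powder gate, since the pattern of a stripped structure is not
physical.  Landscape assessment walks structures in submitted-rank order
and reports, per (form, component), the first matching entry, its rank and
RMSD, and gate/match counts; the trial-cap error is surfaced as its own
verdict, never conflated with "no match".

Landscape overlap: a query structure (top-100 by rank) counts as covered
by a target set (top-100 or the full list) when any target is a PDD match.
Groups with fewer than 100 structures use what they have, with the actual
query size as denominator.  The matrix is asymmetric by construction.

## Stoichiometry hull

For candidate compounds A_x B_y the normalized formation energy
`Δf = (E(AxBy) − x·E(A) − y·E(B))/(x + y)` (per molecule, kJ/mol) is
plotted against composition `y/(x+y)`; stable stoichiometries are the
vertices of the lower convex hull, computed with a monotone chain written
here rather than qhull because the degenerate inputs that matter
(collinear points, duplicate compositions, two-point hulls) need exact
handling.  Pure-component endpoints are pinned at Δf = 0.  Points on a
hull edge but not vertices are reported as boundary cases, not as stable.
Lattice energies stand in for free energies.  The simpler literature
criteria (stoichiometric-sum stability, reaction energy against an
isochemical assemblage) are provided as one-formula helpers on the same
data.

## Synthetic study conditions

The generator provides every pipeline stage with ground truth.  Template
molecules are hard-coded idealized geometries: a chiral 4-atom chain
(S–C–N–O; no automorphisms, cheap exhaustive oracles), a planar
asymmetric 6-ring with an exocyclic O (the polytype layer unit; its point
inversion is visible as an in-plane reorientation), the same ring with a
3-carbon chain (core-only and disorder fixtures; conformer B rotates the
chain 120° about the attachment bond — a torsion flip, deliberately not a
mirror image, which an inversion-allowed overlay would absorb), and an
N–C–C–N chain (centrosymmetric: it exercises Z′ = 1/2 on inversion
centres, and is the second cocrystal component).  Generated crystals are
validated: symmetry-expanded intermolecular contacts below 2.0 Å (or
molecules fused across the boundary) raise an error naming the contact.

Polytypes: layers of one molecule per 8 × 8 Å cell, 4.5 Å stacking, the
molecule tilted 18° out of plane and placed off-centre at (0.35, 0.35).
The polytype inverts every 6th layer through the layer origin — inverting
the molecule *and* moving it to (0.65, 0.65), as in a real inverted
stacking layer.  The off-plane tilt and off-centre placement are what make
the inversion visible in Bragg intensities (similarity ≈ 0.967 with
default profile) and not only in molecular orientation.  Cluster
geometry: a 20-molecule shell around the layer farthest from the
inversion contains no inverted molecule (full match against the uniform
stacking), a 70-molecule shell must contain several (partial match).

Planted landscapes: the designated "experimental" packing, `n_matches`
perturbed copies (default jitter 0.02 Å, strain 0.5 %), and random decoys
(cells ±35 %, free orientation and position, same molecule — as in a real
CSP landscape).  Decoys are *certified* distinct: a candidate is rejected
unless its volume-normalized PDD distance to the experimental structure
and to every other decoy parent exceeds 0.65 Å.  The margin is chosen
against the match protocol's acceptance region: full-shell matches with
RMSD < 1 Å are observed only well below ~0.45 Å in this metric, so 0.65 Å
guarantees a decoy cannot be an accidental true match while remaining easy
to sample (the median random-pair distance is ~0.9 Å).  A Kantorovich
lower bound (weighted column means are 1-Lipschitz functionals of the
rows) filters most candidate pairs before the exact EMD solve.

Hull datasets place the planted stable stoichiometries on a strictly
convex energy curve (every planted point is a hull vertex by
construction) and every decoy structure at least `margin` (default
1 kJ/mol) above the hull.

Randomness: every generator draws from its own named substream
(`default_rng([seed, crc32(name)])`), so adding a generator never shifts
another's output and identical (spec, seed) is bit-identical.

### What the synthetic conditions do not show

Rigid idealized molecules, one or few molecules per cell, no hydrogens,
no thermal motion, pseudo-energies: passing these conditions demonstrates
the correctness of the comparison machinery (invariances, oracle
agreement, planted-truth recovery), not performance on experimental data.
In particular, real conformational flexibility, Z′ > 3, solvates, and
digitized experimental powder patterns with background and preferred
orientation are outside what the fixtures emulate.

## Problem sizes and runtimes

Defaults in the test suite and acceptance script were chosen as the
smallest sizes that still exercise the claimed behaviour: oracle
comparisons on ≤ 5-molecule clusters, polytype scans at 20 and 70
molecules, eight 100-structure landscapes in the acceptance script
(twenty in the test suite), 50 hull datasets.  A full landscape
assessment (100 structures, one form) takes seconds because the powder
gate rejects most decoys before any packing search runs.

## Known limitations

* The packing-similarity criterion is this package's own declared
  formalization of the COMPACK idea; RMSDs agree with a proprietary
  implementation only up to that choice (identical verdicts are expected
  at these tolerance settings, bit-identical RMSDs are not).
* RMSD for shells larger than 8 molecules is the RMSD of the first
  maximum correspondence found, which can exceed the true minimum when
  distinct maximum correspondences exist (rare off ties).
* `allow_molecular_differences` relaxes only element labels in the
  bond-graph match; it does not attempt maximum-common-substructure
  matching between genuinely different molecules.
* The de Gelder window default (1.5° 2θ) and the B = 0 convention mean
  absolute similarity values are comparable within this package, not
  against other programs.
* No Rietveld features: backgrounds, zero-point error, peak asymmetry and
  preferred-orientation refinement are out of scope; only forward
  March–Dollase correction is provided.
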