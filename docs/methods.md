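# Methods

## Model

`ringslit` simulates melts of `M` ring polymers of `N` monomers each on
the fcc lattice, either in bulk (fully periodic) or confined to a slit:
periodic in x and y, impenetrable walls at z = 0 and z = H.  The fcc
lattice is represented as the even-parity sublattice of a simple cubic
grid; the 12 nearest-neighbor vectors are the permutations of
(±1, ±1, 0) in grid units, and the fcc step `a = sqrt(2)` grid units is
the unit of every reported length.  Published slit heights map exactly
onto integer grid gaps under this representation (H/a = 2.12 ⇔ 3 grid
units, 3.53 ⇔ 5, …), which we take as corroboration of the geometry.

Excluded volume allows at most two monomers per site, and two only when
they are consecutive along one chain ("stored length": a zero-length
bond that makes the contour locally elastic).  The mean bond length
`⟨b⟩` is therefore a fluctuating equilibrium property.  The working
density is `rho_site = 5/6` monomers per fcc site.

Bending is governed by `E = kappa_bend * Σ_i (1 − cos θ_i)` in kT units
with `kappa_bend = 2` by default.  An angle involving a zero-length
bond is undefined; two conventions are implemented:

* `zero_bond_angle="drop"` (default): such angles carry no energy.
* `"transmit"`: a zero bond transmits the angle between its nonzero
  neighbors.

The drop convention reproduces the reference bulk stored-length density
(`⟨b⟩/a = 0.661 ± 0.001` at N = 320, M = 30 versus the published
0.663), while transmit equilibrates near 0.74.  The price is a softer
chain: the bulk ring size here is `sqrt(⟨Rg²⟩) ≈ 6.0 a` versus the
reference 7.07 a.  No convention in this one-parameter family matches
both numbers; the microscopic energy rule of the original
kinetic-Monte-Carlo engine is not recoverable from the published
description, so the printed `⟨b⟩` was taken as the calibration anchor.
All confinement ratios `Ĥ = H / sqrt(⟨Rg²⟩_bulk)` are computed
self-consistently from this package's own bulk value.

## Moves and topology control

One elementary kMC step is one attempted monomer move; a sweep is N·M
attempts.  Topology-preserving moves:

* **Rouse-like** single-monomer displacement by one fcc vector,
  accepted if connectivity, occupancy and walls allow;
* **reptation-like** diffusion of a stored-length defect along the
  chain (drawn 50/50 with Rouse moves by default).

A structural fact of the checkerboard representation makes these moves
*exactly* topology-conserving: the surface swept by a nearest-neighbor
displacement consists of minimal triangles whose plane normals are of
(±1, ±1, ±1) type.  Every lattice site sits on an even level of such a
plane while a single fcc bond changes the level by at most two, so no
bond can pierce the swept surface transversally.  Excluded volume alone
enforces the non-crossing constraint; no crossing test is needed, and
with crossings disabled every topological invariant is rigorously
constant (this is checked by enumeration in the test suite).

Strand crossings are therefore realized by an explicit
topology-changing move: with probability `crossing_rate` per elementary
step (default 1e-4, one attempt window per 1e4 steps) the contents of
two adjacent sites are exchanged, passing one filament through the
other.  The proposal probability, `(occ(X)+occ(Y))/(12·M·N)`, is
symmetric under the exchange, and acceptance is Metropolis on the full
bending-energy change, so detailed balance holds move by move.
Intra-ring swaps create and destroy knots; inter-ring swaps catenate
and decatenate.

Because every kernel satisfies detailed balance with respect to
`exp(−E)` over the union of all topology sectors, the *static* ensemble
is independent of `crossing_rate`; the rate only sets how fast the
topology sector mixes.  About 1% of attempted swaps are geometrically
legal and accepted, so the default schedule realizes roughly one strand
passage per 1e6 steps.  Analysis and test runs therefore raise
`crossing_rate` (typically to 1e-2) purely as a mixing accelerator;
this was verified to leave `⟨b⟩`, bending energy and ring-size
statistics unchanged within errors.

## Initial state and equilibration

Rings start as flat two-layer "staples": a serpentine path in one z
layer plus its return in the layer above, with every site doubly
occupied (stored length), tiled through the box.  The chain count is
adjusted to hold the site density fixed once an even-sided box with the
requested height is chosen.  Any start state is acceptable because
equilibration is certified by the plateau of g2 (the monomer
mean-square displacement in the ring's center-of-mass frame); the
pipeline discards the pre-plateau window.

Finite-size caution: at M = 10, N = 320 the periodic box edge is
comparable to one ring, and `⟨b⟩` shifts by ≈ 2.5% relative to M = 30.
Quantitative bond-length comparisons are made at M ≈ 30 where the
box-to-ring ratio is comfortable; the topological trend analyses use
the smaller systems where box effects cancel between conditions.

## Topological analysis

* **Simplification** ("shrinking"): iterative vertex deletion; vertex v
  is removed when the closed triangle (v−1, v, v+1) meets no other
  segment of any ring except at its two surviving corners, so each
  deletion is an ambient isotopy.  Sweeps run in seeded random order to
  a fixed point.  All predicates are exact integer orientation tests;
  degenerate (collinear-triangle) cases fall back to rational
  arithmetic.
* **Gauss linking number**: the exact integer from the analytic
  solid-angle sum over segment pairs (rounded, with a 1e-6 residual
  guard and an extended-precision retry).  Verified against a
  brute-force signed-crossing projection oracle on random ring pairs.
* **Knots**: the self-simplified ring is projected along random
  directions; the diagram with fewest crossings feeds an exact
  Alexander-polynomial computation (integer Bareiss determinants
  evaluated at integer points, interpolated with rationals).  Labels
  come from a table of prime knots to 7 crossings plus composites of
  those; anything else is an explicit `complex(K=…)` bucket with
  heuristic confidence.  |Δ(−1)| (the knot determinant) alone separates
  the species that occur at measurable frequency in these melts
  (unknot 1, 3_1 3, 4_1 5, 5_2 7, 3_1#3_1 9, …).
* **Pair links**: GLN ≠ 0 ⇒ concatenated with weight χ = |GLN|.
  GLN = 0 pairs are jointly simplified; a separating-slab search over
  random orientations handles the clearly split cases, and the
  remaining geometrically stuck pairs are decided by the two-component
  link determinant: 0 ⇒ split (deletion-only shrinking cannot pull
  interpenetrating convex curves apart, so the slab test alone is too
  conservative), 8 ⇒ Whitehead class 5²₁ with K = 5 and χ = K/2 = 2.5,
  otherwise "other-GLN0" with χ from the reduced diagram's crossing
  count.  A diagram in which one component is never the under-strand
  at inter-component crossings certifies splitness directly (that
  component lifts off).
* **Triples**: triangles (all three pairs concatenated) and
  poly(3)catenanes (exactly two) follow from the C matrix alone.
  Otherwise the triple is jointly simplified: separable ⇒ none;
  inseparable with vanishing three-component determinant ⇒ none
  (split); inseparable with one linked pair ⇒ poly(2)catenane+1-ring;
  with none ⇒ Brunnian (e.g. the Borromean rings 6³₂, whose fixture is
  three mutually perpendicular rectangles).
* **Census**: pairs are prefiltered by the rigorous cutoff
  |d_CM| > R_i + R_j; each surviving pair is examined against every
  periodic image whose bounding box overlaps (rings comparable to the
  box can link through more than one image; such pairs are flagged
  `multi-image` with summed weights).  The O(M³) irreducible-triple
  search is off by default in melt censuses and enabled on demand.

## Observables

All curves are emitted as tidy TSV with abscissa, value, error and
sample count.  Gyration tensors, their descending eigenvalues and the
⊥ (zz) / ∥ (xx+yy) split satisfy tr Q = Rg² = Rg²_⊥ + Rg²_∥ exactly.
Bond correlations skip products involving zero bonds and normalize over
contributing pairs only.  Contacts use r_c = a (same-site or
nearest-neighbor pairs).  The ring finite-size variable is
ξ = ℓ(L−ℓ)/L with L = N⟨b⟩; the local exponent γ(ξ) comes from
centered differences on log-binned data and recovers exact power laws
to three significant figures.  Knot and link probabilities carry
binomial errors; means over snapshots use block averages.  The linking
degree is LD_i = Σ_j χ_ij C_ij with ⟨LD⟩ = N/N_e defining the
entanglement length.

## Problem sizes used in the checks

Desk-scale defaults chosen once for the acceptance suite: fixture
topology checks run on the certified curves plus 200 random
closed-walk pairs for the GLN oracle; conservation uses a 10-ring
melt over 1e6 steps; bond-length calibration uses N = 320 with M = 10
(the stated comparison point) and M = 30 (where the box is large
relative to a ring); scaling checks use N ∈ {40, 80, 160} for ν and
N = 320 for γ; the confinement-trend suite compares bulk against the
tightest slit at N = 320, M = 10 over two seeds — at N = 80 the
knotting probability of this (more flexible) realization is too small
to carry a sign test, so the trend is evaluated at the reference chain
length itself.

## Known limitations

* The microscopic move set and zero-bond energy rule of the reference
  engine are published only by citation; this realization matches the
  stated contract (locality, stored length, excluded volume, tunable
  strand crossing) but differs measurably in chain stiffness
  (sqrt(⟨Rg²⟩)_bulk ≈ 6.0 a vs 7.07 a) and in the slit-induced
  reduction of ⟨b⟩ (−2.8% vs −1.1% at the tightest slit).
* Knot labels beyond 7 crossings (and their composites) are reported
  as `complex`; Alexander invariants cannot distinguish chirality or
  certain deep coincidences (e.g. unknot-like Δ = 1 at high crossing
  number, labelled heuristically).
* The separability decision for geometrically stuck GLN = 0 structures
  is exact up to link-determinant coincidences (a nonsplit link with
  determinant 0 would be conservatively misread as split; none occur
  among the small links relevant here).
* Synthetic Gaussian-ring ensembles used as shape oracles emulate
  ideal closed chains only; they carry no excluded volume, so tests
  based on them validate estimators, not melt physics.
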