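# Methods

## Model overview

The package simulates a place-cell ensemble observed during free
exploration and learns relational representations ("schemas") of the
environment from spike timing alone.  The full pipeline is:

1. **Environment** — a navigable polygon: a square arena with a
   central square hole (default 1×1 m, hole side 0.3 m), or a U/W
   corridor track (10 cm wide).  All geometry is handled by shapely.
2. **Trajectory** — a correlated random walk sampled at `dt = 10 ms`.
3. **Spiking** — per-cell inhomogeneous Poisson by thinning.
4. **Coactivity** — 250 ms windows; events feed the four learners.

## Trajectory model

The reference phenomenology does not constrain the trajectory beyond
"exploratory", so the generator is a declared design choice:

- **Arenas**: the heading angle diffuses with decorrelation time 1 s
  (an Ornstein–Uhlenbeck-style persistent walk); the step speed is
  redrawn each step from a truncated normal with mean 0.2 m/s and
  CV 0.3.  A step that would leave the navigable region is rejected
  and the heading resampled away from the wall — a noisy reflection.
- **Tracks**: waypoint navigation along the corridor skeleton at the
  same speed statistics; at the junction the next corridor is chosen
  uniformly among the others, dead ends reverse.

A 25-min default-arena run visits every navigable 10 cm bin (asserted
in the test suite), with empirical mean speed within 10% of nominal.
All simulation stages take independent sub-seeds derived from one run
seed, so components can be varied in isolation and runs are
bit-reproducible.

## Place cells

Rates follow `lambda_i(r) = f_i exp(-|r - r_i|^2 / (2 sigma_i^2))`
with centers uniform over the navigable region and `f_i`, `s_i` drawn
from gamma distributions (positive support, unimodal, CV 0.3).  The
sampled `s_i` is the *place-field size*, understood as the diameter of
the region above 20% of the peak rate — the conventional field
criterion in the experimental literature — giving
`sigma_i = s_i / (2 sqrt(2 ln 5)) ~ s_i / 3.59`.  Reading the 20 cm
mean size directly as the Gaussian sigma would make each field span
most of a 1×1 m arena and drive the coactivity graph to saturation,
which contradicts the ensemble statistics this simulation is meant to
emulate; the conversion is fixed once and not treated as tunable.

Theta modulation is multiplicative, `1 + cos(2 pi f_theta t)`, depth 1,
phase shared by all cells (no precession).  The modulation has mean 1,
so expected counts match the unmodulated model — asserted by a
100-seed Poisson mean test.  Because the coactivity window spans two
full theta periods, the modulation does not bias window-level
coactivity either.

Thinning on the `dt` grid is exact for piecewise-constant rates; the
largest per-step probability at default parameters is ~0.24.

## Coactivity and temporal relations

The session is tiled into consecutive (not sliding) windows of two
theta periods; a window's event is the set of cells with at least one
spike in it.  Tiling makes event counts well defined and matches the
discrete "two theta periods" evidence quantum.

Activity intervals are maximal spike runs with inter-spike gaps at
most one window, padded by half a window per side.  Interval pairs are
classified as separation / overlap / during / inverse-during / equal
with tolerance `tol` (equality of endpoints within `tol`); the package
default for interval algebra on raw spikes is `dt`, while the RCC5
learner uses half a coactivity window, its evidence quantum.

## Graph schema

Edges carry first-detection times; the edge set grows monotonically.
Reported quantities: binary entropy of the connected-pair fraction
(denominator: all `N(N-1)/2` pairs of the wired ensemble, including
never-active cells), link saturation time `T_N` (first time the
remaining growth is below 1% of the final count), the distant-pair
connection time `T_min` (earliest time all final-graph-diameter vertex
pairs are path-connected, via a union-find scan over edge arrivals),
the fraction of links present at `T_min`, Eulerian-path existence and
maximal-clique counts (Bron–Kerbosch via networkx; desk scale only).
"Most distant" is graph distance on the final graph — the only metric
available to the schema itself.

## Simplicial schema

Each coactivity event is a simplex; the stored family keeps only
inclusion-maximal simplexes (an antichain): events contained in a
stored simplex are redundant, and stored simplexes contained in a new
event are absorbed.  Absorbed simplexes remain *faces* of the complex,
so the filtration only grows; the insertion log preserves their
detection times.

Homology is computed over Z2 in dimensions 0–1 on the 2-skeleton.
H0 persistence uses union-find with the elder rule; H1 uses standard
column reduction of the triangle boundary matrix with columns stored
as Python big integers (bitmasks over edge indices), so each column
operation is one XOR.  Per maximal simplex on `k` vertices only the
`C(k-1, 2)` cone triangles through its smallest vertex are inserted:
within a clique every cycle is a Z2-sum of triangles through a common
apex, so the span of the boundary columns — and therefore the entire
H0/H1 persistence diagram — is identical to that of the full
`C(k, 3)` triangle set at every filtration stage.  The test suite
verifies both the cone/full equivalence and agreement with a dense
GF(2) boundary-matrix oracle on the full face lattice.

Face times are the earliest detection time of any containing logged
simplex; ties break lexicographically.  Zero-persistence bars (born
and filled within one window batch) are dropped.  The topological
learning time `T_min` is the latest death among non-surviving bars,
i.e., the first time the Betti numbers hold their session-end values
(up to late births of surviving classes, which the tests handle
separately).

## Mereological schema

Candidates are triples `(U = {i, j}, V = d)` where `d` has cofired
with both `i` and `j` (the "bundled" restriction that keeps the cubic
candidate space tractable).  A relation is detected at the end of the
first activity interval of `V` fully contained in the union of `U`'s
intervals — detection requires one complete covered activity period,
not an instantaneous coincidence — and violated, permanently, at the
first later moment `V` is active outside that union (the readout
neuron fires).  All containment is evaluated on the `dt` grid; the
learner is a vectorized (packed-boolean) implementation verified
candidate-by-candidate against a dense sweep oracle.

## RCC5 schema

Evidence comes from joint-activity *episodes*: connected components of
the union of two cells' activity intervals containing both cells,
labeled by the temporal relation of the two cells' spans and stamped
with the episode end time.  The label map is: temporal overlap certifies
spatial overlap (PO); separation is consistent with {DR, PO}; during /
inverse-during / equal are consistent with containment or PO.  A pair
with no joint episodes is DR.  Containment labels (PP/PPi/EQ) require
every joint episode so far to be during/equal and at least
`n_min = 3` such episodes — containment is only ever a guess, overlap
is not.  One refinement guards against sampling noise: an overlap
shorter than the relation tolerance (half a window) is below the
framework's temporal resolution and counts as separation evidence;
without it, a single glancing contact between padded one-spike
intervals permanently forced PO between cells with disjoint fields.

Label updates move only along the continuity graph (DR–PO, PO–PP,
PO–PPi, PO–EQ), so a DR→PP revision passes through PO, with both steps
recorded in the pair's history.  Converse consistency holds by
construction (one label per unordered pair; the converse is derived).
Composition-table violations are counted over ordered triples with a
vectorized indicator-matrix product; the embedded 5×5 table is checked
against enumeration of all region triples over a 4-element universe.

Track integrals classify each cell by its count of non-DR partners:
endpoint (1), midpoint (2), junction (3+); the stabilization time is
the last change of the cell's classification, replayed from the
transition histories.  On a W-track tiled with 7 deterministic fields
(junction, three midpoints, three endpoints at 0.3 m spacing) the
classification typically settles within the first minute or two.

## Spatial map and information measures

Place fields are reconstructed as convex hulls of spike locations
after discarding spikes farther than 3 MADs from the spike centroid
(raw Poisson stragglers otherwise make hulls unbounded); crisp hulls
deliberately overstate high-order overlaps relative to coactivity —
a property of the representation.  Overlap structure is computed by
1 cm rasterization (exact k-wise polygon intersection is
combinatorial; the grid matches field resolution), deduplicated to
maximal region combinations — exactly the maximal simplexes of the
Cech nerve of the cover.  Entropies of schema and map relationship
streams and the mutual information between them use the standard
plug-in estimators in bits, with MI in its standard non-negative form.

## Problem sizes and determinism

The reference conditions (200 cells, 25-min sessions, 10 seeds) run
end to end in a few minutes on one CPU: trajectory and spiking are
vectorized, the mereological learner uses packed-boolean interval
masks, and the persistence reduction runs on bitmask columns.  Tests
use the same conditions for acceptance-level checks and much smaller
fixtures (tens of cells, minutes of session) for unit-level ones.
Every stochastic component takes an explicit seed.

## Known limitations

- The untruncated Gaussian tuning curve never vanishes, so arbitrarily
  distant cell pairs cofire at a small but nonzero rate.  Over a
  25-min session this produces a steady trickle of first-time distant
  coactivities: relationship networks do not reach a hard plateau, the
  1%-tail saturation times `T_N` land late in the session, and a few
  spurious 1-loops can persist to session end alongside the loop that
  encodes the central hole (median across seeds: the hole's loop plus
  one residual).  A compact-support field model would remove the
  trickle but would contradict the tuning-curve contract this package
  implements.
- No phase precession, remapping, plasticity or biophysical readout
  dynamics: readout neurons are event-level detection rules.
- Homology stops at dimension 1; higher-order covering combinations
  (`k, l > 1`) are out of scope.
- The synthetic trajectory is statistically homogeneous; real rodent
  exploration (thigmotaxis, goal-directed segments, immobility) is
  richer, so passing tests show internal consistency of the learners
  under the stated model, not behavioral realism.
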