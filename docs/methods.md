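# Methods

This note documents the models, numerical choices and limitations
behind `fibermetrics`. Notation: N_GT is the ground-truth network, N_T
the test case, σ the sensitivity (Gaussian envelope standard deviation,
model units), ε the dimensionless sampling accuracy.

## Network model and topology construction

A network is a geometric multigraph: nodes with 3D positions, fibers as
3D polylines joining node pairs. Self-loops (closed rings) and parallel
fibers between one node pair are allowed. Polyline endpoints must
coincide with their node positions to 1e-9.

`build_topology` assembles this from raw polyline segments. Segment
endpoints are welded (exact coordinate match by default; a tolerance
can be supplied for noisy exports, implemented with union-find over a
k-d-tree pair query). Welded vertices of degree ≠ 2 become nodes;
chains through degree-2 vertices merge into single fibers. Two
degenerate cases need a convention:

- **Pure cycles** (every vertex degree 2) have no natural node. A
  cycle gets one node at its first vertex and a single self-loop fiber,
  keeping the graph model total.
- **Exception — parallel pairs:** a two-segment cycle between exactly
  two welded vertices is kept as two nodes and two parallel fibers.
  Rationale: two distinct polylines drawn between the same endpoints
  encode two fibers (e.g., a genuine duplicate edge produced by a
  segmenter), whereas a ring traced in three or more pieces encodes one
  loop. This is a judgment call; a single ring traced as exactly two
  half-arcs will be read as a parallel pair.

SWC input is converted to per-link segments and run through the same
construction, so samples of degree ≠ 2 (roots, tips, branch points)
become nodes and chains collapse; per-point radii survive. A root with
exactly two children is a through-point, not a node. SWC forests are
accepted; forward or dangling parent references and duplicate ids are
structural errors (SWC cannot encode loops, so cycles cannot arise).
Sample `type` codes are ignored: the model is a curve skeleton, with no
special soma handling. OBJ input welds shared *endpoint* vertices of
`l` polyline elements only; an endpoint of one polyline coinciding with
an interior vertex of another does not split the latter (exports that
intend a junction repeat the coordinate as an endpoint).

Coordinates are dimensionless model units; σ must be supplied in the
same units. No voxel/physical conversion is attempted.

## Geometry metric

M(N₁, N₂) = (1/n) Σ 1 − exp(−d(x, N₂)²/2σ²) over n samples x on N₁,
with d the distance to the nearest *sample* of N₂ (cKDTree query), not
the exact point-to-curve distance; the sampling bounds below quantify
exactly that approximation. GFNR = M(N_GT, N_T), GFPR = M(N_T, N_GT).

**Sampling.** Two modes, both with spacing scale εσ (default ε = 0.1):

- *regular*: each fiber of length L is resampled at L/⌈L/spacing⌉
  intervals (endpoints always included). Worst-case metric error
  1 − e^(−ε²/8).
- *grid* (default): samples where fibers cross the cell-boundary planes
  of a uniform grid (cell εσ, origin (0,0,0) unless overridden — both
  networks must share cell and origin). Worst-case per-point error
  e^(−ε²/8) − e^(−ε²/4), and the error vanishes as d → 0, which makes
  self-comparison exactly zero. Fiber endpoints are also emitted so
  that fibers shorter than one cell still contribute samples. A vertex
  lying exactly on a plane is counted once (coincident crossings within
  1e-9 of arc length are merged).

**Accuracy caveat.** The bounds above cover the distance-measurement
error per sample. Comparing two finite sample means additionally
carries a quadrature term of order εσ/L × (range of the weight field),
from end effects and orientation-dependent crossing density. For
fibers long relative to σ — the intended regime; traced fibers are
hundreds of radii long — this term is subdominant, and the test suite
verifies both bounds over random fiber pairs of length 50–100σ with
sub-3σ offsets and small mutual rotations. For single fibers only
~10σ long the grid bound can be exceeded at small ε by the quadrature
term alone.

**Per-point and per-fiber scores.** The per-point weight (the summand
of M) drives the visualization. The per-fiber score M(e) is the
arc-length-weighted trapezoidal mean of that fiber's per-point weights
— not the raw sample mean — so unevenly spaced grid crossings do not
bias fiber scores. The global M remains the plain sample mean.

**Degenerate inputs.** An empty N₁ has no samples and M is undefined:
error. An empty *reference* N₂ yields all weights 1 with a warning, so
incomplete-ground-truth workflows degrade gracefully rather than crash.

**Invariances.** Regular-mode M is invariant under a rigid motion
applied to both networks (arc-length sampling is intrinsic). Grid-mode
M is invariant under common translations when the grid origin is
translated along; rotations change the crossing pattern and perturb M
within the sampling bound, because the grid itself is axis-aligned.

## Connectivity metric

Graphs: one vertex per node, one edge per fiber (multi-edges and
self-loops preserved).

**Coloring.** Candidate pairs are all (GT vertex, test vertex) pairs
with distance < σ (strict); they are accepted greedily by ascending
distance, ties broken by vertex ids, each vertex pairing at most once.
The accepted pair receives the GT vertex id as its shared color;
everything else stays uncolored (−1). Greedy-by-distance resolves the
many-to-one conflicts a per-vertex nearest assignment can produce, and
makes the pairing symmetric under swapping the two networks. The same
σ is used here as in the geometry metric — one sensitivity parameter.

**Edge weights.** W(e) = |e|·M(e) ≥ 0, fiber length times per-fiber
geometric error, measured against the *other* network. Well-matched
fibers cost ≈ 0, so path searches prefer them. Zero weights are valid.

**Core connectivity.** Colored vertices are processed in ascending id
order. From each, a Dijkstra search explores only uncolored vertices
and terminates branches at colored ones; every colored vertex reached
(including the source itself, via a cycle through uncolored mesh)
yields one core edge carrying its realizing path (the ordered original
edge ids). The processed vertex is then removed, so no connection is
emitted twice. Ties in path weight are broken by the lexicographically
smallest edge-id sequence, making results reproducible; with ties the
search settles for *a* deterministic minimum-weight path, which on
exactly tied alternatives may differ from the lexicographically global
minimum (the distinction is unobservable in the rates). Paths through
other colored vertices are never considered, so a colored pair joined
only via colored interiors produces no core edge.

**Comparison.** Core edges match when their colored endpoint pairs
carry the same color pair; parallel core edges per pair (rare — at most
one arises per pair per graph by construction) would match greedily by
ascending path weight. Original edges on matched realizing paths are
true positives, counted per side (tp_gt, tp_t), because a subdivided
ground-truth edge legitimately corresponds to several test edges. Then
FN = (uncolored GT vertices) + (GT edges on no matched path), FP the
same on the test side, CFNR = FN/(FN+TP_gt), CFPR = FP/(FP+TP_t); a
zero denominator yields rate 0. Note that edges on *unmatched* core
paths count as errors: only members of corresponding connections are
true positives. A degenerate consequence: parallel fibers present
identically in both networks contribute one FN and one FP each, since
each side's core keeps only the cheaper route; the fixture generators
do not produce such pairs.

## Synthetic fixtures

`generate_tree(n, branch_length, seed)` grows a rooted binary tree: one
initial fiber, then n branch events each replacing a random leaf with a
junction and two children (2n+1 fibers, 2n+2 nodes). Fiber geometry is
a direction-persistent random walk with ~1-unit steps, Gaussian
direction wobble 0.12 per step and a radial bias away from the root.
The wobble makes fibers tortuous the way real traces are and
decorrelates fiber orientation, so no fiber is locked to a grid-aligned
direction (which would bias its share of grid samples); the radial bias
keeps sibling subtrees spreading apart, as processes radiating from a
soma do. Segment lengths are rescaled so each fiber's arc length is
exactly the requested branch length (a scalar or a (lo, hi) range
sampled per fiber). Every point carries a constant radius (default 1),
so σ defaulting to the mean fiber radius equals 1 for these fixtures.

`generate_lattice_network(nx, ny, nz, jitter, seed, spacing)` produces
a jittered 3D grid graph with loops — a microvasculature-like,
non-tree-like fixture; node degree ≤ 6. Grid nodes are kept as nodes
even where degree is 2 (lattice corners).

`inject_errors` corrupts a copy of a network with the canonical error
taxonomy, returning a ledger of predicted consequences: **gap** (an
interior arc window removed; 2 new endpoint nodes; predicted FN += 1,
FP += 4), **spur** (perpendicular branch at an interior point, creating
a junction; FP += 3), **missing_fiber** (fiber deleted; endpoints left
with degree 0 vanish and degree-2 junctions dissolve, each making the
GT counterpart uncolored; FN += 1 + such endpoints), **spurious_fiber**
(random-walk fiber placed ≥ 10σ outside the bounding box; FP += 3),
**duplicate_edge** (a bowed parallel copy of an existing fiber; FP +=
1), **deformation** (smooth perpendicular sin² bump of given amplitude;
the ledger stores the quadrature prediction of the fiber's M(e), the
mean of 1 − e^(−δ(s)²/2σ²) over the bump profile), **node_jitter**, and
**subdivision** (degree-2 split that topology reconstruction must
re-collapse). Error sites keep ≥ 5σ mutual separation (placement
retries; failure raises), so predictions compose additively; all
randomness flows from one seed. The predictions assume isolated errors
on tree-like neighborhoods (e.g., a gapped fiber with colored
endpoints); overlapping or adjacent errors void them by construction.

`delete_length_fraction` prunes whole subtrees (≤ 3, chosen by
exhaustive enumeration) totaling a target fraction of tree length —
whole subtrees keep the count of deleted/kept attachment boundaries
minimal, since each boundary blurs about 1.3σ of deleted length into
the kept network's envelope.

What the fixtures do *not* emulate: imaging noise, soma geometry,
radius variation along fibers, anisotropic sampling artifacts of
specific microscopes, or densely interleaved fibers closer than a few
σ. Passing tests therefore demonstrate correctness of the metrics'
mechanics and their advertised analytic behavior, not segmentation
performance on real microscopy data.

## Visualization export

Four colormaps map [0,1] scalars to RGB: **diverging** (default;
piecewise-linear blue → light gray → red, chosen so red−blue = 2v−1,
which makes exported colors invertible back to weights within 8-bit
rounding), **rainbow** (HSV hue sweep blue → red), **blackbody**
(black → red → yellow → white ramp), **isoluminant** (two
equal-luminance endpoints, low dynamic range but shading-safe). The
exact tables are this package's choice. Exports are ASCII PLY line
geometry with per-vertex uchar RGB: per-point weights through the
colormap for geometry; for connectivity, node markers first (red =
undetected, gray = detected) followed by fiber polylines colored by
matched-pair palette index, unmatched edges in a configurable neutral
color (default light gray; the choice of white vs gray is cosmetic).
Static file export replaces interactive GPU rendering; tube extrusion
is not performed (polylines with vertex colors).

## Tunable parameters

| parameter | default | units | meaning |
|---|---|---|---|
| σ | mean fiber radius of the GT (flag required if absent) | model units | envelope std. dev.; coloring radius. Larger σ forgives larger deviations: both rates are non-increasing in σ. |
| ε | 0.1 | — | sampling accuracy; samples every ≤ εσ. At ε = 0.1 the grid-mode bound is ≈ 1.25e-3. |
| sampling mode | grid | — | grid (tight bound, exact self-zero) or regular (rigid-motion invariant). |
| grid origin | (0,0,0) | model units | common grid anchor; translate with the data for reproducibility. |
| cull threshold | off (0.9 typical) | — | drop test fibers with M(e) above this before re-measuring, for incomplete ground truths. |
| weld tolerance | 0 (exact) | model units | OBJ endpoint welding radius for noisy exports. |

## Problem sizes used in the checks

Self-comparison uses 10 trees (3 branch events, ~160 length units) and
10 jittered 3×2×2 lattices; sampling-bound checks use 100 random fiber
pairs per ε at lengths 50–100σ with a dense oracle at spacing εσ/50;
the core-connectivity oracle enumerates all simple paths on 200 random
multigraphs of ≤ 8 vertices; ledger checks run each error kind in
isolation on 7-fiber trees. These sizes were chosen so the whole suite
and the acceptance script each complete in well under a minute while
every property is exercised far from trivial limits.

## Known limitations

- Grid-mode M is origin-dependent at the sampling-bound scale; two
  runs with different grid origins differ within the ε bound.
- The connectivity rates count vertices and edges together in FN/FP
  (uncolored nodes plus unused edges); pure edge-based rates would
  differ on heavily gapped data.
- Culling can discard inaccurately segmented fibers along with
  genuinely un-annotated ones, overestimating performance on
  incomplete ground truths.
- Fibers that terminate early (ends > σ from the matching node) leave
  their node uncolored and locally inflate both FN and FP even though
  most of their geometry matches.
- DIADEM-style hierarchical scoring and tree-edit distances are out of
  scope; so are image volumes, meshes, and radius-aware (tube-surface)
  distances.
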