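# fibermetrics

Quantitative comparison of fiber network centerline models — traced
neurons, microvasculature, astrocyte processes — against a ground truth.
Given two explicit network models (SWC neuron morphologies or polyline
OBJ files, which may contain loops), `fibermetrics` reports four
normalized error rates, localizes errors per point and per edge, and
exports colormapped geometry for visual inspection. It is aimed at
developers and evaluators of filament segmentation/tracing algorithms
who need more than a single summary score: *where* and *why* a
segmentation fails, separately for geometry and for connectivity.

## The metrics

A network N is a geometric graph: **nodes** (junctions and endpoints)
joined by **fibers**, each fiber a 3D polyline. Two kinds of error are
measured with a single sensitivity parameter σ (conventionally the mean
fiber radius, in model units).

**Geometry.** The one-directional metric

&nbsp;&nbsp;&nbsp;&nbsp;M(N₁, N₂) = (1/n) Σ_{x∈N₁} [ 1 − exp(−d(x, N₂)² / 2σ²) ]

places a Gaussian envelope of width σ around N₂ and averages the
resulting weight over n points sampled along the fibers of N₁; d(x, N₂)
is the nearest-point distance, resolved with a k-d tree. M estimates
the fraction of N₁'s fiber length with no counterpart in N₂. The
bidirectional pair gives

&nbsp;&nbsp;&nbsp;&nbsp;GFNR = M(N_GT, N_T),&nbsp;&nbsp;&nbsp;GFPR = M(N_T, N_GT).

Networks are resampled at spacing ≤ εσ (default ε = 0.1), either
regularly along arc length (error bound 1 − e^(−ε²/8)) or at the cell
boundaries of a grid shared by both networks (tighter bound
e^(−ε²/8) − e^(−ε²/4), and exact zero for self-comparison; the
default).

**Connectivity.** Each network becomes a multigraph (one edge per
fiber). Node pairs across the two graphs closer than σ are *colored*
with a shared identifier (greedy nearest pairing); each edge carries the
weight W(e) = |e|·M(e), length times mean geometric error. The *core
connectivity* graph connects colored nodes by minimum-weight paths
through uncolored interiors (bounded Dijkstra search). Core edges with
matching color pairs correspond; original edges on matched paths are
true positives, and

&nbsp;&nbsp;&nbsp;&nbsp;CFNR = FN / (FN + TP),&nbsp;&nbsp;&nbsp;CFPR = FP / (FP + TP),

where FN counts uncolored ground-truth nodes plus unused ground-truth
edges (FP likewise on the test side). This handles interconnected,
loop-containing networks — not just rooted trees — and is robust to
gaps, spurs, and subdivided fibers.

## Worked example

Generate a synthetic neuron tree, corrupt a copy with a 2-unit gap and a
5-unit spur, and compare the pair (σ defaults to the mean fiber radius
stored in the SWC file, here 1.0):

```sh
$ fibermetrics generate --kind tree --n-branches 3 \
      --errors "gap:2.0,spur:5.0" --seed 7 --out demo
wrote clean.swc, corrupted.swc, ledger.json to demo

$ fibermetrics compare demo/clean.swc demo/corrupted.swc --out demo/report
GFNR = 0.001007
GFPR = 0.012680
CFNR = 0.142857
CFPR = 0.500000
```

Reading the numbers: the gap removes 2 of ~280 length units but the
envelope of the surviving fragments covers most of it, so only ≈0.1% of
the ground-truth geometry is missed (GFNR). The spur adds 5 units of
false geometry (GFPR ≈ 1.3%). Connectivity is hit much harder, as it
should be: the gapped fiber's connection is lost — 1 missed connection
against 6 correctly detected edges, CFNR = 1/7 — while on the test side
the two gap fragments (2 unusable edges + 2 undetected break nodes) and
the spur (1 excess edge + 2 undetected nodes) give FP = 7 against
TP = 7, CFPR = 1/2. `demo/ledger.json` records exactly these predicted
counts, and `demo/report/` contains the per-point colormapped geometry
(`*_geometry.ply`, blue = matched, red = error, diverging map by
default), the connectivity renderings (`*_connectivity.ply`, red
spheres = undetected nodes, one color per matched connection), and a
JSON summary.

For segmentations evaluated against an *incomplete* ground truth, a
culling pass (`--cull-threshold 0.9`) removes test fibers whose mean
error exceeds the threshold and re-measures, so correctly traced fibers
missing from the partial ground truth stop inflating GFPR.

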