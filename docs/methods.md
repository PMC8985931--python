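# Methods

`neuroherd` implements a complete, testable version of a geometric design and
quantification framework for steering ("herding") dissociated retinal cells on
microelectrode patterns: neurons onto textured, vertically-aligned
carbon-nanotube (VACNT) branches and glia into the smooth SiO2 gaps between
them. This note describes the models, the parameters that matter, the
numerical choices, and what the synthetic data can and cannot demonstrate.

## Electrode geometry

**H-tree fractals.** A design is `(D, m, W_CNT, W)`: fractal dimension `D`
(1 < D <= 2), number of repeating H levels `m` (branch orders n = 0..N,
N = 2m - 1), branch width `W_CNT` and overall pattern width `W`. Branch
lengths follow the exact scaling law

    L_n = L_0 * 2^(-n/D),

and the base length is not free: it solves the width constraint
`W = 2 * sum_{even n <= N-1} L_n + W_CNT`, so every design spans the same
width regardless of `D`. Construction is recursive from the pattern center
(two horizontal order-0 bars of length L_0; at each free endpoint two
perpendicular children of the next order). Each branch is an axis-aligned
rectangle of width `W_CNT` on its centerline. `(D, m)` combinations whose
branches overlap beyond their junctions are rejected
(`OverlappingDesignError`), mirroring the exclusion of closed-gap designs
from the experimental set.

**Euclidean rows.** `(W_CNT, W_Si, W)`: horizontal textured rows of width
`W_CNT` separated by `W_Si`, packed with as many rows as fit in a square of
side `W`. This packing rule is inferred, not stated alongside the published row dimensions; it
is the unique rule that reproduces all seven published (A_CNT, A_Si) pairs at
printed precision.

**Catalogue.** The seven fabricated row designs use `W = 6000 um`; the m = 4
fractals use `W = 6020 um`; the D = 2, m = 5 and 6 trees use `W = 6262 um`
(chosen so the smallest gap of the m = 6 tree is 25 um). Simulated series:
rows with `W_Si = 200..1100 um` (step 100) and fractals with
`D = 1.1..2.0` (step 0.1) at `W = 6262 um`.

## Geometry metrics

Closed forms on the vector tree (exact under the scaling law):

- total centerline branch length `L_b = sum_n 2^(n+1) L_n`;
- branch area `A_CNT = W_CNT * L_b - sum_{n>=1} 2^n W_CNT^2 / 2` (each
  junction double-covers half a `W_CNT^2` square);
- edge length `E = 2 A_CNT / W_CNT + 2 W_CNT` (the algebraically simplified
  perimeter of the branch union; the raw published expression is
  typographically corrupted in extraction, so the perimeter was re-derived
  from the geometry and verified against the raster oracle), and
  `E_n = E / W`;
- tortuosity `T`: the along-branch path from the center to a finest-branch
  tip is `sum_n L_n` for every tip; `T` is the mean over all `2^(N+1)` tips
  of path / straight-line distance, evaluated by enumerating every sign
  combination of the even-order (x) and odd-order (y) offsets;
- characteristic gaps: `W_Si_min = L_{N-2} - L_N - W_CNT/2` (the labeled
  smallest gap between a finest branch tip and its grandparent crossbar —
  this reading reproduces the published 56.4 / 101.0 / 25.0 um values) and
  `W_Si_max = 2 L_0 - W_CNT`. The *global* minimum clearance over all branch
  pairs can be smaller than the labeled gap (e.g. ~96 um vs 101 um for the
  D = 1.5, m = 4 design) and is exposed separately as `min_clearance`;
- gap rectangles: `A_min = (L_{N-2} - W_CNT)(L_{N-1} - W_CNT)` (the cell
  framed by the two finest orders) and `A_max`, the central clear column
  between the innermost even-order branch columns above the crossbar —
  verified to match the maximal-empty-rectangle search on the raster to
  0.02 %. `A_r = A_max / A_min`;
- connected gap area `A_c`: the central multi-scaled gap region enclosed by
  the branch skeleton. The closed form was validated against its design
  anchor: the widest simulated row gap (1100 um) was chosen to match the most
  open fractal's `A_c`, and the closed form gives 6.64e6 vs 6.6e6 um^2.

Raster oracles are computed on a pixel mask (pixel-center sampling, default
1 um/px): label counts for areas, CNT/GAP face-adjacency counting for edge
length (exact for axis-aligned geometry, no corner bias), Euclidean distance
transform for proximity, 4-connected component labeling for connected gaps,
and the classic histogram-stack maximal-empty-rectangle search (numba-
compiled, O(rows x cols), row-major tie-breaking). Proximity `P` is the mean
over gap pixels of the reciprocal distance to the nearest CNT pixel, reported
in 1/um at the stated resolution (no canonical unit convention exists, so the resolution is always recorded alongside P).

Two deliberate definitional points:

- *Bounding box.* The tight union box has height `2 * sum L_odd` (the finest
  vertical branches end exactly at their tips); the published bounding areas
  correspond to `2 * sum L_odd + W_CNT`. `closed_form_metrics` uses the
  latter; the raster mask uses the tight box. The resulting A_Si difference
  is ~0.5 %, inside the 1 % oracle-agreement band.
- *Connected gap area.* The complement of a tree cannot be disconnected, so
  the raster "largest 4-connected gap component" of an H-tree is larger than
  the central-region closed form (`connected_gap_area` vs
  `connected_gap_area_closed`). Both are exposed; both decrease with `m` at
  fixed `D`.
- *Gap scaling with m.* At fixed `D = 2` and fixed `W`, more repeating levels
  shrink the smallest gap cell much faster than the largest one, so
  `A_r = A_max / A_min` *increases* with `m` (~17, ~40, ~117 for m = 4, 5, 6)
  by both the closed forms and the raster search, even though the narrative
  account of the gap-scaling trend is often given the other way around.
  This package follows the mathematics.

## Synthetic cultures

The generator emulates the *spatial statistics* of the cultures, not their
cell biology; it exists so the measurement pipeline can be validated against
exact ground truth. Defaults are the study conditions:

| parameter | default | meaning |
|---|---|---|
| `seed_density` | 9.3e3 cells/mm^2 | homogeneous Poisson seeding |
| `neuron_fraction` | 0.7 | neuron vs glia label (ratio not reported for the dissociated retina; only the spatial contrast depends on it) |
| `div` | 17 | culture age, one of {3, 7, 17} days in vitro |
| `migration_speed` | U(10, 20) um/h | hourly biased random walk |
| `cnt_neuron_affinity` | 3.0 | a/(a+1) chance a neuron anchors on texture |
| `gap_glia_affinity` | 10.0 | gap : electrode retention ratio for glia |
| `cluster_scale` | 100 um | soma-aggregation scale |
| `glia_radius` | 14 um | glial disk radius at 17 DIV (0 disables glia) |
| `proximity_scale` | 60 um | glial retention ~ min(1, 60/d) vs distance d |

Development rules: anchorer neurons walk until first electrode contact and
settle into the branch interior; non-anchorers remain in the gaps and
aggregate into clusters (grid binning at `cluster_scale`, >= 3 cells).
Processes are (i) edge followers — polylines 0.5 um inside branch edges, one
per anchored neuron at most, with mean length 110 um; (ii) bundles between
neighbouring gap clusters (straight, midpoint jitter); (iii) boundary links
from near-branch clusters to the nearest branch point; (iv) on-branch
networks linking anchored-soma clusters along branch centerlines, with rare
(p = 0.1) gap-bridging. Glial coverage is a disk per retained glial soma,
clipped to its surface (gap disks never cross the electrode edges, matching
the observed confinement), with retention weighted by proximity — producing
glia-rich boundary zones near branches and nearly bare "deserts" in
low-proximity gaps.

Time enters through fixed stage factors: lengths and link probabilities grow
to a maximal-complexity state at 7 DIV; by 17 DIV mutually-nearest clusters
coalesce and links are pruned (total process length falls ~30-50 %) while
glial disks keep growing. These factors express the reported qualitative
dynamics (a 7-DIV process-length peak, monotone glial growth); they are
structural constants, not fitted quantities.

All stochasticity flows from one seeded generator per scene; regeneration
from `(mask, params, seed)` is bit-identical. Ground truth is exact: polyline
lengths split by the mask label of each 2-um sub-segment, and shapely
polygon areas split against the vector branch geometry; the normalizing
areas are the mask's label counts, i.e. the same denominators the
measurement uses.

Two generator choices exist purely so the imaging chain can be held to a
tight recovery standard: cell bodies keep a 16 um margin from the field
border (a partially clipped soma cannot be recognized and removed), and soma
aggregates stay clear of the edge corridors used by edge-following processes
(blob radii capped by the local surface half-width / edge distance, process
endpoints trimmed just past the soma blur halo). Without these the measured
skeleton is biased by blob fragments and occlusion bites rather than by the
measurement itself.

**What the synthetic data does not show.** Processes are straight or gently
curved polylines, glia are disks, intensities are flat with Poisson +
Gaussian noise, there is no point-spread function, bleed-through, focus
variation or fabrication defect. Passing the recovery tests demonstrates
that the measurement chain is unbiased on images whose ground truth is
known — it does not certify accuracy on real micrographs, and the published
biological effect sizes and p-values are not reproducible from synthetic
data by construction.

## Imaging and measurement

Rendering follows the microscopy geometry: 16-bit fields of view
(2048 x 2048 px at 0.32 um/px by default) with 10 % overlap; stitching places
tiles on the fixed grid (stride = tile x 0.9) and averages overlap strips;
missing tiles are hard errors unless listed as excluded in the manifest (the
hook for the experimental practice of dropping deformed fields).

Measurement: the mask is aligned to the image grid (rasterized from the
vector tree when available, else nearest-label resampling; optional
dilation/erosion absorbs registration slack). The neuron channel is
binarized by Otsu with a separation guard (an image whose two Otsu classes
are closer than five background sigmas is treated as signal-free), soma
blobs are removed (opening with a ~1.6 um disk to erase thin processes, then
components with area > 80 um^2 and solidity > 0.8, dilated past the blur
halo), the remainder is skeletonized and summed with weight 1 per face step
and sqrt(2) per diagonal step (diagonals that shortcut an L-corner are not
double-counted), each step split half to the label of each endpoint pixel.
Overlapping or bundled processes collapse onto one centerline and are
counted once — the same overlap-insensitivity as the reference tracing
algorithm, and the mechanism behind the post-peak decline of measured
length. Glial coverage uses a global Otsu threshold (or a manual override)
plus a one-pixel opening.

Indices: `N_CNT, N_Si` (um of process per um^2 of surface), `G_CNT, G_Si`
(coverage fractions), `N = N_CNT/(N_CNT+N_Si)`, `G = G_Si/(G_CNT+G_Si)`,
`GN = G*N`; values above 0.5 mean successful herding. When both terms of an
index vanish the index is flagged None (never NaN-propagated). The glial
regime split is `low` iff `G <= 0.95` (boundary inclusive, threshold
configurable).

Measured recovery on default scenes (ten seeds per design, twelve designs,
512 x 512 um centered fields at 0.32 um/px): pooled normalized quantities
within 5 % of ground truth, N and G within 0.03, herding direction
reproduced on >= 99 % of scenes. The residual -2 to -4 % length bias is the
skeleton's endpoint erosion and junction merging; the ~+3-5 % gap-side bias
is the digital staircase of oblique lines under (1, sqrt 2) weighting.

## Statistics

Group comparisons are nonparametric: Kruskal-Wallis (tie-corrected, chi^2
p-values; degenerate all-equal input returns H = 0, p = 1) with Dunn's
post-hoc pairwise z-tests on the pooled ranks. Dunn p-values are raw by
default — the common convention after a significant omnibus test — with Holm
or Bonferroni available; for two groups H = z^2 exactly. Medians carry
seeded percentile-bootstrap 95 % confidence intervals (10^4 resamples by
default; undefined below n = 3). Null simulations show 4.9 % type-I rate at
alpha = 0.05 and ~94 % CI coverage for n = 20; both are checked in the test
suite. Stars follow the usual convention (* <= 0.05 through **** <= 1e-4).

## Problem sizes

Raster oracles run at 1 um/px on full designs (up to ~28 Mpx for the largest
tree). Synthetic-culture validation uses 512 x 512 um centered fields — large
enough to contain the multi-scale central structure of every design and the
>200 um desert zones of the most open fractal — with ten seeds per design
for recovery and twenty seeds per time point for the developmental peak.
These sizes are the package's validation defaults; all generators and
measurements accept arbitrary field sizes and resolutions.

## Known limitations

- The edge-follower model does not turn corners at branch junctions; each
  follower lives on one straight edge segment (junction-adjacent edges are
  populated independently).
- `A_max`/`A_c` closed forms assume the non-overlapping H-tree family; for
  arbitrary masks use the raster search and component labeling.
- The raster-derived edge extraction (used when no vector tree accompanies a
  mask) only recovers axis-aligned boundary runs.
- Glial morphology is a disk; elongated or branched glial shapes (observed
  on branches) are not modeled, only their area budget.
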