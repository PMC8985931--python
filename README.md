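# neuroherd

Tools for designing fractal and Euclidean microelectrode patterns and for
quantifying how dissociated retinal cells assemble on them — neurons
"herded" onto textured, vertically-aligned carbon-nanotube (VACNT) branches
and glia into the smooth SiO2 gaps between them. The package is aimed at
groups designing patterned neural interfaces and at image analysts who need
a validated, reproducible pipeline for the herding measurements.

## What it computes

**Electrode geometry.** H-tree fractals are parameterized by the fractal
dimension `D` (1 < D <= 2), the number of repeating H levels `m` (branch
orders n = 0..N, N = 2m - 1), the branch width `W_CNT` and the overall
width `W`; branch lengths follow `L_n = L_0 2^(-n/D)` with `L_0` solved
from the width constraint. Euclidean designs are rows of width `W_CNT`
separated by gaps `W_Si`. For both, the package computes edge length `E`
(and `E_n = E/W`), tortuosity `T`, mean proximity `P` (mean reciprocal
distance from gap pixels to the nearest branch), areas `A_CNT`, `A_Si`,
`A_bounding`, the multi-scale gap rectangles `A_min`, `A_max`,
`A_r = A_max/A_min`, the connected gap area `A_c`, and the characteristic
gap widths `W_Si_min`, `W_Si_max` — each by an exact closed form on the
vector geometry *and* by an independent raster oracle on the pixel mask.

**Herding quantification.** Two-channel label images (neuron processes,
glial coverage) are stitched from overlapping fields of view, masked into
CNT and gap surfaces, and measured: total neuronal process length by
skeletonization (overlap-insensitive — bundles count once), glial coverage
by thresholding. Normalized per surface area these give

    N = N_CNT / (N_CNT + N_Si),   G = G_Si / (G_CNT + G_Si),   GN = G N,

with 0.5 the neutral point and `G <= 0.95` / `G > 0.95` splitting low and
high glial-herding regimes.

**Synthetic cultures.** Because the raw micrographs behind the original
study are not public, the package ships a seeded generator that emulates
the cultures' spatial statistics (Poisson seeding at 9.3e3 cells/mm^2,
edge-following processes, soma-cluster bundles, proximity-weighted glial
coverage with boundary/cluster/desert structure, a 7-DIV process-length
peak) with exact ground truth, so the whole measurement chain is validated
end to end.

**Statistics.** Kruskal-Wallis omnibus tests with Dunn's post-hoc pairwise
comparisons (raw, Holm or Bonferroni p-values) and median summaries with
seeded bootstrap 95 % confidence intervals.

## Worked example

```python
import neuroherd as nh
from neuroherd.imaging import stitch_tiles, crop_to_scene

design = nh.FRACTAL_DESIGNS["2-6"]          # D = 2, m = 6, W = 6262 um
gm = nh.closed_form_metrics(design)

tree = nh.build_htree(design)
mask = nh.rasterize(tree, 0.32, bounds=(-256, -256, 256, 256))
params = nh.CultureParams(div=17, rng_seed=1)
scene = nh.simulate_development(nh.seed_cells(mask, params), mask, params)
gt = nh.ground_truth_measurements(scene, mask)

tiles, manifest = nh.render_fov_tiles(scene, pixel_size=0.32, tile=1024)
channels = crop_to_scene(stitch_tiles(tiles, manifest), manifest)
res = nh.quantify_scene(channels, mask, label=design.label, div=17)
```

printed output:

```
design 2-6: L0 = 1585.27 um, W_Si_min = 25.0 um, A_CNT = 8.83e+06 um^2, T = 3.464, E_n = 140.9
scene: 2440 cells, 117 processes, 496 glial regions
measured N_CNT = 0.0442, N_Si = 0.0065, G_CNT = 0.0401, G_Si = 0.7342
herding indices: N = 0.872, G = 0.948, GN = 0.827 -> regime low
ground truth:    N = 0.881, G = 0.948
```

Reading it: the branch geometry (solved base length 1585 um, smallest gap
25 um, branch area 8.8e6 um^2) matches the fabricated design; on a
512 x 512 um synthetic field at 17 DIV the pipeline measures about 7x more
normalized process length on the branches than in the gaps (N = 0.87) and
18x more glial coverage in the gaps than on the branches (G = 0.95), within
0.01 of the scene's exact ground truth — successful herding on both counts.

A thin CLI wraps the same functions:

```sh
neuroherd design   --type htree --d 2 --m 6 --wcnt 20 --width 6262 --out out/2-6
neuroherd metrics  --design out/2-6.json --out out/metrics.csv
neuroherd simulate --design out/2-6.json --div 17 --seed 1 --out out/scene
neuroherd quantify --tiles out/scene --design out/2-6.json --out out/results.csv
neuroherd compare  --results out/results.csv --group-by label --out out/stats.csv
```

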