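# vasquant

Automated quantification of vascular networks and pericyte coverage in 2D
fluorescence microscopy.

Microvascular remodelling — developmental angiogenesis, post-stroke
rarefaction in the ischemic border zone, pericyte loss in Alzheimer's
disease — is routinely read out from fluorescence images of endothelial
markers (CD31, lectin, Cldn5-GFP) and mural-cell markers (CD13, PDGFR-β).
`vasquant` turns such images into per-field numbers, reproducibly and
without manual tracing. It is a scriptable Python reimplementation of the
classic ImageJ-style workflow: binarize, skeletonize, measure.

For each calibrated field of view (pixel size in µm supplied explicitly)
the pipeline reports:

| measure | definition | unit |
|---|---|---|
| area fraction | vessel foreground pixels / total pixels | — |
| length density | Σ skeleton centerline length / field area | mm/mm² |
| branch-point density | merged skeleton junctions / field area | 1/mm² |
| nearest-neighbor distance | per vessel object, distance to the closest other object (mean ± SD) | µm |
| pericyte coverage | pericyte area fraction / vessel area fraction | — |
| heatmap | per-tile area fraction on an n×n grid of squares | — |

The skeleton analysis thins the mask homotopically (Lee-style medial-axis
thinning), classifies each skeleton pixel by its 8-neighbor count
(endpoint / slab / junction), merges adjacent junction pixels into single
branch points, and traces segments with the step-count metric (orthogonal
step = 1 px, diagonal = √2 px, measured up to the junction cluster's
central pixel).

Because real tissue comes without ground truth, the package ships a
synthetic-network generator — branching self-avoiding random walks
rasterized as tubes — whose centerline length, bifurcation count,
foreground area and pericyte fraction are known exactly. All validation
runs against it.

## Worked example

```sh
python examples/01_measure_synthetic_field.py
```

```
field: 512 x 512 px at 1.0 um/px = 0.2621 mm^2
area fraction        : 0.0369
length density       : 7.53 mm/mm^2
branch-point density : 72.5 /mm^2
mean NND             : 74.0 +/- 35.2 um over 20 objects

skeleton length 1973 um vs generated 1989 um (-0.82%)
branch points   19 vs generated 19
```

The field carries 3.7% vessel signal and 7.5 mm of centerline per mm²;
the measured skeleton length agrees with the generated centerline within
1% and every generated bifurcation is recovered. The other examples cover
pericyte coverage (`02`, a 43% stamped coverage is measured as exactly
0.4300), heatmaps (`03`, the weighted tile mean reproduces the global
area fraction to machine precision) and the batch pipeline + CLI (`04`).

On your own data:

```sh
vasquant analyze fields/*.tif --pixel-size 0.65 --vessel-channel 0 \
    --pericyte-channel 1 --tiles 10 --out results/
```

writes `results/results.csv` (one row per image), a heatmap PNG/CSV and
mask/skeleton QC TIFFs per image, plus the effective config and a run
log. `vasquant summarize results/results.csv --group-column group` adds
per-group descriptive statistics; inferential testing is deliberately out
of scope.

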