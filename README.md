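# phenocloud

Tools for evaluating geometric measurement accuracy from SfM-derived dense
point clouds of greenhouse scenes: survey planning (field of view, image
overlap, spatial resolution and the combined POU metric), dimension
extraction for calibration objects, greenness-index plant-height
measurement, and error statistics — driven by a seeded synthetic-scene
generator that stands in for real reconstructions.

## Package layout

| module                 | contents                                                                 |
|------------------------|--------------------------------------------------------------------------|
| `phenocloud.geometry`  | FOV, side/forward overlap, SR, POU, inverse survey planner               |
| `phenocloud.scene`     | synthetic clouds: cuboid/cylinder/mushroom objects, plants, POU-driven degradation, power-law error datasets |
| `phenocloud.objects`   | crop, bottom-zeroing, trimmed-histogram height, per-z-slice x/y extents  |
| `phenocloud.plants`    | TGI, exact 1-D 2-means segmentation, 50-bin plant height                 |
| `phenocloud.analysis`  | absolute errors, summaries, power regression, agreement stats, ANOVA     |
| `phenocloud.io`        | PLY (ASCII / binary LE) and CSV readers/writers                          |
| `phenocloud.config`    | YAML run configuration with strict schema validation                     |
| `phenocloud.cli`       | the `phenocloud` command                                                 |

All coordinates are millimetres; colors are 8-bit RGB.

## CLI

```bash
phenocloud plan                          # overlap + POU design tables
phenocloud --seed 3 simulate --shape cuboid --pou 278 --out obj.ply
phenocloud measure-objects --cloud obj.ply --regions regions.csv --out dims.csv
phenocloud measure-plants --cloud tray.ply --regions plants.csv --out heights.csv
phenocloud analyze --measurements dims.csv --truth truth.csv --out report/
phenocloud --seed 7 evaluate --out report/   # full synthetic experiment
```

Global options `--config cfg.yaml`, `--seed N`, `--log-level` come before
the subcommand. A single seed drives every stage; identical invocations
produce byte-identical outputs. `regions.csv` has columns
`object_id,x_min,x_max,y_min,y_max`; `truth.csv` has
`object_id,dim_x,dim_y,dim_z` (repeated manual readings per object are
averaged).

## Notes

- The trimmed-histogram estimators fall back from a two-sided to a
  one-sided trim when the two-sided trim would discard the majority of the
  values, so a concentrated bulk is never dropped in favour of outliers.
- 1-D 2-means is solved exactly (optimal threshold cut via prefix sums)
  rather than by randomly initialised Lloyd iteration, so segmentation is
  deterministic and globally optimal.
- The mushroom shape's x/y dimensions are systematically underestimated by
  slice averaging over the shrinking cap chords; this bias is inherent to
  the estimator and covered by tests.
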