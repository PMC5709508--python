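# rhizohair

A structural simulator of root-hair growth in labelled 3D soil volumes.
Hair populations are grown from a root or planar surface by stepwise,
collision-avoiding tip extension through a voxel grid of soil phases
(gaseous pore, hydrated textural, primary mineral, root), and quantified
with shell-binned total and fluid-coincident length profiles against
bulk-soil controls.

## What it does

- **Geometry** (`rhizohair.geometry`): generators for idealised BCC/HCP
  sphere packings, synthetic three-phase soil (smoothed random field,
  quantile-thresholded to requested volume fractions), and cylindrical
  root-in-soil domains; small-grain filtering by equivalent-sphere diameter;
  surface extraction with inward normals; Euclidean distance maps; TIFF+JSON
  volume I/O.
- **Seeding** (`rhizohair.seeding`): uniform-by-area surface seeding at a
  target density, seeds from partially visible hair segments, two-parameter
  Weibull ML fitting, and conditional ("future lifetime") length sampling by
  closed-form inversion.
- **Growth** (`rhizohair.growth`): per step, a spiral fan of quasi-equally
  spaced test points is classified into equal-width angular bins relative to
  the reference heading; invalid candidates (outside domain, deviation
  ≥ π/2, mineral/root collision, fluid-confinement violation) are discarded
  and a vector is drawn uniformly from the lowest non-empty bin. Reference
  heading is fixed (A0) or follows the previous step (A1); hairs either
  cross fluid boundaries freely (F0) or stay in the hydrated textural phase
  once inside (F1).
- **Morphometrics** (`rhizohair.morphometrics`): 50 µm shell length
  profiles (total and fluid-coincident), bulk-control wet approximation
  (L_wet = j·L_tot), explicit/control elevation, tortuosity, replicate
  statistics, profile periodicity.
- **CLI** (`rhizohair.cli`): `generate-geometry`, `seed`, `grow`,
  `quantify`, `compare`, `run-scenario`, `sweep`.

## CLI quick start

```sh
rhizohair generate-geometry --kind three_phase --domain-edge 1000 \
    --voxel-size 8 --seed 1 --out soil.tif
rhizohair seed --volume soil.tif --density 121 --seed 2 --out seeds.csv
rhizohair grow --volume soil.tif --seeds seeds.csv --length fixed:500 \
    --condition-a A1 --condition-f F1 --seed 3 --out paths.csv
rhizohair quantify --volume soil.tif --paths paths.csv --out profile.csv
```

Full scenario runs (explicit + matched empty-domain control, replicate
statistics, provenance record) are driven by a flat `key = value` config
file:

```sh
rhizohair run-scenario --config scenario.cfg --outdir out --seed 1
rhizohair sweep --config scenario.cfg --parameter step_length \
    --values 16,32,64 --out sweep.csv
```

Exit codes: 0 success, 2 configuration error, 3 runtime failure.

## File formats

- Label volumes: multi-page uint8 TIFF with a JSON sidecar
  (`<file>.json`) carrying `voxel_size_um`, origin, geometry kind and the
  label dialect `{pore: 0, textural: 1, mineral: 2, root: 3, outside: 255}`.
- Seeds / paths / profiles: CSV; hair paths additionally export as legacy
  ASCII VTK polydata for 3D rendering.
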