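# nodalmap

Observer-independent mapping and density analysis of nodal recurrence
patterns in a common template space.

The package implements a complete, testable pipeline for patterns-of-failure
analysis of lymph-node metastases:

- **`nodalmap.template`** — a common LPS voxel template with a synthetic
  nodal-level atlas (tube/box/ellipsoid primitives, mirror-symmetric paired
  levels), per-level volumes, Euclidean margin expansion, point
  classification, and consensus-coverage reporting.
- **`nodalmap.simulate`** — a synthetic cohort generator emulating the
  statistical structure the analyses assume: per-level involvement weights,
  zero-truncated negative-binomial node counts (median 2, range 1–11),
  mostly-unilateral laterality, anchor-level spatial clustering, a surgery
  covariate, and smooth per-patient displacement fields (with numerically
  inverted fields, round-trip accurate to < 0.2 mm).
- **`nodalmap.mapping`** — trilinear point mapping through displacement
  vector fields (native ↔ template), with edge-clamp flagging and per-node
  QC magnitudes. Image registration itself is out of scope; the pipeline
  consumes precomputed or synthetic fields.
- **`nodalmap.density`** — patient-equally-weighted 3D kernel density
  estimation in ‰/cm³ (rectangular p-norm kernel, default bandwidth
  12.5 mm, p = 2), Gaussian post-smoothing (default σ = 2.5 mm, physical
  units), and hotspot extraction.
- **`nodalmap.distances`** — intra-patient vs cohort-level pairwise
  distance statistics with a naive Welch comparison and a patient-level
  bootstrap alternative.
- **`nodalmap.levelstats`** — binary involvement tables, Fisher exact
  tests (log-space hypergeometric enumeration, minimum-likelihood
  two-sided rule) with Bonferroni adjustment, per-patient relative level
  proportions normalized by level volume against a homogeneous-distribution
  reference, and BCa bootstrap CIs / one-sample tests.
- **`nodalmap.pipeline` / `nodalmap.cli`** — reproducible end-to-end runs
  with manifests and checksums.

Volumes are read and written as NRRD (built-in raw codec) or NIfTI
(nibabel); node tables are CSV; metadata are JSON sidecars.

## CLI

```bash
nodalmap template --out atlas.nrrd                       # synthetic level atlas
nodalmap simulate --atlas atlas.nrrd --seed 7 --out cohort/
nodalmap map --nodes cohort/nodes_native.csv --dvf-dir cohort/ --out mapped.csv
nodalmap density --nodes mapped.csv --atlas atlas.nrrd --out density.nrrd
nodalmap distances --nodes mapped.csv --native cohort/nodes_native.csv --out dist.json
nodalmap levelstats --nodes mapped.csv --atlas atlas.nrrd --seed 7 --out stats.json
nodalmap run --seed 7 --out run/                         # full pipeline + report
nodalmap report --run-dir run/
```

`nodalmap run` accepts a YAML config with `gen`, `kde`, `bootstrap`,
`margins_mm`, `stages` and `template` sections; identical config + seed
reproduces byte-identical CSV/JSON outputs (checksums recorded in
`manifest.json`).

## Conventions

- Coordinates: LPS axis order, millimeters, voxel-center world mapping
  `world = origin + index * spacing`. All volume I/O assumes axis-aligned
  diagonal mappings.
- Density units: per-mm³ density × 10⁶ = ‰/cm³; no renormalization after
  smoothing (mass is reported in metadata).
- Percentages in reports are rounded half-up to one decimal.
- Quantiles use the linear-interpolation convention.
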