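# cryoskin

Coupled phase-change heat transfer and thermo-viscoelastic stress simulation
of skin cryopreservation, plus the accompanying bench-assay computations
(CPA permeation kinetics, DSC thermogram quantities, thermocouple-trace
nucleation analysis) and seeded synthetic-data generators so every stage is
testable offline.

## What it does

* **`cryoskin.materials`** — two-phase (frozen/liquid) material models:
  smoothed phase indicator, mixture rules for density / conductivity /
  apparent heat capacity (latent heat folded in through the bounded
  mass-fraction function), phase-change eigenstrain, and named CPA
  formulation presets with literature defaults.
* **`cryoskin.thermal_solver`** — transient 2D conduction with phase change
  on a structured cell grid (20 mm × 20 mm solution square with an embedded
  10 mm × 2 mm skin rectangle): cell-centered finite volumes, implicit
  stepping with an enthalpy-consistent Picard iteration, Dirichlet ramp /
  hold and convective-bath boundary stages, per-stage energy ledger.
* **`cryoskin.mech_solver`** — quasi-static plane-strain Maxwell
  thermo-viscoelastic stress on the same grid (bilinear elements, backward-
  Euler creep, thermal + phase-change eigenstrain, roller/fixed/free edge
  supports), with von Mises / principal-stress reductions, peak finding and
  midline profiles.
* **`cryoskin.scenario`** — protocol composition (−1 °C/min ramp to −80 °C
  plus LN2 stage; 37 °C water-bath rewarming from −196 °C), one-way coupled
  runs, probe traces (interface "Point 1" / solution "Point 2"), milestone
  extraction (ice onset per region, freeze/melt completion, stress peaks,
  interface lag) and deterministic config echo.
* **`cryoskin.assays`** — permeation chain from osmometry records
  (mol / weight / volume / concentration), uptake equilibration time, DSC
  onset / melting enthalpy / nonfreezing-water fraction, supercooling-
  recalescence-plateau event detection.
* **`cryoskin.synthetic_data`** — seeded generators (thermocouple traces,
  DSC thermograms, osmometry series) that always return the exact ground
  truth next to the data.

## CLI

One console script with three groups:

```bash
# simulations (milestone JSON, probe/stress CSV, VTK/HDF5 snapshots)
cryoskin simulate cool   --out-dir out --resolution 100 --preset none
cryoskin simulate rewarm --out-dir out --snapshot-interval 50
cryoskin simulate cycle  --config my_config.yaml --out-dir out

# bench-data analysis (CSV in, JSON report out)
cryoskin assay permeation --in osmometry.csv --out report.json
cryoskin assay dsc        --in scan.csv --out report.json --scan-rate 5 --water-fraction 0.8
cryoskin assay trace      --in probe.csv --out report.json --freezing-point -0.5

# synthetic fixtures (CSV plus a *_truth.json sidecar)
cryoskin synth trace      --seed 1 --out trace.csv
cryoskin synth dsc        --seed 1 --out dsc.csv
cryoskin synth permeation --seed 1 --out uptake.csv
```

`--config` accepts a YAML file with `grid`, `preset`, `materials` overrides,
`cooling` / `rewarming` protocol settings and `mech` edge supports; every
run echoes its full configuration into the milestone report so it can be
reproduced bit-identically.

## Notes

* Temperatures are kelvin internally; Celsius at the CLI/CSV interfaces.
* The convective term of the heat equation is dropped (no flow model); the
  liquid conductivity default is an effective value standing in for
  natural convection in the bath-warmed solution.
* Supplementary material parameters are not published with the paper;
  `materials.py` ships documented literature defaults, and everything is
  overridable from the YAML config.
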