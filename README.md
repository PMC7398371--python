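# fvstent

Fast virtual deployment of braided intracranial stents (flow diverters) on
vessel lumen surface meshes, producing swept 3D wire geometry ready for CFD
meshing. All lengths are millimetres.

The pipeline has four stages:

1. **Centerline** — extract and parameterize the parent-artery centerline
   from a watertight STL lumen surface (greedy maximal-inscribed-sphere
   marching, rotation-minimizing frames), or load one from CSV.
2. **Deployment** — initialize a cylindrical simplex-mesh tube along the
   centerline and expand it adaptively (uniform geometric growth, then
   per-vertex advance with Laplacian regularization) until it apposes the
   wall, capped at the device's labelled free diameter. Foreshortening is
   deliberately neglected, so the deployed length equals the labelled
   length exactly.
3. **Braid mapping** — lay a 16-wire braid (8 clockwise + 8
   counter-clockwise helices) onto the deployed surface in its
   (station, angle) parameter grid and sweep each wire into a capped
   watertight tube (no Boolean unions; wires overlay on one surface).
4. **Metrics** — diameter profile, apposition gap, axial length, wire
   lengths, measured braid angle, parameter-space metal coverage, pore
   density, and aneurysm morphometrics (neck width / dome height).

A `synthetic` module generates parametric phantoms with analytic ground
truth — straight tubes, curved (torus-segment) tubes, and a wide-necked
sidewall-aneurysm phantom (implicit smooth-min blend extracted via marching
cubes) whose preset reproduces neck width 12.27 mm and dome height 9.35 mm —
so every stage is testable without patient data.

## CLI

```sh
# generate a phantom (presets: paper | straight | curved)
fvs synth --preset paper --out vessel.stl --truth truth.json

# extract a centerline between two interior seed points
fvs centerline --vessel vessel.stl --seed-a 0,0,2 --seed-b 0,0,28 --out cl.csv

# deploy a 4.5 x 23 mm device
fvs deploy --vessel vessel.stl --centerline cl.csv --diameter 4.5 --length 23 \
    --out deployed.json --stl-out deployed.stl

# map and sweep the 16-wire braid
fvs braid --deployed deployed.json --wires 16 --angle 60 --wire-diameter 0.06 \
    --out stent.stl

# metrics report
fvs metrics --deployed deployed.json --vessel vessel.stl --out metrics.json

# or everything at once (deterministic; rerun reproduces bytes exactly)
fvs run --synth paper --out run_dir/
```

Exit codes: 0 ok, 2 bad input, 3 convergence/extraction failure.
Configuration is a flat `key=value` file (`--config`) plus `--set key=value`
overrides; unknown keys are rejected.

Defaults that are modelling assumptions rather than published device facts:
wire diameter 0.06 mm, braid angle 60° from the axis, parent-vessel bend
radius 20 mm / 80° in the `paper` preset.

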