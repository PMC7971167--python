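# retistim

A self-contained simulator of epiretinal electrical stimulation on synthetic
patient geometry:

1. **`retistim.geometry`** — parametric patient scenes (eye dimensions,
   electrode-array pose with tilt and standoff, smooth retinal
   thickness/height fields, fibrotic capsule) plus a seeded synthetic-patient
   generator; electrode–retina gap measurement along the array normal.
2. **`retistim.conductivity`** — voxelization of a scene onto a regular grid
   of tissue labels and bulk conductivities (vitreous / retina / fibrotic /
   sclera / electrode metal / insulator), with retina|sclera faces treated as
   a thin resistive membrane (RPE contact impedance).
3. **`retistim.fields`** — quasi-static Poisson solver for unit-current
   stimulation: cell-centred finite volumes with harmonic-mean face
   conductances, solved by conjugate gradients preconditioned with a Galerkin
   geometric multigrid plus floating-electrode deflation (numba kernels).
   Impedance, analytic disk/point-source oracles, fibrotic-conductivity
   calibration, trilinear field sampling, grid-convergence reports, HDF5/VTK
   export.
4. **`retistim.cable`** — multi-compartment retinal ganglion cell: five
   regions (soma, axon hillock, thin segment, sodium-channel band, distal
   axon) of 1-µm compartments with five voltage/calcium-gated currents plus
   leak (amphibian-lineage kinetics at 22 °C), driven through the
   extracellular potential at each compartment. Implicit (backward-Euler /
   Crank–Nicolson) cable integration with Rush–Larsen gating, biphasic
   charge-balanced waveforms, spike detection and initiation-site analysis.
5. **`retistim.retinotopy`** — Lloyd (centroidal-Voronoi) soma placement
   under electrodes and nerve-fiber-bundle axon trajectories (modified polar
   spiral with superior/inferior branches, raphe-respecting), 3-D embedding
   with a 90° bend (soma 55 µm deep, axon following the surface contour at
   15 µm).
6. **`retistim.thresholds`** — per-neuron bisection activation thresholds
   (0.25 µA bracket, one-spike-per-pulse criterion), per-electrode
   (population-minimum) thresholds, activation maps with bounding radii,
   axon-length and electrode-distance sweeps.
7. **`retistim.psycho`** — simulated yes/no observer (Weibull psychometric
   with guess/lapse rates), a staircase-seeded maximum-likelihood adaptive
   threshold procedure with interleaved catch trials, block audits
   (>25 % false-positive exclusion), Pearson/regression model-vs-observed
   comparison and one-way ANOVA across blocks.
8. **`retistim.workbench`** — run configuration, seed derivation, the
   end-to-end per-electrode pipeline (field → placement → routing →
   thresholds) with checksummed, bit-reproducible run directories, and report
   aggregation.

## CLI

```sh
retistim synth --seed 3 --out geom.json
retistim solve --electrode C5 --config run.json
retistim calibrate --target-z 8100 --bounds 0.15 0.37
retistim place --electrode C5 --n 250 --radius 500 --out somas.csv
retistim thresholds --electrode C5 --config run.json --seed 1 --out runs/r1
retistim psycho-sim --threshold 259 --threshold 300 --seed 1 --out trials.csv
retistim compare --model model.csv --observed observed.csv --min-observed 100
retistim report runs/r1
```

`--config` takes a JSON-serialized `RunConfig` (see
`retistim.workbench.RunConfig.to_json`); omitted options fall back to
documented defaults.

## Notes on defaults

Electrode-array geometry (6×10, 200 µm discs, 575 µm pitch), tissue
conductivities, RPE contact impedance, channel densities and the
nerve-fiber-model coefficients are literature-style defaults, all exposed in
configuration objects; synthetic patients are parameter-range stand-ins, not
reconstructions of any individual.
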