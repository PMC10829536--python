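# dbsvta

Volume-of-tissue-activated (VTA) estimation for directional deep-brain-
stimulation (DBS) leads on voxelized volume-conductor models, with a fully
synthetic head-phantom front end so every stage runs and is tested without
clinical imaging data.

Pipeline stages (one module per stage):

| module | role |
| --- | --- |
| `dbsvta.synthetic_head` | nested-ellipsoid head phantoms, target nuclei, pseudo-CT lead artifacts, patient fixture records |
| `dbsvta.lead_model` | lead-axis reconstruction from an artifact mask, 8-contact directional lead geometry (2 rings + 6 segments), rasterization into the tissue model |
| `dbsvta.field_solver` | finite-volume solve of `div(sigma grad phi) = 0` with harmonic-mean face conductivities, monopolar excitation (contact Dirichlet, bottom-face sink, Neumann elsewhere), impedance, nested local refinement |
| `dbsvta.impedance_calibration` | bisection on gray-matter conductivity until the simulated electrode impedance matches a measured value, with a refined-grid confirmation/correction |
| `dbsvta.vta_metric` | resampling onto a fine cube, Hessian of the potential, primary-eigenvalue thresholding (26.6 V/cm² default) into an activation mask |
| `dbsvta.outcome_report` | VTA-target overlap, outcome summaries, end-to-end per-patient orchestration |
| `dbsvta.oracles` | homogeneous closed-form harnesses (point source, sphere spreading resistance, analytic VTA volume) backing the verification suite |

## CLI

All commands live under a single `dbsvta` entry point:

```bash
dbsvta phantom build --patient 1 --out phantom/      # labels.nii + sigma table
dbsvta phantom fixture --patient 1                   # clinical record JSON
dbsvta lead fit --artifact artifact.nii              # axis from CT artifact
dbsvta solve --model labels.nii --sigma sigma.json \
             --current-ma 5.5 --out phi.nii          # potential + impedance
dbsvta calibrate --model labels.nii --sigma sigma.json \
             --target-ohm 926 --bracket 0.02 0.5
dbsvta vta --phi phi.nii --center 6 8 -10 --out vta.nii
dbsvta pipeline run --patient 1 --out results/ [--fast]
```

`pipeline run` executes phantom → artifact → trajectory fit → lead
rasterization → conductivity calibration → local refinement → VTA →
target overlap, and writes one CSV row per patient side plus NIfTI/JSON
artifacts. `--fast` switches to coarser grids (0.2 mm VTA) for CI.

## Conventions

Right-handed world millimetre coordinates, voxel-center sampling, 0-based
indices; NIfTI affines carry origin/spacing. Impedances in Ω, currents in A,
potentials in V, activation threshold in V/cm² (stored internally in V/m²),
volumes in mm³.
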