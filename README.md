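# erpfields

Probabilistic calibration of cardiac electrophysiology (EP) parameter fields
on surface-mesh manifolds from sparse, interval-censored measurements of the
effective refractory period (ERP).

The pipeline has four layers:

1. **`erpfields.cable`** — a 1D strip-of-tissue monodomain simulator for the
   modified Mitchell–Schaeffer (mMS) cell model (Crank–Nicolson diffusion +
   sub-cycled explicit reaction, numba-accelerated), with S1S2 and S1S2S3
   pacing protocols, ERP bracketing/bisection, activation/APD trace
   measurement, and training-table generation over parameter designs.
2. **`erpfields.manifold`** — cotangent-FEM Laplace–Beltrami eigenbases on
   triangle meshes and reduced-rank Gaussian processes built from them:
   spectral densities (RBF, Matérn-5/2), field evaluation/sampling,
   biharmonic distances, empirical lengthscale-to-mm calibration, and
   two-mesh field transfer. Plain-text mesh I/O (OBJ / ASCII PLY / legacy VTK).
3. **`erpfields.surrogate`** — maximin Latin-hypercube designs, bivariate
   cubic polynomial surrogates mapping (τ_out, APD_max) → ERP with a 280 ms
   ERP_S2 validity ceiling, and GAM (penalized-spline) variance-based
   sensitivity indices.
4. **`erpfields.calibration`** — the smoothed top-hat likelihood for ERP
   intervals, the log posterior over latent-field hyperparameters
   (m, α, ρ, η per field) with analytic gradients, a seeded Hamiltonian
   Monte Carlo sampler (burn-in + random thinning retention, split-R̂/ESS
   diagnostics), posterior field evaluation, and the biharmonic-weighted
   constraint projection of out-of-range posterior samples.

**`erpfields.synthetic`** generates fixture meshes (sphere, open cylinder,
ellipsoid with holes), ground-truth Matérn-5/2 parameter fields, maximin
observation designs with boundary exclusion, interval observations, and
RMSE/ISE validation including multi-configuration sweeps.

## CLI

A single entry point with one subcommand per pipeline stage:

```bash
erpfields simulate-strip --tau-out 10 --apd-max 200 --protocol S1S2
erpfields erp-table --n 100 --seed 7 --out table.csv
erpfields fit-surrogates --table table.csv --out surrogates.json
erpfields sensitivity --table table.csv
erpfields eigenbasis --fixture sphere --scale 25 --k 256 --out basis.npz
erpfields sample-field --basis basis.npz --rho 20 --seed 3 --out field.csv
erpfields make-config --out config.json      # paper-headline profile
erpfields run-pipeline --config config.json  # surrogates -> basis -> truth ->
                                             # observe -> calibrate -> validate
erpfields calibrate --config config.json --observations obs.csv
erpfields sweep --surrogates surrogates.json --out sweep.csv
```

Observation CSVs have columns
`vertex_id, protocol (S2|S3), interval_low_ms, interval_width_ms`.
Every run writes a `manifest.json` with the config, seeds, and SHA-256 of
each artifact; reruns with the same config reproduce the hashes.

## Units

mm, ms, normalized membrane voltage throughout; conduction velocities in
m/s equal mm/ms numerically. Kernel lengthscales are in mesh coordinate
units (mm for the shipped fixtures).
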