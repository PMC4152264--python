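# crowdbd

Coarse-grained Brownian dynamics of a crowded bacterial cytoplasm, with
mean-field hydrodynamic interactions and a full anomalous-diffusion
analysis suite.

Protein diffusion inside a cell is dramatically slower than in dilute
solution: macromolecules occupy 20–40% of the cytoplasmic volume, and both
excluded volume and solvent-mediated hydrodynamic interactions (HI) retard
every molecule.  `crowdbd` is for computational biophysicists who want to
simulate that regime at a resolution and cost where *many* independent
microsecond-to-millisecond trajectories are affordable, so that diffusion
coefficients and anomalous-diffusion diagnostics come with honest
statistical errors.

## The model

* **Proteins as flexible sphere clusters.**  Each protein is 1–5 spheres
  (k-means clusters of its Cα atoms; the count set by molecular weight),
  connected by stiff harmonic "stretch" bonds on every sphere pair and
  harmonic "bend" angles on every vertex triple.  Sphere radii scale with
  cluster residue count and are rescaled so the union volume of the spheres
  matches the all-atom volume.
* **Excluded volume.**  The only inter-protein force is a soft harmonic
  overlap penalty E_r = k_r(σ − r)² for sphere pairs closer than the sum of
  their radii σ (k_r = 0.1 kcal/mol/Å²; all harmonic terms use the E = k·x²
  convention).
* **Mean-field HI.**  Instead of an O(N³) diffusion-tensor treatment, each
  sphere's dilute-limit Stokes–Einstein coefficient D⁰ = kBT/6πηa is
  rescaled by its *local volume fraction* φ — the sphere-volume content of
  a ball of radius 4a around it, partial overlaps counted exactly — through
  the Tokuyama short-time hard-sphere correction:

      D = D⁰ / (1 + H(φ)),   b = √(9φ/8),  c = 11φ/16,
      H = 2b²/(1−b) − c/(1+2c) − bc(2+c)/[(1+c)(1−b+c)]

  At φ = 0.3 this halves D (1/(1+H) ≈ 0.47).
* **Overdamped propagation** (Ermak–McCammon):
  rⁿ⁺¹ = rⁿ + DⁿΔt Fⁿ/kBT + Rⁿ, with Gaussian Rⁿ of per-component variance
  2DⁿΔt, in a periodic cubic box (default 406 Å, Δt = 0.01 ns).
* **Analysis.**  Multi-origin MSD of molecular centers of mass; scaling
  exponent α from log-log fits; block-averaged D from the α = 1 intercept;
  time-dependent D(τ) = MSD/6τ; the displacement autocorrelation
  C_δ(t) = ⟨δr(T)·δr(T+t)⟩ whose negative minimum at t = δ is the
  fractional-Brownian-motion signature of subdiffusion
  (C_min = 2^(α−1) − 1); Gaussianity checks of displacement distributions.

See `docs/methods.md` for conventions, tolerances, guards and limitations.

## Worked example

Build a synthetic crowded box at cytoplasm-like occupancy, run 1 µs of BD
with hydrodynamics on, and analyze the tracer:

```python
import crowdbd as cb

state = cb.make_crowded_state(n_proteins=40, occupied_fraction=0.30, seed=21)
state.assign_dilute_diffusion(298.15, 0.891)       # Stokes–Einstein D0 per sphere
cfg = cb.SimulationConfig(box_length=state.box_length, n_steps=100_000,
                          save_interval=1.0, seed=5)
traj = cb.run_simulation(state.copy(), cfg)

com  = cb.com_trajectory(traj, state.tracer_molecules[0])
est  = cb.estimate_D_blocks(com, 1.0, discard=100.0, n_blocks=2, window=(20., 200.))
msd  = cb.msd_multi_origin(com, 1.0, max_lag=300.0)
corr = cb.displacement_autocorrelation(com, 1.0, delta=5.0, max_lag=100.0)
```

Output of the accompanying script (`alpha` below is the log-log MSD slope;
the last line inverts the correlation minimum):

```
box 155.4 A, 122 spheres, mean local phi 0.318
tracer D = 19.81 +/- 5.17 um^2/s  (blocks: 16.15, 23.46)
alpha (log-log fit) = 1.041 +/- 0.006
C_delta minimum = -0.0665 at t = 5 ns -> alpha = 0.901
tracer mean D0 (dilute) = 194.6 um^2/s
```

Reading it: at 30% occupancy the tracer diffuses an order of magnitude
slower than its dilute-limit value (19.8 vs 195 µm²/s — crowding plus
mean-field HI), and successive displacements are anticorrelated
(C_δ(δ) = −0.067), the FBM fingerprint of mild subdiffusion with
α ≈ 0.90; on these 20–200 ns lags the MSD itself is already back to
linear scaling.

The same pipeline is scriptable from the shell:

```bash
crowdbd build    --composition comp.tsv --box-length 406 --seed 1 --out box
crowdbd simulate --state box.state.npz --seed 1 --n-steps 100000 \
                 --save-interval 1.0 --out run.h5          # add --no-hi etc.
crowdbd analyze  --traj run.h5 --delta 5.0 --out-prefix results/run
```

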