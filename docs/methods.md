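# Methods

## Model

`crowdbd` simulates a periodic cubic box of coarse-grained proteins.  Each
protein is a flexible cluster of 1–5 spheres obtained by k-means clustering
of its Cα coordinates; the cluster count is a piecewise-constant function of
molecular weight (1 sphere below 5 kDa, then 2, 3, 4 across the 5–14,
14–23, 23–32 kDa bands, 5 above 32 kDa).  Band edges are treated as
half-open `[lo, hi)`: a 14 kDa protein gets 3 spheres, a 32 kDa protein 5.
Sphere radii scale as r_i ∝ n_i^(1/3) with n_i the residue count of cluster
i — volume proportional to residue count — and a single global scale factor
is found by Brent root finding so that the *union* volume of the placed
spheres (overlap counted once) matches an all-atom reference volume.  When
only the molecular weight is known the reference volume is MW × 1.21 Å³/Da,
the standard protein partial specific volume; a `linear` radius mode
(r_i ∝ n_i) is available for sensitivity checks.

Three harmonic potentials act on the spheres, all in the **E = k·x²
convention (no ½ prefactor)** — the force constants are meaningless without
this statement:

* stretching, every intra-protein sphere pair bonded at its reference
  distance, k_s = 0.06 kcal/mol/Å²;
* bending, every vertex-distinct triple at its reference angle,
  g = 0.006 kcal/mol/rad²;
* excluded volume, E_r = k_r (σ − r)² for inter-protein sphere pairs closer
  than the sum of radii σ, k_r = 0.1 kcal/mol/Å² (sweepable; 1.0 reduces D
  by several percent).  Spheres of the same protein never repel.

There are no electrostatics and no attractive terms.  All distances use the
minimum-image convention; components of a minimum-imaged displacement lie in
[−L/2, L/2).

## Hydrodynamics

Solvent-mediated coupling is a mean-field scalar, not a tensor.  For each
sphere the local volume fraction φ_i is the sphere-volume content of a
cutoff ball of radius R_cut = 4a_i, counting spheres partially inside the
ball by the exact spherical-lens intersection volume, divided by
(4/3)πR_cut³.  The sphere's own volume is included by default (an isolated
sphere has φ = 1/64 and diffuses ≈2.6% below Stokes–Einstein;
`include_self=False` restores the strict dilute limit).  The effective
diffusion coefficient is the Tokuyama–Oppenheim short-time hard-sphere
form

    D_i = D0_i / (1 + H(φ_i)),
    H = 2b²/(1−b) − c/(1+2c) − bc(2+c)/[(1+c)(1−b+c)],
    b = √(9φ/8), c = 11φ/16.

H(0.3) = 1.1143, so a sphere at cytoplasm-like local crowding diffuses at
≈0.47 of its dilute value.  H diverges as φ → 8/9; φ is clamped at 0.63
(random-close-packing vicinity) and the maximum φ seen is logged, because
runs without excluded volume can otherwise drive φ to unphysical values.
D0_i comes from Stokes–Einstein, D0 = kBT/(6πηa_i), at T = 298.15 K and
η = 0.891 mPa·s (water) by default; both are configurable and recorded in
trajectory metadata.

## Propagation

The overdamped Ermak–McCammon update is used throughout (mass never
enters):

    r_i^{n+1} = r_i^n + D_i^n Δt F_i^n / kBT + R_i^n,

with R_i^n Gaussian, independent per component, zero mean, variance
2 D_i^n Δt.  D is a scalar per sphere; there is no inter-sphere diffusion
tensor and no rotational coupling.  The ∇·D correction for
position-dependent diffusion is deliberately omitted (the mean-field D
varies slowly); the config flag for it exists but raises, so the omission
can never be silent.  Forces and φ are evaluated at r^n (explicit scheme).

Defaults: 406 Å box, Δt = 0.01 ns, positions recorded every 10 ns (1 ns or
finer for displacement-autocorrelation work).  Wrapped coordinates stay in
[0, L) with per-sphere integer image counters, so saved trajectories are
continuous (unwrapped).

**RNG policy.**  One (N, 3) block of standard normals is consumed per step
from a `numpy` PCG64 generator seeded by the run seed, no matter which
toggles (hydrodynamics, repulsion, frozen crowders) are active.  Paired
control runs with the same seed therefore share their noise stream exactly,
and runs are bit-reproducible.

**Neighbor search.**  Two Verlet candidate lists (rebuilt O(N²), compared
on squared distances): an excluded-volume list with a 10 Å skin and a φ
list with a 16 Å skin, each refreshed when any sphere has moved half its
skin since the last build.  A per-pair cutoff stored at build time lets the
φ evaluation skip shell pairs without a square root.  The φ list is not
built at all when hydrodynamics is off.  Unit tests pin both lists to
O(N²) brute-force evaluation.

**Numerical guards.**  The bending gradient's 1/sin θ factor is clamped at
sin θ = 1e-8 (measure-zero collinear configurations); coincident bonded or
repelling centers raise; any single-step displacement beyond
10·√(2 D0_max Δt) + 2 Å aborts the run with a diagnostic, as does a
non-finite force or D.

## Box assembly

Molecules are inserted at uniformly random positions and orientations
(quaternion-uniform rotations), rejecting placements whose deepest
inter-protein sphere overlap exceeds a tolerance.  Dense packings
(~30% occupied volume) use a 1–2 Å insertion tolerance followed by
steepest descent on the repulsive energy until the deepest overlap is
≤ 1 Å; the soft harmonic repulsion absorbs the residual during the
discarded equilibration segment.  Assembly is deterministic per seed.

## Analysis

* **MSD** — multi-time-origin ⟨|r(T+τ) − r(T)|²⟩ of a molecule's center of
  mass over every admissible origin, computed by the standard FFT
  decomposition and pinned to the naive sum in tests.  COM weights are
  sphere volumes (the residue-count proxy); a geometric-center option
  exists.
* **α** — OLS slope of log₁₀MSD vs log₁₀t in a stated window.
* **D** — block protocol: discard an initial segment, split the rest into
  equal blocks, fit each block's MSD in the α ≈ 1 window with the slope
  constrained to 1, read D off the intercept (log₁₀6D); report mean ± SD
  across blocks in µm²/s (1 Å²/ns = 10 µm²/s).  The free-slope α of the
  same window is attached, and the estimate is flagged (never silently
  accepted) when |α − 1| exceeds a tolerance (default 0.15).  SDs are
  never derived from overlapping-origin scatter, which is correlated.
* **C_δ(t)** — autocorrelation of span-δ displacement increments over all
  frame origins, returned raw and normalized by C_δ(0); the minimum over
  t ≥ δ is reported (for t < δ overlapping increments correlate trivially).
  Under fractional Brownian motion the normalized value at t = δ is
  2^(α−1) − 1, so the minimum inverts to α = 1 + log₂(1 + C_min), valid on
  −0.5 ≤ C_min ≤ 0.  For normal diffusion C_δ(t ≥ δ) = 0.
* **Gaussianity** — per-component excess kurtosis, skewness and a KS test
  against a moment-matched normal; a report, not a pass/fail gate.

## Synthetic study conditions

The generator module defines the conditions every test and the acceptance
run use: proteins of 1–5 spheres with radii drawn from 10–16 Å per sphere
(protein-like, up to ~30 Å with the size multiplier), neighbors attached at
85% of the radius sum so clusters overlap the way k-means clusters of a
compact chain do; crowded boxes at a cytoplasm-like 30% occupied volume
fraction (the cell's 20–40% macromolecular occupancy); a single flagged
tracer molecule.  Exact-covariance fractional Brownian motion
(Davies–Harte circulant embedding, Cholesky fallback) calibrates the
anomalous-diffusion estimators: its increment autocorrelation at lag δ is
2^(2H−1) − 1 by construction.

What the generator does **not** emulate: real protein shapes and the
measured E. coli abundance spectrum (the box is a uniform mixture of
synthetic 1–5-sphere clusters), electrostatics, attractive interactions,
polydispersity beyond the 10–16 Å radius band, and system sizes beyond a
few hundred spheres.  Passing tests therefore demonstrate correctness of
the mechanics and estimators and reproduce the *qualitative* control-
experiment phenomenology (HI slowdown factor, loss of anomalous diffusion
without repulsion, deeper correlation minima with frozen crowders), not
protein-specific absolute diffusion coefficients, which require the real
159-protein composition and millisecond trajectories.

## Problem sizes

Chosen so the whole suite runs on a single CPU in minutes: force-gradient
checks on ~12-sphere boxes (100 random states); free-diffusion and
mean-field-limit oracles on single spheres (10⁵–3×10⁵ steps); control
experiments on 40–55-protein boxes (~120–170 spheres) over 1–2×10⁵ steps;
the paired hydrodynamics comparison on a 140-protein (~420-sphere) box over
20 µs (2×10⁶ steps) per arm.  For that paired run the local volume
fractions are refreshed every 5 steps rather than every step: spheres move
~0.3 Å rms per step against R_cut ≈ 60 Å, so φ drifts by well under 1%
between refreshes; the default remains per-step evaluation.

## Known limitations

* The mean-field HI has no directionality: it slows spheres down but
  cannot produce the push–pull coupling of true pairwise hydrodynamics.
* Pairwise inclusion–exclusion union volumes neglect triple overlaps
  (slight underestimate for heavily overlapping clusters); a Monte-Carlo
  estimator is provided for verification.
* The block D estimator assumes the fit window sits in the α ≈ 1 regime;
  at desk scales the window is shorter than the 1–100 µs regime of
  full-scale runs and the α flag fires more readily.
* Freezing crowders removes their noise but keeps their forces and φ
  contributions; no attempt is made to re-equilibrate φ statistics under
  freezing.
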