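"""Synthetic fixtures: protein-like sphere clusters, crowded boxes and
fractional Brownian motion.

These generators define the study conditions for every test and the
scaled-down acceptance runs: 1–5-sphere proteins with radii in the
10–30 Å range, boxes packed to a cytoplasm-like ~30% occupied volume
fraction, and exact-covariance FBM paths for calibrating the
anomalous-diffusion estimators.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .cg_builder import assemble_box, build_topology
from .geometry import union_volume
from .model import CGProtein, SystemState

__all__ = [
    "make_synthetic_protein",
    "make_crowded_state",
    "fbm_increments",
    "fbm_path",
    "single_sphere_state",
]


def make_synthetic_protein(
    n_spheres: int,
    size_scale: float = 1.0,
    seed: int = 0,
    protein_id: Optional[str] = None,
    copy_number: int = 1,
    tracer: bool = False,
) -> CGProtein:
    """Random connected cluster of 1–5 spheres standing in for a
    PDB-derived model.

    Sphere radii are drawn uniformly from 10–16 Å (scaled by
    ``size_scale``, staying protein-like up to ~30 Å at size_scale 2);
    each sphere after the first is attached to a random previous sphere at
    85% of the sum of radii, so neighbours overlap the way k-means
    clusters of a compact chain do.  Molecular weight is back-computed
    from the union volume at 1.21 Å³/Da.  Deterministic per seed.
    """
    if not 1 <= n_spheres <= 5:
        raise ValueError("n_spheres must be in 1..5")
    rng = np.random.default_rng(seed)
    radii = rng.uniform(10.0, 16.0, size=n_spheres) * size_scale
    centers = np.zeros((n_spheres, 3))
    for i in range(1, n_spheres):
        parent = int(rng.integers(0, i))
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        dist = 0.85 * (radii[parent] + radii[i])
        centers[i] = centers[parent] + dist * direction
    centers -= centers.mean(axis=0)
    bonds, angles = build_topology(centers)
    mw = union_volume(centers, radii) / 1.21 / 1000.0  # kDa
    prot = CGProtein(
        protein_id=protein_id or f"syn{n_spheres}_{seed}",
        sphere_centers=centers,
        sphere_radii=radii,
        bonds=bonds,
        angles=angles,
        molecular_weight=mw,
        copy_number=copy_number,
        tracer=tracer,
    )
    prot.validate()
    return prot


def make_crowded_state(
    n_proteins: int = 140,
    occupied_fraction: float = 0.30,
    seed: int = 0,
    sphere_counts: Sequence[int] = (1, 2, 3, 4, 5),
    size_scale: float = 1.0,
    box_length: Optional[float] = None,
    tracer_spheres: Optional[int] = 3,
    overlap_tol: float = 2.0,
    relax: bool = True,
    relax_target: float = 1.0,
) -> SystemState:
    """Crowded periodic box of synthetic proteins at a target occupied
    volume fraction.

    Sphere counts cycle through ``sphere_counts`` (uniform mixture by
    default, ~3 spheres/protein).  If ``box_length`` is not given it is
    set so that the summed molecular union volumes occupy
    ``occupied_fraction`` of the box.  One molecule (``tracer_spheres``
    spheres, or the first molecule if None) is flagged as the tracer.
    Placement allows overlaps up to ``overlap_tol`` then relaxes to
    ``relax_target`` by steepest descent; the soft harmonic repulsion
    tolerates the residual during equilibration.
    """
    rng = np.random.default_rng(seed)
    proteins = []
    for m in range(n_proteins):
        k = int(sphere_counts[m % len(sphere_counts)])
        tracer = False
        if tracer_spheres is not None and m == 0:
            k = int(tracer_spheres)
            tracer = True
        elif tracer_spheres is None and m == 0:
            tracer = True
        proteins.append(
            make_synthetic_protein(
                k,
                size_scale=size_scale,
                seed=int(rng.integers(0, 2**31 - 1)),
                protein_id=f"mol{m:04d}",
                tracer=tracer,
            )
        )
    total_volume = sum(p.volume() for p in proteins)
    if box_length is None:
        box_length = (total_volume / occupied_fraction) ** (1.0 / 3.0)
        # keep R_cut = 4*a inside the half-box so HI stays valid; small
        # boxes then land below the requested occupancy
        amax = max(float(np.max(p.sphere_radii)) for p in proteins)
        box_length = max(box_length, 8.05 * amax)
    return assemble_box(
        proteins,
        box_length,
        seed=int(rng.integers(0, 2**31 - 1)),
        overlap_tol=overlap_tol,
        max_attempts=2000,
        relax=relax,
        relax_target=relax_target,
    )


def single_sphere_state(
    radius: float = 19.6, box_length: float = 1000.0, d0: Optional[float] = None
) -> SystemState:
    """One free sphere in a large box — the dilute-limit oracle system."""
    state = SystemState(
        box_length=box_length,
        positions=np.array([[box_length / 2] * 3]),
        radii=np.array([radius]),
        mol_index=np.array([0]),
        molecule_ids=["tracer"],
        tracer_molecules=[0],
    )
    if d0 is not None:
        state.d0 = np.array([float(d0)])
    return state


# ---------------------------------------------------------------------------
# fractional Brownian motion


def fbm_increments(
    n_steps: int,
    hurst: float,
    n_paths: int = 1,
    sigma2: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Fractional Gaussian noise by Davies–Harte circulant embedding.

    Exact covariance gamma(k) = sigma2/2 (|k+1|^{2H} - 2|k|^{2H} +
    |k-1|^{2H}) per unit-lag increment.  Returns (n_paths, n_steps).
    Falls back to a Cholesky construction if the circulant eigenvalues go
    (numerically) negative.
    """
    if not 0 < hurst < 1:
        raise ValueError("hurst must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    n = int(n_steps)
    k = np.arange(n + 1)
    gamma = sigma2 / 2.0 * (
        np.abs(k + 1) ** (2 * hurst)
        - 2 * np.abs(k) ** (2 * hurst)
        + np.abs(k - 1) ** (2 * hurst)
    )
    row = np.concatenate([gamma[: n + 1], gamma[1:n][::-1]])  # circulant, length 2n
    eig = np.fft.rfft(row).real
    if np.min(eig) < -1e-8 * sigma2:
        # rare for H in (0,1) at moderate n; exact dense fallback
        idx = np.arange(n)
        cov = sigma2 / 2.0 * (
            np.abs(idx[:, None] - idx[None, :] + 1) ** (2 * hurst)
            - 2 * np.abs(idx[:, None] - idx[None, :]) ** (2 * hurst)
            + np.abs(idx[:, None] - idx[None, :] - 1) ** (2 * hurst)
        )
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(n))
        return (chol @ rng.standard_normal((n, n_paths))).T
    eig = np.clip(eig, 0.0, None)
    m = 2 * n
    out = np.empty((n_paths, n))
    for p in range(n_paths):
        # hermitian-symmetric complex gaussian spectrum
        z = rng.standard_normal(len(eig)) + 1j * rng.standard_normal(len(eig))
        z[0] = rng.standard_normal() * np.sqrt(2.0)
        if m % 2 == 0:
            z[-1] = rng.standard_normal() * np.sqrt(2.0)
        spectrum = z * np.sqrt(eig * m / 2.0)
        path = np.fft.irfft(spectrum, n=m)
        out[p] = path[:n]
    return out


def fbm_path(
    n_steps: int,
    hurst: float,
    dt: float = 1.0,
    n_paths: int = 1,
    n_dim: int = 3,
    diffusion_scale: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """FBM position paths, shape (n_paths, n_steps+1, n_dim), starting at
    the origin.  Per-component increment variance over one step of length
    dt is 2*diffusion_scale*dt^{2H}, so hurst=0.5, diffusion_scale=D gives
    ordinary diffusion with MSD = 2*n_dim*D*t."""
    sigma2 = 2.0 * diffusion_scale * dt ** (2 * hurst)
    inc = fbm_increments(
        n_steps, hurst, n_paths=n_paths * n_dim, sigma2=sigma2, seed=seed
    )
    inc = inc.reshape(n_paths, n_dim, n_steps).transpose(0, 2, 1)
    paths = np.concatenate(
        [np.zeros((n_paths, 1, n_dim)), np.cumsum(inc, axis=1)], axis=1
    )
    return paths
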