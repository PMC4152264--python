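"""Ermak–McCammon Brownian-dynamics propagation.

The overdamped update for sphere i at step n is

    r_i^{n+1} = r_i^n + D_i^n * dt / (kB T) * F_i^n + R_i^n,

with R_i^n Gaussian (independent per component), zero mean and variance
2 D_i^n dt.  D_i^n is the Tokuyama-rescaled effective diffusion
coefficient evaluated at r^n (or the dilute-limit D0_i when hydrodynamics
is off).  Positions are wrapped into [0, L) with integer image counters,
so the saved trajectory is continuous (unwrapped).

The divergence (grad-D) correction for position-dependent diffusion is
omitted by design — the mean-field scheme treats D as slowly varying; a
config flag exists for sensitivity studies but is not implemented as a
propagation term (it raises if enabled).

RNG policy: a single (N, 3) block of standard normals is drawn every step
no matter which toggles are active, so runs that share a seed share the
noise stream across HI / repulsion / frozen-crowder variants.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np

from . import _kernels
from .model import SimulationConfig, SystemState, Trajectory
from .units import KB_KCAL_PER_MOL_K, stokes_einstein_d0

__all__ = ["stokes_einstein_D0", "bd_step", "run_simulation", "freeze_crowders"]

# re-export under the engine's conventional name
stokes_einstein_D0 = stokes_einstein_d0


class SimulationError(RuntimeError):
    """Instability or non-finite quantity during propagation."""


def bd_step(
    state: SystemState,
    forces: np.ndarray,
    effective_D: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    temperature: float = 298.15,
    noise_scale: float = 1.0,
) -> SystemState:
    """Single explicit BD step (reference implementation; the production
    loop lives in the compiled kernel).  Returns a new state; frozen
    spheres do not move.  ``noise_scale=0`` gives the deterministic drift
    limit used to test the mobility relation v = D F / kBT."""
    if not np.all(np.isfinite(forces)) or not np.all(np.isfinite(effective_D)):
        raise SimulationError("non-finite force or diffusion coefficient")
    kbt = KB_KCAL_PER_MOL_K * temperature
    new = state.copy()
    d = np.asarray(effective_D, float)
    xi = rng.standard_normal((state.n_spheres, 3))  # drawn for all spheres
    step = (d * dt / kbt)[:, None] * forces + (
        noise_scale * np.sqrt(2.0 * d * dt)[:, None]
    ) * xi
    step[state.frozen] = 0.0
    pos = new.positions + step
    shift = np.floor(pos / state.box_length)
    new.positions = pos - shift * state.box_length
    new.images = new.images + shift.astype(np.int64)
    return new


def _instability_bound(state: SystemState, dt: float) -> float:
    d0max = float(np.max(state.d0)) if state.d0 is not None else 1.0
    return 10.0 * np.sqrt(2.0 * d0max * dt) + 2.0


def run_simulation(state: SystemState, config: SimulationConfig) -> Trajectory:
    """Propagate ``state`` (in place) for config.n_steps and return the
    trajectory of unwrapped positions.

    Per-step order: Verlet-list refresh -> local volume fractions (HI) ->
    forces -> Ermak–McCammon update.  Bit-reproducible for a fixed seed.
    """
    config.validate(state)
    if config.divergence_correction:
        raise NotImplementedError(
            "grad-D correction is not part of the reference scheme"
        )
    if state.d0 is None:
        state.assign_dilute_diffusion(config.temperature, config.viscosity)

    n = state.n_spheres
    stride = config.save_stride
    n_frames = config.n_steps // stride + 1
    out_pos = np.zeros((n_frames, n, 3))
    out_energy = np.zeros((n_frames, 3))
    out_phimax = np.zeros(n_frames)
    kbt = KB_KCAL_PER_MOL_K * config.temperature

    # persistent buffers shared across noise chunks
    cap = n * (n - 1) // 2 + 1
    hi = config.hydrodynamics_enabled
    rep_i = np.empty(cap, np.int64)
    rep_j = np.empty(cap, np.int64)
    ph_i = np.empty(cap if hi else 1, np.int64)
    ph_j = np.empty(cap if hi else 1, np.int64)
    ph_c1 = np.empty(cap if hi else 1, float)
    ph_c2 = np.empty(cap if hi else 1, float)
    counts = np.zeros(3, np.int64)  # n_rep, n_phi, frame
    phi = np.zeros(n)
    deff = state.d0.copy()
    disp_r = np.zeros((n, 3))
    disp_p = np.zeros((n, 3))
    trackers = np.zeros(1)
    dmax = _instability_bound(state, config.dt)

    rng = np.random.default_rng(int(config.seed) % (2**31))
    chunk = max(1, min(config.n_steps, 4_000_000 // max(1, 3 * n))) or 1
    step0 = 0
    status = 0
    stop_step = config.n_steps
    while step0 < config.n_steps or (config.n_steps == 0 and step0 == 0):
        m = min(chunk, config.n_steps - step0)
        noise = rng.standard_normal((m, n, 3))
        status, stop_step = _kernels.integrate_chunk(
            state.positions,
            state.images,
            state.radii,
            state.mol_index,
            state.d0,
            state.frozen,
            state.bond_i,
            state.bond_j,
            state.bond_l0,
            state.ang_a,
            state.ang_v,
            state.ang_b,
            state.ang_t0,
            state.box_length,
            config.dt,
            kbt,
            config.k_stretch,
            config.k_bend,
            config.k_repulse,
            config.repulsion_enabled,
            hi,
            config.rcut_multiplier,
            config.include_self,
            config.phi_max,
            config.phi_update_interval,
            step0,
            stride,
            dmax,
            noise,
            rep_i,
            rep_j,
            ph_i,
            ph_j,
            ph_c1,
            ph_c2,
            counts,
            phi,
            deff,
            disp_r,
            disp_p,
            trackers,
            out_pos,
            out_energy,
            out_phimax,
        )
        if status != 0:
            break
        step0 += m
        if config.n_steps == 0:
            break
    max_phi = float(trackers[0])
    if status == 1:
        raise SimulationError(
            f"instability at step {stop_step}: a displacement exceeded the bound; "
            "reduce dt, relax the initial configuration, or lower k_repulse"
        )
    if status == 2:
        raise SimulationError(f"non-finite force or D at step {stop_step}")

    cfg = config.to_dict()
    meta = {
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "max_phi": float(max_phi),
        "molecule_ids": list(state.molecule_ids),
        "tracer_molecules": list(state.tracer_molecules),
        "energies_kcal_mol": {
            "stretch": float(out_energy[-1, 0]),
            "bend": float(out_energy[-1, 1]),
            "repulsion": float(out_energy[-1, 2]),
        },
    }
    times = np.arange(n_frames) * config.save_interval
    traj = Trajectory(
        times=times,
        positions=out_pos,
        radii=state.radii.copy(),
        mol_index=state.mol_index.copy(),
        box_length=state.box_length,
        metadata=meta,
    )
    if config.output_path:
        traj.save(config.output_path)
    return traj


def freeze_crowders(state: SystemState, tracer_ids) -> SystemState:
    """Return a state in which every molecule except the named tracers is
    frozen.  Frozen spheres still exert forces and contribute to phi; they
    simply do not move.  ``tracer_ids`` may be molecule indices or ids from
    ``state.molecule_ids``."""
    keep = set()
    for t in tracer_ids:
        if isinstance(t, str):
            if t not in state.molecule_ids:
                raise KeyError(f"unknown molecule id {t!r}")
            keep.update(
                m for m, mid in enumerate(state.molecule_ids) if mid == t
            )
        else:
            if not 0 <= int(t) < state.n_molecules:
                raise KeyError(f"molecule index {t} out of range")
            keep.add(int(t))
    new = state.copy()
    new.frozen = ~np.isin(new.mol_index, sorted(keep))
    return new
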