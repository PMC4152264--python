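"""Mean-field hydrodynamic interactions.

Each sphere's crowding is summarised by its local volume fraction phi_i:
the fraction of a cutoff ball of radius R_cut = 4*a_i (configurable
multiplier) occupied by sphere volume, counting spheres that lie partially
inside the ball by the exact lens intersection.  The sphere's dilute-limit
diffusion coefficient is then rescaled with the Tokuyama short-time
hard-sphere-suspension correction:

    D_i = D0_i / (1 + H(phi_i)),
    H(phi) = 2 b^2/(1-b) - c/(1+2c) - b c (2+c)/[(1+c)(1-b+c)],
    b = sqrt(9 phi / 8),  c = 11 phi / 16.

H(0) = 0 and H diverges as phi -> 8/9 (b -> 1); phi is therefore clamped
at ``phi_max`` (default 0.63, the random-close-packing vicinity) with the
clamp reported through the engine's max-phi log.

Including the sphere's own volume in phi_i (the default) means even an
isolated sphere diffuses ~2.6% below its Stokes–Einstein value, since
phi = a^3/(4a)^3 = 1/64; ``include_self=False`` restores the strict
dilute limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .geometry import min_image, sphere_overlap_volume, sphere_volume
from .model import SystemState

__all__ = [
    "HydroParams",
    "ball_sphere_overlap_volume",
    "local_volume_fraction",
    "local_volume_fractions",
    "tokuyama_H",
    "effective_diffusion",
]


@dataclass
class HydroParams:
    enabled: bool = True
    rcut_multiplier: float = 4.0
    include_self: bool = True
    phi_max: float = 0.63

    def __post_init__(self):
        if self.rcut_multiplier <= 1:
            raise ValueError("rcut_multiplier must exceed 1")
        if not 0 < self.phi_max < 1:
            raise ValueError("phi_max must lie in (0, 1)")


def ball_sphere_overlap_volume(d: float, R: float, a: float):
    """Volume of a sphere of radius ``a`` centered at distance ``d`` from
    the center of a cutoff ball of radius ``R`` that lies inside the ball.

    Full sphere volume when d <= R - a, zero when d >= R + a, spherical
    lens in between.  This is just the two-sphere intersection volume.
    """
    if np.any(np.asarray(d) < 0):
        raise ValueError("distance must be non-negative")
    return sphere_overlap_volume(d, R, a)


def local_volume_fraction(
    state: SystemState, sphere_index: int, params: HydroParams | None = None
) -> float:
    """Reference (pure-numpy, O(N)) evaluation of phi for one sphere."""
    params = params or HydroParams()
    i = int(sphere_index)
    a_i = state.radii[i]
    rcut = params.rcut_multiplier * a_i
    vloc = sphere_volume(rcut)
    num = sphere_volume(a_i) if params.include_self else 0.0
    if state.n_spheres > 1:
        others = np.arange(state.n_spheres) != i
        disp = min_image(
            state.positions[others] - state.positions[i], state.box_length
        )
        d = np.linalg.norm(disp, axis=1)
        num += float(
            np.sum(ball_sphere_overlap_volume(d, rcut, state.radii[others]))
        )
    return float(min(num / vloc, params.phi_max))


def local_volume_fractions(
    state: SystemState, params: HydroParams | None = None
) -> np.ndarray:
    """phi for every sphere via the cell/Verlet-list kernel the engine uses."""
    params = params or HydroParams()
    n = state.n_spheres
    cap = n * (n - 1) // 2 + 1
    ph_i = np.empty(cap, np.int64)
    ph_j = np.empty(cap, np.int64)
    ph_c1 = np.empty(cap, np.float64)
    ph_c2 = np.empty(cap, np.float64)
    n_phi = _kernels.build_phi_list(
        state.positions,
        state.radii,
        state.box_length,
        params.rcut_multiplier,
        0.0,
        ph_i,
        ph_j,
        ph_c1,
        ph_c2,
    )
    phi = np.zeros(n)
    _kernels.phi_kernel(
        state.positions,
        state.radii,
        ph_i,
        ph_j,
        ph_c1,
        ph_c2,
        n_phi,
        state.box_length,
        params.rcut_multiplier,
        params.include_self,
        params.phi_max,
        phi,
    )
    return phi


def tokuyama_H(phi, phi_max: float = 0.63):
    """Tokuyama–Oppenheim short-time correction H(phi); vectorised.

    Raises for phi outside [0, phi_max] — callers clamp before evaluating.
    """
    arr = np.asarray(phi, dtype=float)
    if np.any(arr < 0) or np.any(arr > phi_max + 1e-12):
        raise ValueError(f"phi outside [0, {phi_max}]")
    b = np.sqrt(9.0 * arr / 8.0)
    c = 11.0 * arr / 16.0
    out = (
        2.0 * b**2 / (1.0 - b)
        - c / (1.0 + 2.0 * c)
        - b * c * (2.0 + c) / ((1.0 + c) * (1.0 - b + c))
    )
    return out if out.ndim else float(out)


def effective_diffusion(
    state: SystemState, params: HydroParams | None = None
) -> np.ndarray:
    """Per-sphere D_i = D0_i / (1 + H(phi_i)); D0_i unchanged when disabled."""
    params = params or HydroParams()
    if state.d0 is None:
        raise ValueError("state.d0 not set; call assign_dilute_diffusion first")
    if not params.enabled:
        return state.d0.copy()
    phi = local_volume_fractions(state, params)
    return state.d0 / (1.0 + tokuyama_H(phi, params.phi_max))
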