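"""Bonded and excluded-volume potentials under periodic minimum-image
geometry.

Three harmonic terms, all without a 1/2 prefactor (E = k*x**2):

* stretching  E_s = sum_bonds  k_s (l - l0)^2      (intra-protein, all pairs)
* bending     E_b = sum_angles g   (theta - theta0)^2
* repulsion   E_r = sum_{inter-protein pairs, r < sigma} k_r (sigma - r)^2,
  with sigma the sum of the two sphere radii.  Spheres of the same protein
  never repel, regardless of distance.

Force constants are meaningless without the prefactor convention, so note
that the defaults (0.06, 0.006, 0.1 in kcal/mol per Å² or rad²) assume the
k*x² form above.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import _kernels
from .geometry import min_image
from .model import SystemState

__all__ = [
    "ForceFieldParams",
    "ForceReport",
    "stretch_energy_forces",
    "bend_energy_forces",
    "repulsion_energy_forces",
    "total_forces",
    "build_neighbor_pairs",
]


@dataclass
class ForceFieldParams:
    k_stretch: float = 0.06  # kcal/mol/Å²
    k_bend: float = 0.006  # kcal/mol/rad²
    k_repulse: float = 0.1  # kcal/mol/Å²
    repulsion_enabled: bool = True
    bonded_enabled: bool = True

    def __post_init__(self):
        if min(self.k_stretch, self.k_bend, self.k_repulse) < 0:
            raise ValueError("force constants must be non-negative")


@dataclass
class ForceReport:
    energies: dict = field(default_factory=dict)  # kcal/mol per term
    forces: np.ndarray = None  # (N, 3) kcal/mol/Å

    @property
    def total_energy(self) -> float:
        return float(sum(self.energies.values()))

    def __add__(self, other: "ForceReport") -> "ForceReport":
        en = dict(self.energies)
        for k, v in other.energies.items():
            en[k] = en.get(k, 0.0) + v
        return ForceReport(energies=en, forces=self.forces + other.forces)


def _check_bond_distances(state: SystemState) -> None:
    if len(state.bond_i) == 0:
        return
    d = min_image(
        state.positions[state.bond_i] - state.positions[state.bond_j],
        state.box_length,
    )
    if np.any(np.einsum("ij,ij->i", d, d) < 1e-20):
        raise ValueError("coincident bonded sphere centers: force direction undefined")


def stretch_energy_forces(state: SystemState, params: ForceFieldParams) -> ForceReport:
    """Harmonic all-pair bond term; forces are the exact negative gradient."""
    _check_bond_distances(state)
    forces = np.zeros((state.n_spheres, 3))
    e = _kernels.stretch_kernel(
        state.positions,
        state.bond_i,
        state.bond_j,
        state.bond_l0,
        params.k_stretch,
        state.box_length,
        forces,
    )
    return ForceReport(energies={"stretch": float(e)}, forces=forces)


def bend_energy_forces(state: SystemState, params: ForceFieldParams) -> ForceReport:
    forces = np.zeros((state.n_spheres, 3))
    e = _kernels.bend_kernel(
        state.positions,
        state.ang_a,
        state.ang_v,
        state.ang_b,
        state.ang_t0,
        params.k_bend,
        state.box_length,
        forces,
    )
    return ForceReport(energies={"bend": float(e)}, forces=forces)


def build_neighbor_pairs(state: SystemState, cutoff_pad: float = 0.0) -> np.ndarray:
    """All inter-protein sphere pairs within sigma + cutoff_pad (min image).

    O(N^2); the engine keeps its own incremental Verlet lists, this is the
    reference path used by the module API and the brute-force tests.
    """
    n = state.n_spheres
    out_i, out_j = [], []
    for i in range(n - 1):
        d = min_image(state.positions[i + 1 :] - state.positions[i], state.box_length)
        dist = np.linalg.norm(d, axis=1)
        sig = state.radii[i] + state.radii[i + 1 :]
        hit = np.nonzero(
            (dist < sig + cutoff_pad) & (state.mol_index[i + 1 :] != state.mol_index[i])
        )[0]
        out_i.extend([i] * len(hit))
        out_j.extend((hit + i + 1).tolist())
    return np.array([out_i, out_j], dtype=np.int64).reshape(2, -1)


def repulsion_energy_forces(
    state: SystemState,
    params: ForceFieldParams,
    pairs: Optional[np.ndarray] = None,
) -> ForceReport:
    """Inter-protein overlap penalty.  ``pairs`` is a (2, M) candidate list
    (e.g. from :func:`build_neighbor_pairs`); if omitted it is built fresh."""
    if pairs is None:
        pairs = build_neighbor_pairs(state, cutoff_pad=0.0)
    pair_i = np.ascontiguousarray(pairs[0], dtype=np.int64)
    pair_j = np.ascontiguousarray(pairs[1], dtype=np.int64)
    # guard: coincident centers of interacting pairs
    if len(pair_i):
        d = min_image(
            state.positions[pair_i] - state.positions[pair_j], state.box_length
        )
        if np.any(np.einsum("ij,ij->i", d, d) < 1e-20):
            raise ValueError("coincident sphere centers: repulsion direction undefined")
    forces = np.zeros((state.n_spheres, 3))
    e = _kernels.repulsion_kernel(
        state.positions,
        state.radii,
        pair_i,
        pair_j,
        len(pair_i),
        params.k_repulse,
        state.box_length,
        forces,
    )
    return ForceReport(energies={"repulsion": float(e)}, forces=forces)


def total_forces(state: SystemState, params: ForceFieldParams) -> ForceReport:
    """Sum of the enabled terms."""
    n = state.n_spheres
    report = ForceReport(energies={}, forces=np.zeros((n, 3)))
    if params.bonded_enabled:
        report = report + stretch_energy_forces(state, params)
        report = report + bend_energy_forces(state, params)
    if params.repulsion_enabled:
        report = report + repulsion_energy_forces(state, params)
    return report
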