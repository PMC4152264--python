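"""Domain types shared across the package.

A coarse-grained protein is a small cluster of spheres (1–5) with an
all-pairs harmonic bond network and all-vertex harmonic angles that pin
its reference geometry.  A system is a periodic cubic box of such
molecules; a trajectory is the time series of unwrapped sphere positions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .geometry import union_volume
from .units import stokes_einstein_d0

__all__ = ["CGProtein", "SystemState", "SimulationConfig", "Trajectory"]


@dataclass
class CGProtein:
    """One coarse-grained protein in its reference (local) frame.

    ``bonds`` rows are (i, j, l0) with l0 the reference center distance (Å);
    ``angles`` rows are (a, v, b, theta0) with v the vertex sphere and
    theta0 the reference angle (rad).
    """

    protein_id: str
    sphere_centers: np.ndarray  # (k, 3) Å
    sphere_radii: np.ndarray  # (k,) Å
    bonds: np.ndarray  # (m, 3) float: i, j, l0
    angles: np.ndarray  # (p, 4) float: a, vertex, b, theta0
    molecular_weight: float  # kDa
    copy_number: int = 1
    tracer: bool = False

    def __post_init__(self):
        self.sphere_centers = np.atleast_2d(np.asarray(self.sphere_centers, float))
        self.sphere_radii = np.atleast_1d(np.asarray(self.sphere_radii, float))
        self.bonds = np.asarray(self.bonds, float).reshape(-1, 3)
        self.angles = np.asarray(self.angles, float).reshape(-1, 4)

    @property
    def n_spheres(self) -> int:
        return len(self.sphere_radii)

    def validate(self) -> None:
        k = self.n_spheres
        if not 1 <= k <= 5:
            raise ValueError(f"{self.protein_id}: sphere count {k} outside 1..5")
        if np.any(self.sphere_radii <= 0):
            raise ValueError(f"{self.protein_id}: non-positive sphere radius")
        if self.copy_number < 1:
            raise ValueError(f"{self.protein_id}: copy_number must be >= 1")
        pairs = {tuple(sorted((int(i), int(j)))) for i, j, _ in self.bonds}
        expected = {(i, j) for i in range(k) for j in range(i + 1, k)}
        if pairs != expected:
            raise ValueError(f"{self.protein_id}: bond set is not all unordered pairs")
        for i, j, l0 in self.bonds:
            d = np.linalg.norm(self.sphere_centers[int(i)] - self.sphere_centers[int(j)])
            if abs(d - l0) > 1e-6 * max(1.0, d):
                raise ValueError(f"{self.protein_id}: bond l0 != reference distance")

    def volume(self) -> float:
        """Union volume of the placed spheres (Å³)."""
        return union_volume(self.sphere_centers, self.sphere_radii)

    def to_dict(self) -> dict:
        return {
            "protein_id": self.protein_id,
            "sphere_centers": self.sphere_centers.tolist(),
            "sphere_radii": self.sphere_radii.tolist(),
            "bonds": self.bonds.tolist(),
            "angles": self.angles.tolist(),
            "molecular_weight": self.molecular_weight,
            "copy_number": int(self.copy_number),
            "tracer": bool(self.tracer),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CGProtein":
        return cls(
            protein_id=d["protein_id"],
            sphere_centers=np.asarray(d["sphere_centers"], float),
            sphere_radii=np.asarray(d["sphere_radii"], float),
            bonds=np.asarray(d["bonds"], float).reshape(-1, 3),
            angles=np.asarray(d["angles"], float).reshape(-1, 4),
            molecular_weight=float(d["molecular_weight"]),
            copy_number=int(d.get("copy_number", 1)),
            tracer=bool(d.get("tracer", False)),
        )


@dataclass
class SystemState:
    """Periodic box of spheres with molecule bookkeeping.

    Positions are wrapped into [0, L); ``images`` holds the integer
    periodic image counters so that ``positions + images*L`` is the
    continuous (unwrapped) coordinate.  Global topology arrays index
    spheres of the whole box.
    """

    box_length: float
    positions: np.ndarray  # (N, 3) wrapped, Å
    radii: np.ndarray  # (N,)
    mol_index: np.ndarray  # (N,) int, molecule id per sphere
    images: np.ndarray = None  # (N, 3) int
    d0: Optional[np.ndarray] = None  # (N,) Å²/ns dilute-limit D
    frozen: np.ndarray = None  # (N,) bool
    # global topology
    bond_i: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    bond_j: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    bond_l0: np.ndarray = field(default_factory=lambda: np.zeros(0, float))
    ang_a: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    ang_v: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    ang_b: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    ang_t0: np.ndarray = field(default_factory=lambda: np.zeros(0, float))
    molecule_ids: list = field(default_factory=list)  # per molecule
    tracer_molecules: list = field(default_factory=list)  # molecule indices

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        n = len(self.positions)
        self.radii = np.asarray(self.radii, float).ravel()
        self.mol_index = np.asarray(self.mol_index, np.int64).ravel()
        if self.images is None:
            self.images = np.zeros((n, 3), np.int64)
        if self.frozen is None:
            self.frozen = np.zeros(n, bool)
        self.images = np.asarray(self.images, np.int64).reshape(-1, 3)
        self.frozen = np.asarray(self.frozen, bool).ravel()

    @property
    def n_spheres(self) -> int:
        return len(self.positions)

    @property
    def n_molecules(self) -> int:
        return 0 if self.n_spheres == 0 else int(self.mol_index.max()) + 1

    def unwrapped_positions(self) -> np.ndarray:
        return self.positions + self.images * self.box_length

    def assign_dilute_diffusion(self, temperature: float, viscosity: float) -> None:
        """Set per-sphere D0 from Stokes–Einstein at the given conditions."""
        self.d0 = np.array(
            [stokes_einstein_d0(a, temperature, viscosity) for a in self.radii]
        )

    def copy(self) -> "SystemState":
        return SystemState(
            box_length=self.box_length,
            positions=self.positions.copy(),
            radii=self.radii.copy(),
            mol_index=self.mol_index.copy(),
            images=self.images.copy(),
            d0=None if self.d0 is None else self.d0.copy(),
            frozen=self.frozen.copy(),
            bond_i=self.bond_i.copy(),
            bond_j=self.bond_j.copy(),
            bond_l0=self.bond_l0.copy(),
            ang_a=self.ang_a.copy(),
            ang_v=self.ang_v.copy(),
            ang_b=self.ang_b.copy(),
            ang_t0=self.ang_t0.copy(),
            molecule_ids=list(self.molecule_ids),
            tracer_molecules=list(self.tracer_molecules),
        )


@dataclass
class SimulationConfig:
    """Run control, physical constants and toggles for the BD engine.

    Defaults follow the reference protocol: 406 Å cubic box, 0.01 ns time
    step, positions recorded every 10 ns.  Temperature and viscosity set
    the Stokes–Einstein dilute-limit D of every sphere.
    """

    box_length: float = 406.0  # Å
    dt: float = 0.01  # ns
    n_steps: int = 1000
    save_interval: float = 10.0  # ns between saved frames
    temperature: float = 298.15  # K
    viscosity: float = 0.891  # mPa·s (water at 25 C)
    seed: int = 0
    hydrodynamics_enabled: bool = True
    repulsion_enabled: bool = True
    k_stretch: float = 0.06  # kcal/mol/Å²
    k_bend: float = 0.006  # kcal/mol/rad²
    k_repulse: float = 0.1  # kcal/mol/Å²
    rcut_multiplier: float = 4.0
    include_self: bool = True
    phi_max: float = 0.63
    phi_update_interval: int = 1  # steps between local-volume-fraction refreshes
    divergence_correction: bool = False  # grad-D term, off in the reference scheme
    output_path: Optional[str] = None

    def validate(self, state: Optional[SystemState] = None) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps < 0:
            raise ValueError("n_steps must be >= 0")
        stride = self.save_interval / self.dt
        if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
            raise ValueError("save_interval must be a positive integer multiple of dt")
        if self.phi_update_interval < 1:
            raise ValueError("phi_update_interval must be >= 1")
        if self.rcut_multiplier <= 1:
            raise ValueError("rcut_multiplier must exceed 1")
        if not 0 < self.phi_max < 1:
            raise ValueError("phi_max must lie in (0, 1)")
        if state is not None and state.n_spheres:
            amax = float(state.radii.max())
            need = 2.0 * self.rcut_multiplier * amax
            if self.box_length < need:
                raise ValueError(
                    f"box_length {self.box_length} too small: R_cut requires > {need}"
                )

    @property
    def save_stride(self) -> int:
        return int(round(self.save_interval / self.dt))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_yaml(self, path) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class Trajectory:
    """Uniformly spaced frames of unwrapped sphere positions."""

    times: np.ndarray  # (F,) ns
    positions: np.ndarray  # (F, N, 3) unwrapped Å
    radii: np.ndarray  # (N,)
    mol_index: np.ndarray  # (N,)
    box_length: float
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def frame_interval(self) -> float:
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        return float(self.times[1] - self.times[0])

    def save(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as fh:
            fh.create_dataset("times", data=self.times)
            fh.create_dataset("positions", data=self.positions)
            fh.create_dataset("radii", data=self.radii)
            fh.create_dataset("mol_index", data=self.mol_index)
            fh.attrs["box_length"] = self.box_length
            fh.attrs["metadata"] = json.dumps(
                self.metadata,
                default=lambda o: o.item() if hasattr(o, "item") else str(o),
            )

    @classmethod
    def load(cls, path) -> "Trajectory":
        import h5py

        with h5py.File(path, "r") as fh:
            return cls(
                times=fh["times"][...],
                positions=fh["positions"][...],
                radii=fh["radii"][...],
                mol_index=fh["mol_index"][...],
                box_length=float(fh.attrs["box_length"]),
                metadata=json.loads(fh.attrs.get("metadata", "{}")),
            )

    def to_xyz(self, path, element: str = "C") -> None:
        """Plain-text XYZ export for visualization tools."""
        with open(path, "w") as fh:
            n = self.positions.shape[1]
            for t, frame in zip(self.times, self.positions):
                fh.write(f"{n}\nt={t:.6g} ns\n")
                for x, y, z in frame:
                    fh.write(f"{element} {x:.4f} {y:.4f} {z:.4f}\n")
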