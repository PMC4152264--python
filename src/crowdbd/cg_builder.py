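"""Coarse-grained model construction.

Proteins are reduced to 1–5 spheres by k-means clustering of their Cα
coordinates; the cluster count is set by molecular weight (one sphere
below 5 kDa, then one more per ~9 kDa band up to five above 32 kDa).
Sphere radii scale with cluster residue counts and are globally rescaled
so the union volume of the spheres (overlap counted once) matches an
all-atom reference volume.  Every sphere pair is bonded harmonically at
its reference distance and every vertex triple carries a harmonic angle,
pinning the reference geometry while leaving the model flexible.

A crowded box is assembled from a composition table by inserting each
copy at a random position and orientation, rejecting placements that
overlap previously placed molecules beyond a tolerance, with an optional
steepest-descent relaxation on the repulsive energy for dense packings.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .forcefield import ForceFieldParams, total_forces
from .geometry import min_image, sphere_volume, union_volume
from .model import CGProtein, SystemState

__all__ = [
    "MW_BAND_EDGES",
    "VOLUME_PER_DALTON",
    "cluster_count_for_mw",
    "kmeans_calpha",
    "assign_radii",
    "build_topology",
    "coarse_grain",
    "read_calpha_pdb",
    "read_composition",
    "build_proteins",
    "assemble_box",
    "relax_overlaps",
    "save_model",
    "load_model",
    "write_pseudo_pdb",
]

#: molecular-weight band edges (kDa); bands are half-open [lo, hi), so a
#: protein exactly at an edge takes the larger cluster count
MW_BAND_EDGES = (5.0, 14.0, 23.0, 32.0)

#: all-atom reference volume per Dalton (standard protein partial specific
#: volume 0.73 cm^3/g = 1.21 Å³/Da), used when only the MW is known
VOLUME_PER_DALTON = 1.21


class PackingError(RuntimeError):
    """Random insertion failed; retry with relax=True or a larger box."""


def cluster_count_for_mw(mw: float, edges: Sequence[float] = MW_BAND_EDGES) -> int:
    """Number of coarse-grained spheres for a protein of ``mw`` kDa."""
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    k = 1
    for edge in edges:
        if mw >= edge:
            k += 1
    return k


def kmeans_calpha(calpha_coords, k: int, seed: int = 0):
    """k-means clustering of Cα coordinates (k-means++, 50 restarts,
    deterministic for a fixed seed).

    Labels are canonicalised by order of first appearance along the chain,
    so cluster 0 always contains residue 0.  Returns (labels, centers).
    """
    from sklearn.cluster import KMeans

    coords = np.asarray(calpha_coords, dtype=float).reshape(-1, 3)
    if k < 1 or len(coords) < k:
        raise ValueError(f"need at least k={k} residues, got {len(coords)}")
    if k == 1:
        return np.zeros(len(coords), dtype=int), coords.mean(axis=0, keepdims=True)
    km = KMeans(n_clusters=k, init="k-means++", n_init=50, random_state=int(seed))
    raw = km.fit_predict(coords)
    if len(np.unique(raw)) != k:
        raise ValueError("k-means produced an empty cluster")
    # canonical relabel: first-appearance order
    order = {}
    for lab in raw:
        if lab not in order:
            order[lab] = len(order)
    labels = np.array([order[lab] for lab in raw], dtype=int)
    centers = np.stack([coords[labels == c].mean(axis=0) for c in range(k)])
    return labels, centers


def assign_radii(
    labels,
    calpha_coords,
    target_volume: float,
    mode: str = "cuberoot",
) -> np.ndarray:
    """Sphere radii r_i = s * n_i^(1/3) (``mode='cuberoot'``, volume
    proportional to residue count) or r_i = s * n_i (``mode='linear'``),
    with the single scale s chosen by root finding so the union volume of
    the spheres placed at their cluster centers equals ``target_volume``.
    """
    if target_volume <= 0:
        raise ValueError("target_volume must be positive")
    labels = np.asarray(labels, dtype=int)
    coords = np.asarray(calpha_coords, dtype=float).reshape(-1, 3)
    k = labels.max() + 1
    counts = np.bincount(labels, minlength=k).astype(float)
    if np.any(counts == 0):
        raise ValueError("empty cluster in labels")
    centers = np.stack([coords[labels == c].mean(axis=0) for c in range(k)])
    if mode == "cuberoot":
        base = counts ** (1.0 / 3.0)
    elif mode == "linear":
        base = counts.copy()
    else:
        raise ValueError("mode must be 'cuberoot' or 'linear'")

    def f(s):
        return union_volume(centers, s * base) - target_volume

    # bracket: disjoint spheres give the upper volume bound (s_lo root if no
    # overlap); a single largest sphere the lower bound
    s_lo = (target_volume / float(np.sum(sphere_volume(base)))) ** (1.0 / 3.0)
    s_hi = (target_volume / float(sphere_volume(base.max()))) ** (1.0 / 3.0)
    s_lo *= 0.999
    s_hi *= 1.5
    if f(s_lo) > 0 or f(s_hi) < 0:
        raise RuntimeError("cannot bracket the radius scale for target volume")
    s = brentq(f, s_lo, s_hi, xtol=1e-12, rtol=1e-12)
    return s * base


def build_topology(centers):
    """All-pair bonds and all vertex-distinct angle triples with reference
    equilibrium geometry.  One sphere yields empty topology.

    Returns (bonds (m,3): i, j, l0;  angles (p,4): a, vertex, b, theta0).
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    k = len(centers)
    bonds = []
    for i in range(k):
        for j in range(i + 1, k):
            bonds.append((i, j, float(np.linalg.norm(centers[i] - centers[j]))))
    angles = []
    for v in range(k):
        others = [i for i in range(k) if i != v]
        for x in range(len(others)):
            for y in range(x + 1, len(others)):
                a, b = others[x], others[y]
                u = centers[a] - centers[v]
                w = centers[b] - centers[v]
                ct = np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w))
                angles.append((a, v, b, float(np.arccos(np.clip(ct, -1.0, 1.0)))))
    return (
        np.asarray(bonds, dtype=float).reshape(-1, 3),
        np.asarray(angles, dtype=float).reshape(-1, 4),
    )


def coarse_grain(
    calpha_coords,
    molecular_weight: float,
    protein_id: str = "protein",
    seed: int = 0,
    copy_number: int = 1,
    tracer: bool = False,
    target_volume: Optional[float] = None,
    radius_mode: str = "cuberoot",
) -> CGProtein:
    """Full pipeline: cluster count from MW, k-means, radii, topology."""
    coords = np.asarray(calpha_coords, dtype=float).reshape(-1, 3)
    k = cluster_count_for_mw(molecular_weight)
    k = min(k, len(coords))
    labels, centers = kmeans_calpha(coords, k, seed=seed)
    if target_volume is None:
        target_volume = molecular_weight * 1000.0 * VOLUME_PER_DALTON
    radii = assign_radii(labels, coords, target_volume, mode=radius_mode)
    centers = centers - centers.mean(axis=0)  # reference frame at centroid
    bonds, angles = build_topology(centers)
    prot = CGProtein(
        protein_id=protein_id,
        sphere_centers=centers,
        sphere_radii=radii,
        bonds=bonds,
        angles=angles,
        molecular_weight=molecular_weight,
        copy_number=copy_number,
        tracer=tracer,
    )
    prot.validate()
    return prot


def read_calpha_pdb(path) -> np.ndarray:
    """Cα coordinates from a PDB file: first model, altloc '' or 'A'."""
    import gemmi

    st = gemmi.read_structure(str(path))
    coords = []
    model = st[0]
    for chain in model:
        for residue in chain:
            for atom in residue:
                if atom.name == "CA" and atom.altloc in ("\x00", "", "A"):
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise ValueError(f"no Cα atoms found in {path}")
    return np.asarray(coords, dtype=float)


# ---------------------------------------------------------------------------
# composition table


def read_composition(path) -> pd.DataFrame:
    """TSV with header columns protein_id, source, molecular_weight,
    copy_number (and optional tracer).  ``source`` is a PDB path or a
    synthetic source ``synthetic:<n_spheres>``."""
    df = pd.read_csv(path, sep="\t")
    required = {"protein_id", "source", "molecular_weight", "copy_number"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"composition table missing columns: {sorted(missing)}")
    if df["protein_id"].duplicated().any():
        raise ValueError("protein_ids must be unique")
    if (df["copy_number"] < 1).any():
        raise ValueError("copy_number must be >= 1")
    return df


def build_proteins(composition: pd.DataFrame, seed: int = 0) -> List[CGProtein]:
    from .synthetic import make_synthetic_protein

    out = []
    for row_index, row in enumerate(composition.itertuples(index=False)):
        tracer = bool(getattr(row, "tracer", False))
        src = str(row.source)
        if src.startswith("synthetic:"):
            n_spheres = int(src.split(":", 1)[1])
            prot = make_synthetic_protein(
                n_spheres, seed=seed + 1000 * row_index, protein_id=row.protein_id
            )
            prot.molecular_weight = float(row.molecular_weight)
            prot.copy_number = int(row.copy_number)
            prot.tracer = tracer
        else:
            coords = read_calpha_pdb(src)
            prot = coarse_grain(
                coords,
                float(row.molecular_weight),
                protein_id=row.protein_id,
                seed=seed + 1000 * row_index,
                copy_number=int(row.copy_number),
                tracer=tracer,
            )
        out.append(prot)
    return out


# ---------------------------------------------------------------------------
# box assembly


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix from a normalised random quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _max_overlap(pos_new, rad_new, pos_old, rad_old, box) -> float:
    """Deepest inter-molecule sphere overlap (Å) under minimum image."""
    if len(pos_old) == 0 or len(pos_new) == 0:
        return 0.0
    worst = 0.0
    for p, a in zip(pos_new, rad_new):
        d = np.linalg.norm(min_image(pos_old - p, box), axis=1)
        depth = (rad_old + a) - d
        m = float(depth.max())
        if m > worst:
            worst = m
    return worst


def assemble_box(
    proteins: Sequence[CGProtein],
    box_length: float,
    seed: int = 0,
    overlap_tol: float = 0.0,
    max_attempts: int = 100_000,
    relax: bool = False,
    relax_target: Optional[float] = None,
    temperature: Optional[float] = None,
    viscosity: Optional[float] = None,
) -> SystemState:
    """Place every copy of every protein at a uniformly random position and
    orientation with no inter-protein overlap deeper than ``overlap_tol``.

    Deterministic for a fixed seed.  When a molecule cannot be inserted in
    ``max_attempts`` tries: with ``relax=False`` a :class:`PackingError` is
    raised (suggesting relaxation); with ``relax=True`` the least-bad
    candidate is accepted and a steepest-descent relaxation on the
    repulsive energy runs afterwards until the deepest overlap is at most
    ``relax_target`` (default: ``overlap_tol``).
    """
    if proteins:
        amax = max(float(np.max(p.sphere_radii)) for p in proteins)
        if box_length <= 2.0 * amax:
            raise ValueError("box_length must exceed twice the largest radius")
    rng = np.random.default_rng(seed)
    placed_pos: list = []
    placed_rad: list = []
    mol_index: list = []
    molecule_ids: list = []
    tracer_molecules: list = []
    bond_i, bond_j, bond_l0 = [], [], []
    ang_a, ang_v, ang_b, ang_t0 = [], [], [], []
    all_pos = np.zeros((0, 3))
    all_rad = np.zeros(0)
    needs_relax = False

    mol = 0
    for prot in proteins:
        local = prot.sphere_centers - prot.sphere_centers.mean(axis=0)
        for copy_idx in range(prot.copy_number):
            best = None
            best_depth = math.inf
            ok = False
            for _ in range(max_attempts):
                rot = _random_rotation(rng)
                origin = rng.uniform(0.0, box_length, size=3)
                cand = local @ rot.T + origin
                depth = _max_overlap(cand, prot.sphere_radii, all_pos, all_rad, box_length)
                if depth < best_depth:
                    best_depth = depth
                    best = cand
                if depth <= overlap_tol:
                    ok = True
                    break
            if not ok:
                if not relax:
                    raise PackingError(
                        f"could not place {prot.protein_id} copy {copy_idx} within "
                        f"{max_attempts} attempts (deepest residual overlap "
                        f"{best_depth:.2f} Å); rerun with relax=True or enlarge the box"
                    )
                needs_relax = True
            cand = best
            offset = len(all_pos)
            for i, j, l0 in prot.bonds:
                bond_i.append(offset + int(i))
                bond_j.append(offset + int(j))
                bond_l0.append(float(l0))
            for a, v, b, t0 in prot.angles:
                ang_a.append(offset + int(a))
                ang_v.append(offset + int(v))
                ang_b.append(offset + int(b))
                ang_t0.append(float(t0))
            placed_pos.append(cand)
            placed_rad.append(prot.sphere_radii)
            mol_index.extend([mol] * prot.n_spheres)
            molecule_ids.append(
                prot.protein_id if prot.copy_number == 1 else f"{prot.protein_id}#{copy_idx}"
            )
            if prot.tracer:
                tracer_molecules.append(mol)
            mol += 1
            all_pos = np.concatenate([all_pos, cand])
            all_rad = np.concatenate([all_rad, prot.sphere_radii])

    pos = all_pos if len(all_pos) else np.zeros((0, 3))
    shift = np.floor(pos / box_length) if len(pos) else pos
    state = SystemState(
        box_length=box_length,
        positions=pos - shift * box_length if len(pos) else pos,
        radii=all_rad,
        mol_index=np.asarray(mol_index, np.int64),
        images=shift.astype(np.int64) if len(pos) else None,
        bond_i=np.asarray(bond_i, np.int64),
        bond_j=np.asarray(bond_j, np.int64),
        bond_l0=np.asarray(bond_l0, float),
        ang_a=np.asarray(ang_a, np.int64),
        ang_v=np.asarray(ang_v, np.int64),
        ang_b=np.asarray(ang_b, np.int64),
        ang_t0=np.asarray(ang_t0, float),
        molecule_ids=molecule_ids,
        tracer_molecules=tracer_molecules,
    )
    if temperature is not None and viscosity is not None:
        state.assign_dilute_diffusion(temperature, viscosity)
    if needs_relax or (relax and relax_target is not None):
        relax_overlaps(
            state,
            target=relax_target if relax_target is not None else max(overlap_tol, 0.5),
        )
    return state


def relax_overlaps(
    state: SystemState,
    target: float = 0.5,
    max_iter: int = 2000,
    step_scale: float = 0.4,
    k_repulse: float = 0.1,
) -> float:
    """Steepest descent on the repulsive (+bonded) energy until the deepest
    inter-molecule overlap is at most ``target`` Å.  Returns the final
    deepest overlap; modifies the state in place."""
    params = ForceFieldParams(k_repulse=k_repulse)
    for _ in range(max_iter):
        worst = _deepest_overlap(state)
        if worst <= target:
            return worst
        rep = total_forces(state, params)
        f = rep.forces
        fmax = float(np.abs(f).max())
        if fmax == 0.0:
            return worst
        gamma = step_scale / fmax  # largest single move = step_scale Å
        pos = state.positions + gamma * f
        shift = np.floor(pos / state.box_length)
        state.positions = pos - shift * state.box_length
        state.images = state.images + shift.astype(np.int64)
    return _deepest_overlap(state)


def _deepest_overlap(state: SystemState) -> float:
    worst = 0.0
    pos, rad, mol, L = state.positions, state.radii, state.mol_index, state.box_length
    for i in range(state.n_spheres - 1):
        d = np.linalg.norm(min_image(pos[i + 1 :] - pos[i], L), axis=1)
        depth = (rad[i] + rad[i + 1 :]) - d
        depth[mol[i + 1 :] == mol[i]] = 0.0
        m = float(depth.max()) if len(depth) else 0.0
        if m > worst:
            worst = m
    return worst


# ---------------------------------------------------------------------------
# model I/O


def save_model(proteins: Sequence[CGProtein], path) -> None:
    with open(path, "w") as fh:
        json.dump({"proteins": [p.to_dict() for p in proteins]}, fh, indent=1)


def load_model(path) -> List[CGProtein]:
    with open(path) as fh:
        data = json.load(fh)
    return [CGProtein.from_dict(d) for d in data["proteins"]]


def write_pseudo_pdb(proteins_or_state, path) -> None:
    """One HETATM per sphere, radius in the B-factor column, for quick
    visual inspection in any molecular viewer."""
    lines = []
    serial = 1
    if isinstance(proteins_or_state, SystemState):
        st = proteins_or_state
        for i in range(st.n_spheres):
            x, y, z = st.positions[i]
            lines.append(
                f"HETATM{serial:5d}  CG  SPH A{int(st.mol_index[i]) % 9999 + 1:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{st.radii[i]:6.2f}          C"
            )
            serial += 1
    else:
        for m, prot in enumerate(proteins_or_state):
            for c, a in zip(prot.sphere_centers, prot.sphere_radii):
                x, y, z = c
                lines.append(
                    f"HETATM{serial:5d}  CG  SPH A{m % 9999 + 1:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{a:6.2f}          C"
                )
                serial += 1
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\nEND\n" if lines else "END\n"))
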