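"""Periodic-geometry and sphere-volume primitives.

All lengths in Å, volumes in Å³.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "min_image",
    "sphere_volume",
    "sphere_overlap_volume",
    "union_volume",
    "union_volume_mc",
]


def min_image(displacement, box_length: float):
    """Map displacement components into the half-open interval [-L/2, L/2).

    Works on a single 3-vector or any array of displacements.
    """
    if box_length <= 0:
        raise ValueError("box_length must be positive")
    d = np.asarray(displacement, dtype=float)
    return d - box_length * np.floor(d / box_length + 0.5)


def sphere_volume(radius):
    """Volume 4/3*pi*a^3 of a sphere (vectorised)."""
    r = np.asarray(radius, dtype=float)
    return 4.0 / 3.0 * np.pi * r**3


def sphere_overlap_volume(d, r1, r2):
    """Exact intersection volume of two spheres of radii ``r1``, ``r2``
    whose centers are a distance ``d`` apart.

    Piecewise: full containment of the smaller sphere when d <= |r1 - r2|,
    zero when d >= r1 + r2, the spherical-lens closed form in between.
    Continuous at both regime boundaries.  Vectorised over d.
    """
    d = np.asarray(d, dtype=float)
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    if np.any(r1 <= 0) or np.any(r2 <= 0):
        raise ValueError("radii must be positive")
    small = np.minimum(r1, r2)
    full = sphere_volume(small)
    with np.errstate(divide="ignore", invalid="ignore"):
        lens = (
            np.pi
            * (r1 + r2 - d) ** 2
            * (d**2 + 2.0 * d * (r1 + r2) - 3.0 * (r1 - r2) ** 2)
            / (12.0 * d)
        )
    out = np.where(d >= r1 + r2, 0.0, np.where(d <= np.abs(r1 - r2), full, lens))
    return out if out.ndim else float(out)


def union_volume(centers, radii) -> float:
    """Volume of a union of spheres.

    Exact for one or two spheres (lens formula).  For three or more,
    pairwise inclusion–exclusion: sum of sphere volumes minus the sum of
    pairwise intersection volumes; triple and higher overlaps are neglected
    (they slightly underestimate the union where three spheres share a
    region).  Use :func:`union_volume_mc` as an unbiased stochastic check.
    """
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    if len(radii) != len(centers):
        raise ValueError("centers and radii length mismatch")
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    total = float(np.sum(sphere_volume(radii)))
    n = len(radii)
    for i in range(n - 1):
        d = np.linalg.norm(centers[i + 1 :] - centers[i], axis=1)
        total -= float(np.sum(sphere_overlap_volume(d, radii[i], radii[i + 1 :])))
    return total


def union_volume_mc(centers, radii, n_samples: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the union volume (uniform sampling of the
    bounding box).  Standard error ~ V_box*sqrt(p(1-p)/n)."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 3)
    radii = np.asarray(radii, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    lo = (centers - radii[:, None]).min(axis=0)
    hi = (centers + radii[:, None]).max(axis=0)
    vbox = float(np.prod(hi - lo))
    hits = 0
    chunk = 250_000
    remaining = int(n_samples)
    while remaining > 0:
        m = min(chunk, remaining)
        pts = rng.uniform(lo, hi, size=(m, 3))
        inside = np.zeros(m, dtype=bool)
        for c, r in zip(centers, radii):
            inside |= np.einsum("ij,ij->i", pts - c, pts - c) <= r * r
        hits += int(inside.sum())
        remaining -= m
    return vbox * hits / n_samples
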