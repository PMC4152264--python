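"""Numba-compiled kernels for forces, local volume fractions and the
Ermak–McCammon propagation loop.

These are internal: the public surface lives in :mod:`crowdbd.forcefield`,
:mod:`crowdbd.hydrodynamics` and :mod:`crowdbd.bd_engine`.  Everything here
operates on plain float64/int64 arrays under the minimum-image convention.

Status codes returned by :func:`integrate`:
  0 ok; 1 instability (a per-step displacement exceeded the allowed bound);
  2 non-finite force or diffusion coefficient.
"""

import numpy as np
from numba import njit

SIN_CLAMP = 1e-8  # collinear-angle guard: sin(theta) floored at this value


@njit(cache=True, inline="always")
def _mi(x, box):
    """Minimum-image a scalar displacement component into [-L/2, L/2)."""
    return x - box * np.floor(x / box + 0.5)


@njit(cache=True, fastmath=True)
def stretch_kernel(pos, bond_i, bond_j, bond_l0, ks, box, forces):
    """Harmonic bond energy E = sum ks*(l - l0)^2 and forces (accumulated)."""
    e = 0.0
    for m in range(bond_i.shape[0]):
        i = bond_i[m]
        j = bond_j[m]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        dl = r - bond_l0[m]
        e += ks * dl * dl
        if r > 0.0:
            f = -2.0 * ks * dl / r
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
    return e


@njit(cache=True, fastmath=True)
def bend_kernel(pos, ang_a, ang_v, ang_b, ang_t0, kb, box, forces):
    """Harmonic angle energy E = sum kb*(theta - theta0)^2 and forces.

    Angle at vertex v between arms v->a and v->b.  The gradient has a
    1/sin(theta) factor; sin(theta) is clamped at SIN_CLAMP to stay finite
    at (measure-zero) collinear configurations.
    """
    e = 0.0
    for m in range(ang_v.shape[0]):
        a = ang_a[m]
        v = ang_v[m]
        b = ang_b[m]
        ux = _mi(pos[a, 0] - pos[v, 0], box)
        uy = _mi(pos[a, 1] - pos[v, 1], box)
        uz = _mi(pos[a, 2] - pos[v, 2], box)
        wx = _mi(pos[b, 0] - pos[v, 0], box)
        wy = _mi(pos[b, 1] - pos[v, 1], box)
        wz = _mi(pos[b, 2] - pos[v, 2], box)
        nu = np.sqrt(ux * ux + uy * uy + uz * uz)
        nw = np.sqrt(wx * wx + wy * wy + wz * wz)
        if nu == 0.0 or nw == 0.0:
            continue
        ct = (ux * wx + uy * wy + uz * wz) / (nu * nw)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = np.arccos(ct)
        dth = theta - ang_t0[m]
        e += kb * dth * dth
        st = np.sqrt(1.0 - ct * ct)
        if st < SIN_CLAMP:
            st = SIN_CLAMP
        # dtheta/dr_a = -(w_hat - ct*u_hat)/(nu*st); symmetric for b
        coef = -2.0 * kb * dth  # force prefactor: F = -dE/dtheta * dtheta/dr
        gax = -(wx / nw - ct * ux / nu) / (nu * st)
        gay = -(wy / nw - ct * uy / nu) / (nu * st)
        gaz = -(wz / nw - ct * uz / nu) / (nu * st)
        gbx = -(ux / nu - ct * wx / nw) / (nw * st)
        gby = -(uy / nu - ct * wy / nw) / (nw * st)
        gbz = -(uz / nu - ct * wz / nw) / (nw * st)
        fax = coef * gax
        fay = coef * gay
        faz = coef * gaz
        fbx = coef * gbx
        fby = coef * gby
        fbz = coef * gbz
        forces[a, 0] += fax
        forces[a, 1] += fay
        forces[a, 2] += faz
        forces[b, 0] += fbx
        forces[b, 1] += fby
        forces[b, 2] += fbz
        forces[v, 0] -= fax + fbx
        forces[v, 1] -= fay + fby
        forces[v, 2] -= faz + fbz
    return e


@njit(cache=True, fastmath=True)
def repulsion_kernel(pos, radii, pair_i, pair_j, n_pairs, kr, box, forces):
    """Inter-protein soft-core overlap penalty E = sum kr*(sigma - r)^2 for
    r < sigma = a_i + a_j, over a precomputed candidate pair list."""
    e = 0.0
    for m in range(n_pairs):
        i = pair_i[m]
        j = pair_j[m]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        r2 = dx * dx + dy * dy + dz * dz
        sigma = radii[i] + radii[j]
        if r2 >= sigma * sigma:
            continue
        r = np.sqrt(r2)
        ov = sigma - r
        e += kr * ov * ov
        if r > 0.0:
            f = 2.0 * kr * ov / r  # repulsive: push i away from j
            forces[i, 0] += f * dx
            forces[i, 1] += f * dy
            forces[i, 2] += f * dz
            forces[j, 0] -= f * dx
            forces[j, 1] -= f * dy
            forces[j, 2] -= f * dz
    return e


@njit(cache=True, inline="always")
def overlap_volume(d, r_big, r_small):
    """Intersection volume of spheres with radii r_big, r_small at center
    distance d (both orderings accepted)."""
    lo = abs(r_big - r_small)
    hi = r_big + r_small
    if d >= hi:
        return 0.0
    rm = r_small if r_small < r_big else r_big
    if d <= lo:
        return 4.0 / 3.0 * np.pi * rm * rm * rm
    return (
        np.pi
        * (hi - d) ** 2
        * (d * d + 2.0 * d * hi - 3.0 * (r_big - r_small) ** 2)
        / (12.0 * d)
    )


@njit(cache=True, fastmath=True)
def build_rep_list(pos, radii, mol, box, skin_rep, rep_i, rep_j):
    """O(N^2), sqrt-free rebuild of the repulsion Verlet list:
    inter-molecule pairs with d < a_i + a_j + skin_rep."""
    n = pos.shape[0]
    nr = 0
    cap = rep_i.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            if mol[i] == mol[j]:
                continue
            dx = _mi(pos[i, 0] - pos[j, 0], box)
            dy = _mi(pos[i, 1] - pos[j, 1], box)
            dz = _mi(pos[i, 2] - pos[j, 2], box)
            d2 = dx * dx + dy * dy + dz * dz
            c = radii[i] + radii[j] + skin_rep
            if d2 < c * c:
                if nr >= cap:
                    return -1
                rep_i[nr] = i
                rep_j[nr] = j
                nr += 1
    return nr


@njit(cache=True, fastmath=True)
def build_phi_list(
    pos, radii, box, rcut_mult, skin_phi, phi_i, phi_j, phi_c1, phi_c2
):
    """O(N^2), sqrt-free rebuild of the local-volume-fraction Verlet list:
    every pair that can contribute to either sphere's phi before the next
    rebuild.  Stores the two directional cutoffs (rcut_mult*a_i + a_j and
    the reverse) so the evaluation loop can skip shell pairs without a
    sqrt.  Returns the count; -1 signals overflow."""
    n = pos.shape[0]
    np_ = 0
    cap = phi_i.shape[0]
    for i in range(n - 1):
        for j in range(i + 1, n):
            dx = _mi(pos[i, 0] - pos[j, 0], box)
            dy = _mi(pos[i, 1] - pos[j, 1], box)
            dz = _mi(pos[i, 2] - pos[j, 2], box)
            d2 = dx * dx + dy * dy + dz * dz
            c1 = rcut_mult * radii[i] + radii[j]
            c2 = rcut_mult * radii[j] + radii[i]
            cmax = c1 if c1 > c2 else c2
            cmax += skin_phi
            if d2 < cmax * cmax:
                if np_ >= cap:
                    return -1
                phi_i[np_] = i
                phi_j[np_] = j
                phi_c1[np_] = c1
                phi_c2[np_] = c2
                np_ += 1
    return np_


@njit(cache=True, fastmath=True)
def phi_kernel(
    pos,
    radii,
    phi_i,
    phi_j,
    phi_c1,
    phi_c2,
    n_phi,
    box,
    rcut_mult,
    include_self,
    phi_max,
    phi,
):
    """Local volume fraction of every sphere (Eq.-7-style):

    phi_i = (self volume [optional] + sum of neighbor-sphere volume lying
    inside the cutoff ball of radius rcut_mult*a_i) / (4/3 pi R_cut^3),
    clamped to [0, phi_max].  Partial overlaps use the exact lens form.
    """
    n = pos.shape[0]
    self_frac = 1.0 / rcut_mult**3 if include_self else 0.0
    for i in range(n):
        phi[i] = self_frac
    for m in range(n_phi):
        i = phi_i[m]
        j = phi_j[m]
        c1 = phi_c1[m]
        c2 = phi_c2[m]
        dx = _mi(pos[i, 0] - pos[j, 0], box)
        dy = _mi(pos[i, 1] - pos[j, 1], box)
        dz = _mi(pos[i, 2] - pos[j, 2], box)
        d2 = dx * dx + dy * dy + dz * dz
        cmax = c1 if c1 > c2 else c2
        if d2 >= cmax * cmax:
            continue
        d = np.sqrt(d2)
        if d < c1:
            ri = rcut_mult * radii[i]
            phi[i] += overlap_volume(d, ri, radii[j]) / (4.0 / 3.0 * np.pi * ri**3)
        if d < c2:
            rj = rcut_mult * radii[j]
            phi[j] += overlap_volume(d, rj, radii[i]) / (4.0 / 3.0 * np.pi * rj**3)
    mx = 0.0
    for i in range(n):
        if phi[i] > mx:
            mx = phi[i]
        if phi[i] > phi_max:
            phi[i] = phi_max
    return mx


@njit(cache=True, inline="always")
def tokuyama_h_scalar(phi):
    """Tokuyama–Oppenheim short-time correction H(phi):
    b = sqrt(9 phi / 8), c = 11 phi / 16,
    H = 2 b^2/(1-b) - c/(1+2c) - b c (2+c) / ((1+c)(1-b+c))."""
    if phi <= 0.0:
        return 0.0
    b = np.sqrt(9.0 * phi / 8.0)
    c = 11.0 * phi / 16.0
    return (
        2.0 * b * b / (1.0 - b)
        - c / (1.0 + 2.0 * c)
        - b * c * (2.0 + c) / ((1.0 + c) * (1.0 - b + c))
    )


@njit(cache=True, fastmath=True)
def integrate_chunk(
    pos,
    img,
    radii,
    mol,
    d0,
    frozen,
    bond_i,
    bond_j,
    bond_l0,
    ang_a,
    ang_v,
    ang_b,
    ang_t0,
    box,
    dt,
    kbt,
    ks,
    kb,
    kr,
    rep_on,
    hi_on,
    rcut_mult,
    include_self,
    phi_max,
    phi_stride,
    step0,
    save_stride,
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
):
    """Ermak–McCammon steps for one noise chunk:

        r_i^{n+1} = r_i^n + D_i^n dt F_i^n / kBT + sqrt(2 D_i^n dt) xi_i^n.

    ``noise`` is a pre-drawn (chunk_steps, N, 3) block of standard normals:
    one (N, 3) slice is consumed per step regardless of toggles or frozen
    flags, so the random stream is identical across HI/repulsion/freezing
    variants of the same seed.  Verlet lists, local volume fractions,
    effective diffusion coefficients and displacement trackers persist
    across chunks through the caller-owned buffers:
    counts = [n_rep, n_phi, frame]; trackers = [max_phi_seen].
    At step0 == 0 the lists are built and frame 0 is written.

    Saves unwrapped positions (and per-term energies, max phi) every
    ``save_stride`` steps.  Returns (status, global_step) with status
    0 ok / 1 instability / 2 non-finite.
    """
    n = pos.shape[0]
    skin_rep = 10.0
    skin_phi = 16.0
    lim_r = (0.5 * skin_rep) ** 2
    lim_p = (0.5 * skin_phi) ** 2

    if step0 == 0:
        counts[0] = build_rep_list(pos, radii, mol, box, skin_rep, rep_i, rep_j)
        if hi_on:
            counts[1] = build_phi_list(
                pos, radii, box, rcut_mult, skin_phi, ph_i, ph_j, ph_c1, ph_c2
            )
            mx = phi_kernel(
                pos,
                radii,
                ph_i,
                ph_j,
                ph_c1,
                ph_c2,
                counts[1],
                box,
                rcut_mult,
                include_self,
                phi_max,
                phi,
            )
            out_phimax[0] = mx
            trackers[0] = mx
        counts[2] = 0
        for i in range(n):
            for k in range(3):
                out_pos[0, i, k] = pos[i, k] + img[i, k] * box

    forces = np.zeros((n, 3))
    n_chunk = noise.shape[0]
    for s in range(n_chunk):
        step = step0 + s
        # refresh each Verlet list when anything moved half its skin
        mxr = 0.0
        mxp = 0.0
        for i in range(n):
            d2 = disp_r[i, 0] ** 2 + disp_r[i, 1] ** 2 + disp_r[i, 2] ** 2
            if d2 > mxr:
                mxr = d2
            if hi_on:
                d2 = disp_p[i, 0] ** 2 + disp_p[i, 1] ** 2 + disp_p[i, 2] ** 2
                if d2 > mxp:
                    mxp = d2
        if mxr > lim_r:
            counts[0] = build_rep_list(pos, radii, mol, box, skin_rep, rep_i, rep_j)
            disp_r[:] = 0.0
        if hi_on and mxp > lim_p:
            counts[1] = build_phi_list(
                pos, radii, box, rcut_mult, skin_phi, ph_i, ph_j, ph_c1, ph_c2
            )
            disp_p[:] = 0.0

        # local volume fractions -> effective D
        if hi_on and step % phi_stride == 0:
            mx = phi_kernel(
                pos,
                radii,
                ph_i,
                ph_j,
                ph_c1,
                ph_c2,
                counts[1],
                box,
                rcut_mult,
                include_self,
                phi_max,
                phi,
            )
            if mx > trackers[0]:
                trackers[0] = mx
            for i in range(n):
                deff[i] = d0[i] / (1.0 + tokuyama_h_scalar(phi[i]))

        # forces at r^n
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        e_s = stretch_kernel(pos, bond_i, bond_j, bond_l0, ks, box, forces)
        e_b = bend_kernel(pos, ang_a, ang_v, ang_b, ang_t0, kb, box, forces)
        e_r = 0.0
        if rep_on:
            e_r = repulsion_kernel(
                pos, radii, rep_i, rep_j, counts[0], kr, box, forces
            )

        for i in range(n):
            if frozen[i]:
                continue
            di = deff[i]
            if not np.isfinite(di) or di < 0.0:
                return 2, step
            drift = di * dt / kbt
            amp = np.sqrt(2.0 * di * dt)
            ddx = drift * forces[i, 0] + amp * noise[s, i, 0]
            ddy = drift * forces[i, 1] + amp * noise[s, i, 1]
            ddz = drift * forces[i, 2] + amp * noise[s, i, 2]
            if not (np.isfinite(ddx) and np.isfinite(ddy) and np.isfinite(ddz)):
                return 2, step
            if ddx * ddx + ddy * ddy + ddz * ddz > dmax * dmax:
                return 1, step
            pos[i, 0] += ddx
            pos[i, 1] += ddy
            pos[i, 2] += ddz
            disp_r[i, 0] += ddx
            disp_r[i, 1] += ddy
            disp_r[i, 2] += ddz
            disp_p[i, 0] += ddx
            disp_p[i, 1] += ddy
            disp_p[i, 2] += ddz
            # wrap into [0, L)
            for k in range(3):
                sh = np.floor(pos[i, k] / box)
                if sh != 0.0:
                    pos[i, k] -= sh * box
                    img[i, k] += np.int64(sh)

        if (step + 1) % save_stride == 0:
            counts[2] += 1
            frame = counts[2]
            for i in range(n):
                for k in range(3):
                    out_pos[frame, i, k] = pos[i, k] + img[i, k] * box
            out_energy[frame, 0] = e_s
            out_energy[frame, 1] = e_b
            out_energy[frame, 2] = e_r
            if hi_on:
                out_phimax[frame] = trackers[0]

    return 0, step0 + n_chunk
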