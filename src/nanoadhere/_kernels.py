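"""Compiled Monte Carlo kernels.

All hot loops live here as numba ``njit`` functions operating on flat
arrays.  The Python-facing engine (`nanoadhere.engine`) owns scheduling,
burn-in tuning, observable assembly and checkpointing; the kernel executes
a batch of attempted moves and updates state in place.

Move kinds (the seven-move scheme):
  0 vertex move, 1 link flip, 2 NC translation, 3 NC rotation,
  4 receptor diffusion, 5 receptor flexure (Rosenbluth),
  6 bond make/break (configurational-bias with analytic cap densities).

Energies are k_B T, lengths nm.  The membrane energy per vertex is
``kappa |lap|^2 / (8 A_v) + sigma A_v`` with ``lap`` the cotangent
Laplacian of the position — identical arithmetic to the Python-side
``mesh`` module, so full recomputation cross-checks the running total.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _wrap(d, box):
    if box > 0.0:
        return d - box * np.round(d / box)
    return d


@njit(cache=True)
def _tri_area_vec(t, pos, tris, box, out):
    a, b, c = tris[t, 0], tris[t, 1], tris[t, 2]
    e1x = _wrap(pos[b, 0] - pos[a, 0], box)
    e1y = _wrap(pos[b, 1] - pos[a, 1], box)
    e1z = pos[b, 2] - pos[a, 2]
    e2x = _wrap(pos[c, 0] - pos[a, 0], box)
    e2y = _wrap(pos[c, 1] - pos[a, 1], box)
    e2z = pos[c, 2] - pos[a, 2]
    out[0] = 0.5 * (e1y * e2z - e1z * e2y)
    out[1] = 0.5 * (e1z * e2x - e1x * e2z)
    out[2] = 0.5 * (e1x * e2y - e1y * e2x)


@njit(cache=True)
def vertex_energy(v, pos, nbr, nlink, deg, link_opp, link_tri, tris,
                  box, kappa, sigma):
    """Bending + tension energy associated with vertex v (k_B T)."""
    lapx = 0.0
    lapy = 0.0
    lapz = 0.0
    A_v = 0.0
    av = np.empty(3)
    for k in range(deg[v]):
        j = nbr[v, k]
        li = nlink[v, k]
        # vertex area: each incident triangle appears for two incident links
        for s in range(2):
            t = link_tri[li, s]
            _tri_area_vec(t, pos, tris, box, av)
            A_v += np.sqrt(av[0] ** 2 + av[1] ** 2 + av[2] ** 2) / 6.0
        # cotangent weights at the two opposite vertices
        w = 0.0
        for s in range(2):
            o = link_opp[li, s]
            ux = _wrap(pos[v, 0] - pos[o, 0], box)
            uy = _wrap(pos[v, 1] - pos[o, 1], box)
            uz = pos[v, 2] - pos[o, 2]
            wx = _wrap(pos[j, 0] - pos[o, 0], box)
            wy = _wrap(pos[j, 1] - pos[o, 1], box)
            wz = pos[j, 2] - pos[o, 2]
            dot = ux * wx + uy * wy + uz * wz
            cx = uy * wz - uz * wy
            cy = uz * wx - ux * wz
            cz = ux * wy - uy * wx
            cross = np.sqrt(cx * cx + cy * cy + cz * cz)
            if cross < 1e-12:
                cross = 1e-12
            w += dot / cross
        dx = _wrap(pos[v, 0] - pos[j, 0], box)
        dy = _wrap(pos[v, 1] - pos[j, 1], box)
        dz = pos[v, 2] - pos[j, 2]
        lapx += w * dx
        lapy += w * dy
        lapz += w * dz
    if A_v < 1e-12:
        A_v = 1e-12
    lap2 = lapx * lapx + lapy * lapy + lapz * lapz
    return kappa * lap2 / (8.0 * A_v) + sigma * A_v


@njit(cache=True)
def patch_energy(vs, nv, pos, nbr, nlink, deg, link_opp, link_tri, tris,
                 box, kappa, sigma):
    e = 0.0
    for i in range(nv):
        e += vertex_energy(vs[i], pos, nbr, nlink, deg, link_opp,
                           link_tri, tris, box, kappa, sigma)
    return e


@njit(cache=True)
def total_membrane_energy(pos, nbr, nlink, deg, link_opp, link_tri,
                          tris, box, kappa, sigma):
    e = 0.0
    for v in range(pos.shape[0]):
        e += vertex_energy(v, pos, nbr, nlink, deg, link_opp, link_tri,
                           tris, box, kappa, sigma)
    return e


@njit(cache=True)
def vertex_normal(v, pos, nlink, deg, link_tri, tris, box, out):
    out[0] = 0.0
    out[1] = 0.0
    out[2] = 0.0
    av = np.empty(3)
    for k in range(deg[v]):
        li = nlink[v, k]
        for s in range(2):
            t = link_tri[li, s]
            _tri_area_vec(t, pos, tris, box, av)
            out[0] += av[0]
            out[1] += av[1]
            out[2] += av[2]
    n = np.sqrt(out[0] ** 2 + out[1] ** 2 + out[2] ** 2)
    if n < 1e-12:
        n = 1e-12
    out[0] /= n
    out[1] /= n
    out[2] /= n


@njit(cache=True)
def _tangent_frame(n, t1, t2):
    """Deterministic tangent frame from the global x axis (matches
    molecules.tangent_frame)."""
    d = n[0]
    t1[0] = 1.0 - n[0] * d
    t1[1] = -n[1] * d
    t1[2] = -n[2] * d
    tn = np.sqrt(t1[0] ** 2 + t1[1] ** 2 + t1[2] ** 2)
    if tn < 1e-8:
        d = n[1]
        t1[0] = -n[0] * d
        t1[1] = 1.0 - n[1] * d
        t1[2] = -n[2] * d
        tn = np.sqrt(t1[0] ** 2 + t1[1] ** 2 + t1[2] ** 2)
    t1[0] /= tn
    t1[1] /= tn
    t1[2] /= tn
    t2[0] = n[1] * t1[2] - n[2] * t1[1]
    t2[1] = n[2] * t1[0] - n[0] * t1[2]
    t2[2] = n[0] * t1[1] - n[1] * t1[0]


@njit(cache=True)
def receptor_tip_kernel(v, theta, phi, rec_len, pos, nlink, deg, link_tri,
                        tris, box, out):
    """Tip of the receptor based at vertex v."""
    n = np.empty(3)
    t1 = np.empty(3)
    t2 = np.empty(3)
    vertex_normal(v, pos, nlink, deg, link_tri, tris, box, n)
    _tangent_frame(n, t1, t2)
    st = np.sin(theta)
    ct = np.cos(theta)
    cp = np.cos(phi)
    sp = np.sin(phi)
    for i in range(3):
        out[i] = pos[v, i] + rec_len * (ct * n[i] + st * (cp * t1[i] + sp * t2[i]))


@njit(cache=True)
def _quat_mul(a, b, out):
    out[0] = a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3]
    out[1] = a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2]
    out[2] = a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1]
    out[3] = a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0]


@njit(cache=True)
def _update_ligand_tips(center, quat, lig_dirs, tip_radius, lig_tip):
    w, x, y, z = quat[0], quat[1], quat[2], quat[3]
    r00 = 1 - 2 * (y * y + z * z)
    r01 = 2 * (x * y - w * z)
    r02 = 2 * (x * z + w * y)
    r10 = 2 * (x * y + w * z)
    r11 = 1 - 2 * (x * x + z * z)
    r12 = 2 * (y * z - w * x)
    r20 = 2 * (x * z - w * y)
    r21 = 2 * (y * z + w * x)
    r22 = 1 - 2 * (x * x + y * y)
    for j in range(lig_dirs.shape[0]):
        ux, uy, uz = lig_dirs[j, 0], lig_dirs[j, 1], lig_dirs[j, 2]
        lig_tip[j, 0] = center[0] + tip_radius * (r00 * ux + r01 * uy + r02 * uz)
        lig_tip[j, 1] = center[1] + tip_radius * (r10 * ux + r11 * uy + r12 * uz)
        lig_tip[j, 2] = center[2] + tip_radius * (r20 * ux + r21 * uy + r22 * uz)


@njit(cache=True)
def compute_delta_r(pos, center, box, r_capture):
    """|R_CM - R_NC| over membrane vertices within r_capture of the centre."""
    cx = 0.0
    cy = 0.0
    cz = 0.0
    cnt = 0
    r2 = r_capture * r_capture
    for v in range(pos.shape[0]):
        dx = _wrap(pos[v, 0] - center[0], box)
        dy = _wrap(pos[v, 1] - center[1], box)
        dz = pos[v, 2] - center[2]
        if dx * dx + dy * dy + dz * dz < r2:
            cx += dx
            cy += dy
            cz += dz
            cnt += 1
    if cnt == 0:
        # no vertices in range: use vertical distance to the reference frame
        return np.abs(center[2])
    cx /= cnt
    cy /= cnt
    cz /= cnt
    return np.sqrt(cx * cx + cy * cy + cz * cz)


@njit(cache=True)
def _bond_harmonic(d, H0, kb, dstar):
    return H0 + 0.5 * kb * (d - dstar) ** 2


@njit(cache=True)
def _dist3(ax, ay, az, bx, by, bz, box):
    dx = _wrap(ax - bx, box)
    dy = _wrap(ay - by, box)
    dz = az - bz
    return np.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True)
def _draw_flex_angle(kappa_f):
    """theta ~ sin(theta) exp(-kappa_f theta^2 / 2) on [0, pi/2]: rejection
    from the Rayleigh proposal theta exp(-kappa_f theta^2 / 2)."""
    tmax = np.pi / 2.0
    if kappa_f < 1e-9:
        return np.arccos(np.random.random())
    cap = 1.0 - np.exp(-0.5 * kappa_f * tmax * tmax)
    while True:
        u = np.random.random()
        th = np.sqrt(-2.0 * np.log(1.0 - u * cap) / kappa_f)
        if th < 1e-12:
            return th
        if np.random.random() < np.sin(th) / th:
            return th


@njit(cache=True)
def _has_directed_edge(tris, t, a, b):
    for k in range(3):
        if tris[t, k] == a and tris[t, (k + 1) % 3] == b:
            return True
    return False


@njit(cache=True)
def _fix_boundary_link(vx, vy, t_old1, t_old2, t_new, opp_new, nbr, nlink,
                       deg, link_tri, link_opp):
    """Point the (vx, vy) link's entry for triangle t_old1-or-2 at t_new."""
    for k in range(deg[vx]):
        if nbr[vx, k] == vy:
            lo = nlink[vx, k]
            for s in range(2):
                if link_tri[lo, s] == t_old1 or link_tri[lo, s] == t_old2:
                    link_tri[lo, s] = t_new
                    link_opp[lo, s] = opp_new
            return


@njit(cache=True)
def _do_flip(li, a, b, c, d2, t1, t2, links, link_opp, link_tri, tris, nbr,
             nlink, deg):
    """Flip link li = (a, b) -> (c, d2).

    Convention: t1 contains the directed edge a->b with opposite vertex c,
    t2 contains b->a with opposite d2.  New triangles: t1 = (a, d2, c),
    t2 = (d2, b, c); consistent orientation is preserved.
    """
    links[li, 0] = c
    links[li, 1] = d2
    link_opp[li, 0] = a
    link_opp[li, 1] = b
    link_tri[li, 0] = t1
    link_tri[li, 1] = t2
    tris[t1, 0] = a
    tris[t1, 1] = d2
    tris[t1, 2] = c
    tris[t2, 0] = d2
    tris[t2, 1] = b
    tris[t2, 2] = c
    # boundary links: (a,c) stays in t1 (opp d2); (b,c) -> t2 (opp d2);
    # (a,d2) -> t1 (opp c); (b,d2) stays in t2 (opp c)
    _fix_boundary_link(a, c, t1, t2, t1, d2, nbr, nlink, deg, link_tri, link_opp)
    _fix_boundary_link(b, c, t1, t2, t2, d2, nbr, nlink, deg, link_tri, link_opp)
    _fix_boundary_link(a, d2, t1, t2, t1, c, nbr, nlink, deg, link_tri, link_opp)
    _fix_boundary_link(b, d2, t1, t2, t2, c, nbr, nlink, deg, link_tri, link_opp)
    # adjacency: drop (a, b), add (c, d2)
    for k in range(deg[a]):
        if nbr[a, k] == b:
            nbr[a, k] = nbr[a, deg[a] - 1]
            nlink[a, k] = nlink[a, deg[a] - 1]
            nbr[a, deg[a] - 1] = -1
            nlink[a, deg[a] - 1] = -1
            deg[a] -= 1
            break
    for k in range(deg[b]):
        if nbr[b, k] == a:
            nbr[b, k] = nbr[b, deg[b] - 1]
            nlink[b, k] = nlink[b, deg[b] - 1]
            nbr[b, deg[b] - 1] = -1
            nlink[b, deg[b] - 1] = -1
            deg[b] -= 1
            break
    nbr[c, deg[c]] = d2
    nlink[c, deg[c]] = li
    deg[c] += 1
    nbr[d2, deg[d2]] = c
    nlink[d2, deg[d2]] = li
    deg[d2] += 1


@njit(cache=True)
def run_mc(
    # mesh state
    pos, nbr, nlink, deg, links, link_opp, link_tri, tris, pinned,
    # receptor state
    rec_vertex, rec_theta, rec_phi, rec_bond, occupied,
    # carrier state
    center, quat, lig_dirs, lig_tip, lig_bond,
    # parameters
    box, kappa, sigma, a0, lmax, rec_len, kappa_f, H0, kb, dstar,
    r_nc, lig_len, L_z, z_flex_norm,
    # umbrella bias; k_bias <= 0 disables
    k_bias, dr0,
    # move proposal
    cum_weights, step_v, step_t, step_r, k_trials,
    # schedule
    n_steps, seed,
    # recording
    cadence_fast, cadence_slow, rec_nb, rec_dr, rec_quat, rec_center,
    rec_energy,
    # accumulators
    move_stats, bound_mom, nc_mom,
):
    """Run n_steps attempted moves in place; returns (energy, delta_r).

    move_stats: (7, 2) attempts/accepts.  bound_mom and nc_mom are
    6-vectors [count, Sx, Sy, Sxx, Syy, Sxy] of streaming moments for
    bound-receptor tangent coordinates (relative to the NC axis) and the
    NC lateral position.
    """
    np.random.seed(seed)
    n_vert = pos.shape[0]
    n_rec = rec_vertex.shape[0]
    n_lig = lig_dirs.shape[0]
    has_nc = r_nc > 0.0
    tip_radius = r_nc + lig_len
    bias_on = k_bias > 0.0 and has_nc

    energy = total_membrane_energy(pos, nbr, nlink, deg, link_opp,
                                   link_tri, tris, box, kappa, sigma)
    tipbuf = np.empty(3)
    tipbuf2 = np.empty(3)
    qbuf = np.empty(4)
    qnew = np.empty(4)
    nvec = np.empty(3)
    fr1 = np.empty(3)
    fr2 = np.empty(3)
    affected = np.empty(64, dtype=np.int64)
    quad = np.empty(4, dtype=np.int64)
    feas = np.empty(512, dtype=np.int64)
    e_cand = np.empty(k_trials)
    th_cand = np.empty(k_trials)
    ph_cand = np.empty(k_trials)
    new_tip = np.empty((n_lig, 3))

    for r in range(n_rec):
        energy += 0.5 * kappa_f * rec_theta[r] * rec_theta[r]
        if rec_bond[r] >= 0:
            receptor_tip_kernel(rec_vertex[r], rec_theta[r], rec_phi[r],
                                rec_len, pos, nlink, deg, link_tri, tris, box,
                                tipbuf)
            j = rec_bond[r]
            d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                       lig_tip[j, 1], lig_tip[j, 2], box)
            energy += _bond_harmonic(d, H0, kb, dstar)

    dr_cur = 0.0
    if has_nc:
        dr_cur = compute_delta_r(pos, center, box, 2.0 * r_nc)
    if bias_on:
        energy += 0.5 * k_bias * (dr_cur - dr0) ** 2

    n_b = 0
    for r in range(n_rec):
        if rec_bond[r] >= 0:
            n_b += 1

    for step in range(n_steps):
        # -------------------------------------------------- recording
        if step % cadence_fast == 0:
            idx = step // cadence_fast
            if idx < rec_nb.shape[0]:
                rec_nb[idx] = n_b
        if step % cadence_slow == 0:
            idx = step // cadence_slow
            if idx < rec_energy.shape[0]:
                if has_nc:
                    dr_cur = compute_delta_r(pos, center, box, 2.0 * r_nc)
                    rec_dr[idx] = dr_cur
                for i in range(4):
                    rec_quat[idx, i] = quat[i]
                for i in range(3):
                    rec_center[idx, i] = center[i]
                rec_energy[idx] = energy
            if has_nc:
                nc_mom[0] += 1.0
                nc_mom[1] += center[0]
                nc_mom[2] += center[1]
                nc_mom[3] += center[0] * center[0]
                nc_mom[4] += center[1] * center[1]
                nc_mom[5] += center[0] * center[1]
                for r in range(n_rec):
                    if rec_bond[r] >= 0:
                        vb = rec_vertex[r]
                        tx = _wrap(pos[vb, 0] - center[0], box)
                        ty = _wrap(pos[vb, 1] - center[1], box)
                        bound_mom[0] += 1.0
                        bound_mom[1] += tx
                        bound_mom[2] += ty
                        bound_mom[3] += tx * tx
                        bound_mom[4] += ty * ty
                        bound_mom[5] += tx * ty

        u = np.random.random()
        kind = 6
        for m in range(7):
            if u < cum_weights[m]:
                kind = m
                break
        move_stats[kind, 0] += 1

        # ------------------------------------------------ vertex move
        if kind == 0:
            v = np.random.randint(0, n_vert)
            if pinned[v]:
                continue
            dxp = step_v * (np.random.random() - 0.5)
            dyp = step_v * (np.random.random() - 0.5)
            dzp = step_v * (np.random.random() - 0.5)
            nx = pos[v, 0] + dxp
            ny = pos[v, 1] + dyp
            nz = pos[v, 2] + dzp
            ok = True
            for k in range(deg[v]):
                j = nbr[v, k]
                d = _dist3(nx, ny, nz, pos[j, 0], pos[j, 1], pos[j, 2], box)
                if d < a0 or d > lmax:
                    ok = False
                    break
            if ok and has_nc:
                d = _dist3(nx, ny, nz, center[0], center[1], center[2], box)
                if d < r_nc:
                    ok = False
            if not ok:
                continue
            na = 0
            affected[na] = v
            na += 1
            for k in range(deg[v]):
                affected[na] = nbr[v, k]
                na += 1
            e_old = patch_energy(affected, na, pos, nbr, nlink, deg,
                                 link_opp, link_tri, tris, box, kappa, sigma)
            eb_old = 0.0
            for i in range(na):
                rr = occupied[affected[i]]
                if rr >= 0 and rec_bond[rr] >= 0:
                    receptor_tip_kernel(rec_vertex[rr], rec_theta[rr],
                                        rec_phi[rr], rec_len, pos, nlink, deg,
                                        link_tri, tris, box, tipbuf)
                    j = rec_bond[rr]
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                               lig_tip[j, 1], lig_tip[j, 2], box)
                    eb_old += _bond_harmonic(d, H0, kb, dstar)
            ox, oy, oz = pos[v, 0], pos[v, 1], pos[v, 2]
            pos[v, 0] = nx
            pos[v, 1] = ny
            pos[v, 2] = nz
            e_new = patch_energy(affected, na, pos, nbr, nlink, deg,
                                 link_opp, link_tri, tris, box, kappa, sigma)
            eb_new = 0.0
            for i in range(na):
                rr = occupied[affected[i]]
                if rr >= 0 and rec_bond[rr] >= 0:
                    receptor_tip_kernel(rec_vertex[rr], rec_theta[rr],
                                        rec_phi[rr], rec_len, pos, nlink, deg,
                                        link_tri, tris, box, tipbuf)
                    j = rec_bond[rr]
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                               lig_tip[j, 1], lig_tip[j, 2], box)
                    eb_new += _bond_harmonic(d, H0, kb, dstar)
            d_e = (e_new - e_old) + (eb_new - eb_old)
            dr_new = dr_cur
            if bias_on:
                dr_new = compute_delta_r(pos, center, box, 2.0 * r_nc)
                d_e += 0.5 * k_bias * ((dr_new - dr0) ** 2
                                       - (dr_cur - dr0) ** 2)
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e):
                energy += d_e
                dr_cur = dr_new
                move_stats[kind, 1] += 1
            else:
                pos[v, 0] = ox
                pos[v, 1] = oy
                pos[v, 2] = oz

        # ------------------------------------------------ link flip
        elif kind == 1:
            li = np.random.randint(0, links.shape[0])
            a, b = links[li, 0], links[li, 1]
            t1, t2 = link_tri[li, 0], link_tri[li, 1]
            c, d2 = link_opp[li, 0], link_opp[li, 1]
            # orient so t1 holds the directed edge a->b (opp c)
            if not _has_directed_edge(tris, t1, a, b):
                t1, t2 = t2, t1
                c, d2 = d2, c
            if c == d2:
                continue
            if deg[a] <= 3 or deg[b] <= 3:
                continue
            if deg[c] >= nbr.shape[1] - 1 or deg[d2] >= nbr.shape[1] - 1:
                continue
            exists = False
            for k in range(deg[c]):
                if nbr[c, k] == d2:
                    exists = True
                    break
            if exists:
                continue
            dl = _dist3(pos[c, 0], pos[c, 1], pos[c, 2], pos[d2, 0],
                        pos[d2, 1], pos[d2, 2], box)
            if dl < a0 or dl > lmax:
                continue
            quad[0] = a
            quad[1] = b
            quad[2] = c
            quad[3] = d2
            e_old = patch_energy(quad, 4, pos, nbr, nlink, deg, link_opp,
                                 link_tri, tris, box, kappa, sigma)
            # bonds of receptors on the quad: tips ride the vertex normals
            for i in range(4):
                rr = occupied[quad[i]]
                if rr >= 0 and rec_bond[rr] >= 0:
                    receptor_tip_kernel(quad[i], rec_theta[rr], rec_phi[rr],
                                        rec_len, pos, nlink, deg, link_tri,
                                        tris, box, tipbuf)
                    j = rec_bond[rr]
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                               lig_tip[j, 1], lig_tip[j, 2], box)
                    e_old += _bond_harmonic(d, H0, kb, dstar)
            _do_flip(li, a, b, c, d2, t1, t2, links, link_opp, link_tri,
                     tris, nbr, nlink, deg)
            e_new = patch_energy(quad, 4, pos, nbr, nlink, deg, link_opp,
                                 link_tri, tris, box, kappa, sigma)
            for i in range(4):
                rr = occupied[quad[i]]
                if rr >= 0 and rec_bond[rr] >= 0:
                    receptor_tip_kernel(quad[i], rec_theta[rr], rec_phi[rr],
                                        rec_len, pos, nlink, deg, link_tri,
                                        tris, box, tipbuf)
                    j = rec_bond[rr]
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                               lig_tip[j, 1], lig_tip[j, 2], box)
                    e_new += _bond_harmonic(d, H0, kb, dstar)
            d_e = e_new - e_old
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e):
                energy += d_e
                move_stats[kind, 1] += 1
            else:
                # reverse flip: edge (c, d2); t2 now holds c->d2 (opp b)
                _do_flip(li, c, d2, b, a, t2, t1, links, link_opp, link_tri,
                         tris, nbr, nlink, deg)

        # ------------------------------------------------ NC translation
        elif kind == 2:
            if not has_nc:
                continue
            dxp = step_t * (np.random.random() - 0.5)
            dyp = step_t * (np.random.random() - 0.5)
            dzp = step_t * (np.random.random() - 0.5)
            nx = center[0] + dxp
            ny = center[1] + dyp
            nz = center[2] + dzp
            if nz < r_nc or nz > L_z - r_nc:
                continue
            ok = True
            for v in range(n_vert):
                d = _dist3(pos[v, 0], pos[v, 1], pos[v, 2], nx, ny, nz, box)
                if d < r_nc:
                    ok = False
                    break
            if not ok:
                continue
            eb_old = 0.0
            eb_new = 0.0
            for r in range(n_rec):
                j = rec_bond[r]
                if j >= 0:
                    receptor_tip_kernel(rec_vertex[r], rec_theta[r],
                                        rec_phi[r], rec_len, pos, nlink, deg,
                                        link_tri, tris, box, tipbuf)
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                               lig_tip[j, 1], lig_tip[j, 2], box)
                    eb_old += _bond_harmonic(d, H0, kb, dstar)
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2],
                               lig_tip[j, 0] + dxp, lig_tip[j, 1] + dyp,
                               lig_tip[j, 2] + dzp, box)
                    eb_new += _bond_harmonic(d, H0, kb, dstar)
            d_e = eb_new - eb_old
            dr_new = dr_cur
            if bias_on:
                ocx, ocy, ocz = center[0], center[1], center[2]
                center[0] = nx
                center[1] = ny
                center[2] = nz
                dr_new = compute_delta_r(pos, center, box, 2.0 * r_nc)
                center[0] = ocx
                center[1] = ocy
                center[2] = ocz
                d_e += 0.5 * k_bias * ((dr_new - dr0) ** 2
                                       - (dr_cur - dr0) ** 2)
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e):
                center[0] = nx
                center[1] = ny
                center[2] = nz
                for j in range(n_lig):
                    lig_tip[j, 0] += dxp
                    lig_tip[j, 1] += dyp
                    lig_tip[j, 2] += dzp
                energy += d_e
                dr_cur = dr_new
                move_stats[kind, 1] += 1

        # ------------------------------------------------ NC rotation
        elif kind == 3:
            if not has_nc:
                continue
            ax = np.random.standard_normal()
            ay = np.random.standard_normal()
            az = np.random.standard_normal()
            an = np.sqrt(ax * ax + ay * ay + az * az)
            if an < 1e-12:
                continue
            ang = step_r * (np.random.random() - 0.5)
            h = 0.5 * ang
            sh = np.sin(h) / an
            qbuf[0] = np.cos(h)
            qbuf[1] = sh * ax
            qbuf[2] = sh * ay
            qbuf[3] = sh * az
            _quat_mul(qbuf, quat, qnew)
            qn = np.sqrt(qnew[0] ** 2 + qnew[1] ** 2 + qnew[2] ** 2
                         + qnew[3] ** 2)
            for i in range(4):
                qnew[i] /= qn
            _update_ligand_tips(center, qnew, lig_dirs, tip_radius, new_tip)
            eb_old = 0.0
            eb_new = 0.0
            for r in range(n_rec):
                j = rec_bond[r]
                if j >= 0:
                    receptor_tip_kernel(rec_vertex[r], rec_theta[r],
                                        rec_phi[r], rec_len, pos, nlink, deg,
                                        link_tri, tris, box, tipbuf)
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                               lig_tip[j, 1], lig_tip[j, 2], box)
                    eb_old += _bond_harmonic(d, H0, kb, dstar)
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2],
                               new_tip[j, 0], new_tip[j, 1], new_tip[j, 2],
                               box)
                    eb_new += _bond_harmonic(d, H0, kb, dstar)
            d_e = eb_new - eb_old
            if d_e <= 0.0 or np.random.random() < np.exp(-d_e):
                for i in range(4):
                    quat[i] = qnew[i]
                for j in range(n_lig):
                    for i in range(3):
                        lig_tip[j, i] = new_tip[j, i]
                energy += d_e
                move_stats[kind, 1] += 1

        # ------------------------------------------------ receptor diffusion
        elif kind == 4:
            if n_rec == 0:
                continue
            r = np.random.randint(0, n_rec)
            v = rec_vertex[r]
            k = np.random.randint(0, deg[v])
            vnew = nbr[v, k]
            if occupied[vnew] >= 0:
                continue
            j = rec_bond[r]
            d_e = 0.0
            if j >= 0:
                receptor_tip_kernel(v, rec_theta[r], rec_phi[r], rec_len, pos,
                                    nlink, deg, link_tri, tris, box, tipbuf)
                d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                           lig_tip[j, 1], lig_tip[j, 2], box)
                e_o = _bond_harmonic(d, H0, kb, dstar)
                receptor_tip_kernel(vnew, rec_theta[r], rec_phi[r], rec_len,
                                    pos, nlink, deg, link_tri, tris, box,
                                    tipbuf2)
                d = _dist3(tipbuf2[0], tipbuf2[1], tipbuf2[2], lig_tip[j, 0],
                           lig_tip[j, 1], lig_tip[j, 2], box)
                e_n = _bond_harmonic(d, H0, kb, dstar)
                d_e = e_n - e_o
            ratio = deg[v] / deg[vnew]  # proposal asymmetry of the hop
            if np.random.random() < min(1.0, ratio * np.exp(-d_e)):
                occupied[v] = -1
                occupied[vnew] = r
                rec_vertex[r] = vnew
                energy += d_e
                move_stats[kind, 1] += 1

        # ------------------------------------------------ receptor flexure
        elif kind == 5:
            if n_rec == 0:
                continue
            r = np.random.randint(0, n_rec)
            v = rec_vertex[r]
            j = rec_bond[r]
            w_new = 0.0
            for t in range(k_trials):
                cth = np.random.random()
                th = np.arccos(cth)
                ph = 2.0 * np.pi * np.random.random()
                e = 0.5 * kappa_f * th * th
                if j >= 0:
                    receptor_tip_kernel(v, th, ph, rec_len, pos, nlink, deg,
                                        link_tri, tris, box, tipbuf)
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                               lig_tip[j, 1], lig_tip[j, 2], box)
                    e += _bond_harmonic(d, H0, kb, dstar)
                th_cand[t] = th
                ph_cand[t] = ph
                e_cand[t] = e
                w_new += np.exp(-e)
            if w_new <= 0.0:
                continue
            usel = np.random.random() * w_new
            acc = 0.0
            sel = 0
            for t in range(k_trials):
                acc += np.exp(-e_cand[t])
                if usel <= acc:
                    sel = t
                    break
            e_old_o = 0.5 * kappa_f * rec_theta[r] * rec_theta[r]
            if j >= 0:
                receptor_tip_kernel(v, rec_theta[r], rec_phi[r], rec_len, pos,
                                    nlink, deg, link_tri, tris, box, tipbuf)
                d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                           lig_tip[j, 1], lig_tip[j, 2], box)
                e_old_o += _bond_harmonic(d, H0, kb, dstar)
            w_old = np.exp(-e_old_o)
            for t in range(k_trials - 1):
                cth = np.random.random()
                th = np.arccos(cth)
                ph = 2.0 * np.pi * np.random.random()
                e = 0.5 * kappa_f * th * th
                if j >= 0:
                    receptor_tip_kernel(v, th, ph, rec_len, pos, nlink, deg,
                                        link_tri, tris, box, tipbuf)
                    d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j, 0],
                               lig_tip[j, 1], lig_tip[j, 2], box)
                    e += _bond_harmonic(d, H0, kb, dstar)
                w_old += np.exp(-e)
            if np.random.random() < w_new / w_old:
                energy += e_cand[sel] - e_old_o
                rec_theta[r] = th_cand[sel]
                rec_phi[r] = ph_cand[sel]
                move_stats[kind, 1] += 1

        # ------------------------------------------------ bond make/break
        elif kind == 6:
            if n_rec == 0 or not has_nc:
                continue
            r = np.random.randint(0, n_rec)
            v = rec_vertex[r]
            j0 = rec_bond[r]
            nf = 0
            j0_feasible = False
            for j in range(n_lig):
                if lig_bond[j] >= 0 and lig_bond[j] != r:
                    continue
                D = _dist3(pos[v, 0], pos[v, 1], pos[v, 2], lig_tip[j, 0],
                           lig_tip[j, 1], lig_tip[j, 2], box)
                if np.abs(D - rec_len) <= dstar and nf < feas.shape[0]:
                    feas[nf] = j
                    nf += 1
                    if j == j0:
                        j0_feasible = True
            strained = 1 if (j0 >= 0 and not j0_feasible) else 0
            n_opt_old = 1 + nf + strained
            pick = np.random.randint(0, n_opt_old)
            if pick == 0:
                jnew = -1
            elif pick <= nf:
                jnew = feas[pick - 1]
            else:
                # strained current bond selected as target: its cap is
                # empty, the proposal cannot generate it -> null move
                continue
            # old configuration energy (flexure + possibly bond)
            receptor_tip_kernel(v, rec_theta[r], rec_phi[r], rec_len, pos,
                                nlink, deg, link_tri, tris, box, tipbuf)
            e_old_o = 0.5 * kappa_f * rec_theta[r] * rec_theta[r]
            if j0 >= 0:
                d = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j0, 0],
                           lig_tip[j0, 1], lig_tip[j0, 2], box)
                e_old_o += _bond_harmonic(d, H0, kb, dstar)
            # forward draw
            if jnew < 0:
                th = _draw_flex_angle(kappa_f)
                ph = 2.0 * np.pi * np.random.random()
                g_fwd = np.exp(-0.5 * kappa_f * th * th) / z_flex_norm
                e_new_o = 0.5 * kappa_f * th * th
            else:
                D = _dist3(pos[v, 0], pos[v, 1], pos[v, 2], lig_tip[jnew, 0],
                           lig_tip[jnew, 1], lig_tip[jnew, 2], box)
                carg = (rec_len * rec_len + D * D - dstar * dstar) / \
                       (2.0 * rec_len * D)
                if carg > 1.0:
                    carg = 1.0
                if carg < -1.0:
                    carg = -1.0
                omega = 2.0 * np.pi * (1.0 - carg)
                if omega < 1e-14:
                    continue
                cg = carg + np.random.random() * (1.0 - carg)
                sg = np.sqrt(max(0.0, 1.0 - cg * cg))
                alpha = 2.0 * np.pi * np.random.random()
                uxx = _wrap(lig_tip[jnew, 0] - pos[v, 0], box) / D
                uyy = _wrap(lig_tip[jnew, 1] - pos[v, 1], box) / D
                uzz = (lig_tip[jnew, 2] - pos[v, 2]) / D
                if np.abs(uxx) < 0.9:
                    px, py, pz = 1.0, 0.0, 0.0
                else:
                    px, py, pz = 0.0, 1.0, 0.0
                e1x = py * uzz - pz * uyy
                e1y = pz * uxx - px * uzz
                e1z = px * uyy - py * uxx
                en = np.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
                e1x /= en
                e1y /= en
                e1z /= en
                e2x = uyy * e1z - uzz * e1y
                e2y = uzz * e1x - uxx * e1z
                e2z = uxx * e1y - uyy * e1x
                ca = np.cos(alpha)
                sa = np.sin(alpha)
                dirx = cg * uxx + sg * (ca * e1x + sa * e2x)
                diry = cg * uyy + sg * (ca * e1y + sa * e2y)
                dirz = cg * uzz + sg * (ca * e1z + sa * e2z)
                vertex_normal(v, pos, nlink, deg, link_tri, tris, box, nvec)
                cth = dirx * nvec[0] + diry * nvec[1] + dirz * nvec[2]
                if cth < 0.0:
                    continue  # rod below the membrane surface: forbidden
                if cth > 1.0:
                    cth = 1.0
                th = np.arccos(cth)
                _tangent_frame(nvec, fr1, fr2)
                ph = np.arctan2(
                    dirx * fr2[0] + diry * fr2[1] + dirz * fr2[2],
                    dirx * fr1[0] + diry * fr1[1] + dirz * fr1[2])
                g_fwd = 1.0 / omega
                tx = pos[v, 0] + rec_len * dirx
                ty = pos[v, 1] + rec_len * diry
                tz = pos[v, 2] + rec_len * dirz
                d_new = _dist3(tx, ty, tz, lig_tip[jnew, 0], lig_tip[jnew, 1],
                               lig_tip[jnew, 2], box)
                e_new_o = 0.5 * kappa_f * th * th + \
                    _bond_harmonic(d_new, H0, kb, dstar)
            # reverse density for regenerating the old configuration
            if j0 < 0:
                g_rev = np.exp(-0.5 * kappa_f * rec_theta[r] ** 2) \
                    / z_flex_norm
            else:
                D0 = _dist3(pos[v, 0], pos[v, 1], pos[v, 2], lig_tip[j0, 0],
                            lig_tip[j0, 1], lig_tip[j0, 2], box)
                d0 = _dist3(tipbuf[0], tipbuf[1], tipbuf[2], lig_tip[j0, 0],
                            lig_tip[j0, 1], lig_tip[j0, 2], box)
                if d0 > dstar or np.abs(D0 - rec_len) > dstar:
                    g_rev = 0.0
                else:
                    carg0 = (rec_len * rec_len + D0 * D0 - dstar * dstar) / \
                            (2.0 * rec_len * D0)
                    if carg0 > 1.0:
                        carg0 = 1.0
                    if carg0 < -1.0:
                        carg0 = -1.0
                    om0 = 2.0 * np.pi * (1.0 - carg0)
                    g_rev = 1.0 / om0 if om0 > 1e-14 else 0.0
            if g_rev <= 0.0:
                continue  # old state unreachable in reverse: reject
            # option count is state-independent for this receptor except for
            # the strained-bond slot, which exists only in the old state
            n_opt_new = 1 + nf
            ratio = np.exp(-(e_new_o - e_old_o)) * (g_rev / g_fwd) \
                * (n_opt_old / n_opt_new)
            if np.random.random() < min(1.0, ratio):
                if j0 >= 0:
                    lig_bond[j0] = -1
                    n_b -= 1
                if jnew >= 0:
                    lig_bond[jnew] = r
                    n_b += 1
                rec_bond[r] = jnew
                rec_theta[r] = th
                rec_phi[r] = ph
                energy += e_new_o - e_old_o
                move_stats[kind, 1] += 1

    if has_nc:
        dr_cur = compute_delta_r(pos, center, box, 2.0 * r_nc)
    return energy, dr_cur
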