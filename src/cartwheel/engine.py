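"""Numba-accelerated Brownian-dynamics engine.

Because every oligomer snaps to the exact arc geometry, the simulation
state is just, per cluster, a species index (chain size 1–9 or ring), a
position and an orientation quaternion; all per-species geometry and the
rigid-body diffusion tensors come from :mod:`cartwheel.species` packed into
flat arrays.  One time step comprises

1. anisotropic Brownian propagation of every cluster (body-frame mobility at
   the center of diffusion, drift from scaffold/wall forces, Gaussian
   displacements with covariance 2 D Δt),
2. per-bond dissociation trials with window re-placement (detailed balance),
3. encounter detection between free donor/acceptor ends and stochastic
   association with snapping, the rigid 9-chain closing into the ring at
   the enhanced last-bond rate,
4. optional grand-canonical monomer exchange in the reservoir region.

Clusters are ideal between reactions (no mutual excluded volume); a bond
that would place the merged cluster inside the scaffold core or the wall is
rejected, and merges beyond nine members are geometrically self-overlapping
and never occur.  Randomness is numba's global NumPy RNG, seeded once per
run, so trajectories are reproducible given (config, seed).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# scaffold type codes
SCAFFOLD_NONE = 0
SCAFFOLD_CYLINDER = 1
SCAFFOLD_SPHERE = 2
SCAFFOLD_SEMISPHERE = 3

RING = 9  # species index of the closed ring


# ---------------------------------------------------------------------------
# quaternion helpers (scalar-first)


@njit(cache=True, inline="always")
def _qmul(a, b):
    return np.array(
        [
            a[0] * b[0] - a[1] * b[1] - a[2] * b[2] - a[3] * b[3],
            a[0] * b[1] + a[1] * b[0] + a[2] * b[3] - a[3] * b[2],
            a[0] * b[2] - a[1] * b[3] + a[2] * b[0] + a[3] * b[1],
            a[0] * b[3] + a[1] * b[2] - a[2] * b[1] + a[3] * b[0],
        ]
    )


@njit(cache=True, inline="always")
def _qconj(q):
    return np.array([q[0], -q[1], -q[2], -q[3]])


@njit(cache=True, inline="always")
def _qrot(q, v):
    # rotate v by quaternion q
    t0 = q[2] * v[2] - q[3] * v[1]
    t1 = q[3] * v[0] - q[1] * v[2]
    t2 = q[1] * v[1] - q[2] * v[0]
    t0 += t0
    t1 += t1
    t2 += t2
    return np.array(
        [
            v[0] + q[0] * t0 + q[2] * t2 - q[3] * t1,
            v[1] + q[0] * t1 + q[3] * t0 - q[1] * t2,
            v[2] + q[0] * t2 + q[1] * t1 - q[2] * t0,
        ]
    )


@njit(cache=True, inline="always")
def _qnormalize(q):
    n = np.sqrt(q[0] * q[0] + q[1] * q[1] + q[2] * q[2] + q[3] * q[3])
    return q / n


@njit(cache=True, inline="always")
def _q_from_rotvec(w):
    angle = np.sqrt(w[0] * w[0] + w[1] * w[1] + w[2] * w[2])
    q = np.empty(4)
    if angle < 1e-12:
        q[0] = 1.0
        q[1] = 0.5 * w[0]
        q[2] = 0.5 * w[1]
        q[3] = 0.5 * w[2]
        return _qnormalize(q)
    half = 0.5 * angle
    s = np.sin(half) / angle
    q[0] = np.cos(half)
    q[1] = s * w[0]
    q[2] = s * w[1]
    q[3] = s * w[2]
    return q


@njit(cache=True)
def _rand_quat():
    # uniform orientation via normalized 4-Gaussian
    q = np.empty(4)
    for k in range(4):
        q[k] = np.random.normal()
    return _qnormalize(q)


@njit(cache=True)
def _sample_window_quat(cos_align, cos_tors):
    """Uniform SO(3) rotation restricted to the angular window (rejection).

    Canonical axes: e_x is the center-to-center direction, e_z the torsion
    direction; callers conjugate into the actual patch frame.
    """
    while True:
        q = _rand_quat()
        rxx = 1.0 - 2.0 * (q[2] * q[2] + q[3] * q[3])
        if rxx < cos_align:
            continue
        rzz = 1.0 - 2.0 * (q[1] * q[1] + q[2] * q[2])
        if rzz < cos_tors:
            continue
        return q


@njit(cache=True)
def _q_from_axes(c, t):
    """Quaternion mapping e_x -> c and e_z -> t (c, t orthonormal)."""
    m00, m01, m02 = c[0], t[1] * c[2] - t[2] * c[1], t[0]
    m10, m11, m12 = c[1], t[2] * c[0] - t[0] * c[2], t[1]
    m20, m21, m22 = c[2], t[0] * c[1] - t[1] * c[0], t[2]
    tr = m00 + m11 + m22
    q = np.empty(4)
    if tr > 0.0:
        s = np.sqrt(tr + 1.0) * 2.0
        q[0] = 0.25 * s
        q[1] = (m21 - m12) / s
        q[2] = (m02 - m20) / s
        q[3] = (m10 - m01) / s
    elif m00 >= m11 and m00 >= m22:
        s = np.sqrt(1.0 + m00 - m11 - m22) * 2.0
        q[0] = (m21 - m12) / s
        q[1] = 0.25 * s
        q[2] = (m01 + m10) / s
        q[3] = (m02 + m20) / s
    elif m11 >= m22:
        s = np.sqrt(1.0 + m11 - m00 - m22) * 2.0
        q[0] = (m02 - m20) / s
        q[1] = (m01 + m10) / s
        q[2] = 0.25 * s
        q[3] = (m12 + m21) / s
    else:
        s = np.sqrt(1.0 + m22 - m00 - m11) * 2.0
        q[0] = (m10 - m01) / s
        q[1] = (m02 + m20) / s
        q[2] = (m12 + m21) / s
        q[3] = 0.25 * s
    return _qnormalize(q)


@njit(cache=True)
def _sample_ball(radius):
    while True:
        v = np.empty(3)
        for k in range(3):
            v[k] = (2.0 * np.random.random() - 1.0) * radius
        if v[0] * v[0] + v[1] * v[1] + v[2] * v[2] <= radius * radius:
            return v


@njit(cache=True, inline="always")
def _min_image(d, box, periodic):
    for ax in range(3):
        if periodic[ax]:
            d[ax] -= box[ax] * np.round(d[ax] / box[ax])
    return d


# ---------------------------------------------------------------------------
# scaffold forces


@njit(cache=True)
def _scaffold_site_force(p, stype, center, r_s, dr_s, strength, k_rep, attract):
    """Force on one site; ``attract`` switches the layer attraction on
    (charge sites) or off (plain beads, which only feel the soft core)."""
    f = np.zeros(3)
    if stype == SCAFFOLD_NONE:
        return f
    if stype == SCAFFOLD_CYLINDER:
        dx = p[0] - center[0]
        dy = p[1] - center[1]
        r = np.sqrt(dx * dx + dy * dy)
        if r < 1e-12:
            return f
        ux, uy, uz = dx / r, dy / r, 0.0
    else:
        dx = p[0] - center[0]
        dy = p[1] - center[1]
        dz = p[2] - center[2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r < 1e-12:
            return f
        ux, uy, uz = dx / r, dy / r, dz / r
    if r < r_s:
        mag = k_rep * (r_s - r)  # steep soft core, outward
        f[0] = mag * ux
        f[1] = mag * uy
        f[2] = mag * uz
        return f
    if attract and r < r_s + dr_s:
        if stype == SCAFFOLD_SEMISPHERE and p[2] <= 0.0:
            return f
        mag = -strength / dr_s  # constant inward force, total depth l·kT
        f[0] = mag * ux
        f[1] = mag * uy
        f[2] = mag * uz
    return f


@njit(cache=True)
def _cluster_force_torque(
    sp, pos, quat, beads, nbead, brad, chg, nchg,
    stype, center, r_s, dr_s, strength, k_rep,
    wall, k_wall, box,
):
    """Net world-frame force and torque (about the cluster origin = center of
    diffusion) from scaffold core, attractive layer and planar walls."""
    f = np.zeros(3)
    tau = np.zeros(3)
    if stype != SCAFFOLD_NONE or wall:
        for b in range(nbead[sp]):
            rb = _qrot(quat, beads[sp, b])
            pw = pos + rb
            fb = _scaffold_site_force(pw, stype, center, r_s, dr_s, strength, k_rep, False)
            if wall:
                pen = brad[sp, b] - pw[2]
                if pen > 0.0:
                    fb[2] += k_wall * pen
                pen2 = pw[2] - (box[2] - brad[sp, b])
                if pen2 > 0.0:
                    fb[2] -= k_wall * pen2
            f += fb
            tau[0] += rb[1] * fb[2] - rb[2] * fb[1]
            tau[1] += rb[2] * fb[0] - rb[0] * fb[2]
            tau[2] += rb[0] * fb[1] - rb[1] * fb[0]
    if stype != SCAFFOLD_NONE:
        for c in range(nchg[sp]):
            rc = _qrot(quat, chg[sp, c])
            pw = pos + rc
            fc = _scaffold_site_force(pw, stype, center, r_s, dr_s, strength, k_rep, True)
            f += fc
            tau[0] += rc[1] * fc[2] - rc[2] * fc[1]
            tau[1] += rc[2] * fc[0] - rc[0] * fc[2]
            tau[2] += rc[0] * fc[1] - rc[1] * fc[0]
    return f, tau


@njit(cache=True)
def _count_bound(species, pos, quat, nclus, chg, nchg, stype, center, r_s, dr_s, nmem):
    """Homodimers with at least one charge site inside the attractive layer."""
    total = 0
    outer = r_s + dr_s
    for i in range(nclus):
        sp = species[i]
        if sp < 0:
            continue
        per_mem = 2
        n = nmem[sp]
        for m in range(n):
            hit = False
            for c in range(per_mem):
                p = pos[i] + _qrot(quat[i], chg[sp, m * per_mem + c])
                if stype == SCAFFOLD_CYLINDER:
                    dx = p[0] - center[0]
                    dy = p[1] - center[1]
                    r = np.sqrt(dx * dx + dy * dy)
                else:
                    dx = p[0] - center[0]
                    dy = p[1] - center[1]
                    dz = p[2] - center[2]
                    r = np.sqrt(dx * dx + dy * dy + dz * dz)
                if r < outer:
                    if stype == SCAFFOLD_SEMISPHERE and p[2] <= 0.0:
                        continue
                    hit = True
                    break
            if hit:
                total += 1
    return total


# ---------------------------------------------------------------------------
# scaffold / wall admissibility of a pose (used to veto snapped bonds)


@njit(cache=True)
def _pose_blocked(sp, p, q, beads, nbead, brad, stype, center, r_s, wall, box, tol):
    if stype == SCAFFOLD_NONE and not wall:
        return False
    for b in range(nbead[sp]):
        pw = p + _qrot(q, beads[sp, b])
        if stype == SCAFFOLD_CYLINDER:
            dx = pw[0] - center[0]
            dy = pw[1] - center[1]
            r = np.sqrt(dx * dx + dy * dy)
            if r < r_s - tol:
                return True
        elif stype != SCAFFOLD_NONE:
            dx = pw[0] - center[0]
            dy = pw[1] - center[1]
            dz = pw[2] - center[2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r < r_s - tol:
                return True
        if wall and pw[2] < brad[sp, b] - tol:
            return True
        if wall and pw[2] > box[2] - brad[sp, b] + tol:
            return True
    return False


# ---------------------------------------------------------------------------
# the time step


@njit(cache=True)
def run_chunk(
    # state
    species, pos, quat,
    # species tables
    nmem, nbead, beads, brad, nchg, chg,
    ends,  # (10, 2, 3, 3): [sp][donor=0/acc=1][anchor,c2c,tors]
    gq, gp,  # member poses in species frame (10, 9, 4)/(10, 9, 3)
    pd_anchor,  # donor patch anchor in the homodimer frame (3,)
    reach,  # (10,) max anchor distance from the cluster origin per species
    mob, sqrt2d,  # (10,6,6) mobility and chol(2D)
    # box
    box, periodic, wall, k_wall,
    # scaffold
    stype, center, r_s, dr_s, strength, k_rep,
    # reactions
    p_assoc, p_dissoc, p_ring, w_dist, cos_align, cos_tors, reactions_on,
    # gcmc
    gcmc_on, gcmc_every, gcmc_width, gcmc_nbar,
    # run control
    n_steps, dt, record_every,
    rec_counts, rec_occupancy, rec_offset,
):
    sqdt = np.sqrt(dt)
    ncap = species.shape[0]
    cand_a = np.empty(ncap * 4, dtype=np.int64)
    cand_b = np.empty(ncap * 4, dtype=np.int64)
    active = np.empty(ncap, dtype=np.int64)
    gen = np.empty(6)
    move = np.empty(6)
    noise = np.empty(6)
    dx = np.empty(3)
    dw = np.empty(3)
    born = np.zeros(ncap, dtype=np.uint8)
    forces_on = (stype != SCAFFOLD_NONE) or wall
    n_rec = rec_offset

    for step in range(n_steps):
        # --- 1. propagation -------------------------------------------------
        for i in range(ncap):
            sp = species[i]
            if sp < 0:
                continue
            qi = quat[i]
            if forces_on:
                f, tau = _cluster_force_torque(
                    sp, pos[i], qi, beads, nbead, brad, chg, nchg,
                    stype, center, r_s, dr_s, strength, k_rep, wall, k_wall, box,
                )
                fb = _qrot(_qconj(qi), f)
                tb = _qrot(_qconj(qi), tau)
                for k in range(3):
                    gen[k] = fb[k]
                    gen[3 + k] = tb[k]
            else:
                for k in range(6):
                    gen[k] = 0.0
            for k in range(6):
                noise[k] = np.random.normal()
            for r in range(6):
                acc = 0.0
                if forces_on:
                    for c in range(6):
                        acc += mob[sp, r, c] * gen[c]
                acc *= dt
                acc2 = 0.0
                for c in range(r + 1):
                    acc2 += sqrt2d[sp, r, c] * noise[c]
                move[r] = acc + acc2 * sqdt
            for k in range(3):
                dx[k] = move[k]
                dw[k] = move[3 + k]
            pos[i] += _qrot(qi, dx)
            quat[i] = _qnormalize(_qmul(qi, _q_from_rotvec(dw)))
            for ax in range(3):
                if periodic[ax]:
                    pos[i, ax] -= box[ax] * np.floor(pos[i, ax] / box[ax])

        if reactions_on:
            # fragments created by dissociation this step must not react
            # before the next propagation (exact per-step detailed balance)
            for i in range(ncap):
                born[i] = 0
            # --- 2. dissociation --------------------------------------------
            for i in range(ncap):
                sp = species[i]
                if sp < 1 or p_dissoc <= 0.0:
                    continue
                if sp == RING:
                    nbonds = 9
                elif sp >= 1:
                    nbonds = sp  # chain size sp+1 has sp bonds
                else:
                    continue
                fired = -1
                for b in range(nbonds):
                    if np.random.random() < p_dissoc:
                        fired = b
                        break
                if fired < 0:
                    continue
                if sp == RING:
                    # bond k joins member k (donor) to member (k+1)%9: the
                    # ring opens into the 9-chain starting at member k+1
                    k0 = (fired + 1) % 9
                    qh = _qmul(quat[i], gq[RING, k0])
                    ph = pos[i] + _qrot(quat[i], gp[RING, k0])
                    # chain-9 frame: member 0 pose gq[8,0], gp[8,0]
                    qn = _qmul(qh, _qconj(gq[8, 0]))
                    species[i] = 8
                    quat[i] = _qnormalize(qn)
                    pos[i] = ph - _qrot(qn, gp[8, 0])
                    born[i] = 1
                else:
                    n = sp + 1
                    b = fired + 1  # split members [0..b-1] | [b..n-1]
                    spx = b - 1
                    spy = n - b - 1
                    qo = quat[i]
                    po = pos[i]
                    # fragment X holds members 0..b-1 (carries the donor of
                    # the broken bond at member b-1)
                    qxh = _qmul(qo, gq[sp, 0])
                    pxh = po + _qrot(qo, gp[sp, 0])
                    qx = _qnormalize(_qmul(qxh, _qconj(gq[spx, 0])))
                    px = pxh - _qrot(qx, gp[spx, 0])
                    # fragment Y holds members b..n-1
                    qyh = _qmul(qo, gq[sp, b])
                    pyh = po + _qrot(qo, gp[sp, b])
                    qy = _qnormalize(_qmul(qyh, _qconj(gq[spy, 0])))
                    py = pyh - _qrot(qy, gp[spy, 0])
                    # re-place fragment X by a uniform window draw about the
                    # donor anchor (detailed balance): the canonical window
                    # rotation is conjugated into the patch frame spanned by
                    # the world center-to-center and torsion vectors
                    qmem = _qmul(qo, gq[sp, b - 1])
                    anchor = po + _qrot(qo, gp[sp, b - 1]) + _qrot(qmem, pd_anchor)
                    c_w = _qrot(qx, ends[spx, 0, 1])
                    t_w = _qrot(qx, ends[spx, 0, 2])
                    qa = _q_from_axes(c_w, t_w)
                    dq = _sample_window_quat(cos_align, cos_tors)
                    dq = _qmul(qa, _qmul(dq, _qconj(qa)))
                    off = _sample_ball(w_dist)
                    px = _qrot(dq, px - anchor) + anchor + off
                    qx = _qnormalize(_qmul(dq, qx))
                    species[i] = spx
                    pos[i] = px
                    quat[i] = qx
                    slot = -1
                    for t in range(ncap):
                        if species[t] < 0:
                            slot = t
                            break
                    species[slot] = spy
                    pos[slot] = py
                    quat[slot] = qy
                    born[i] = 1
                    born[slot] = 1

            # --- 3. ring closure of rigid 9-chains --------------------------
            for i in range(ncap):
                if species[i] == 8 and born[i] == 0 and np.random.random() < p_ring:
                    species[i] = RING  # identical geometry, pose unchanged

            # --- 4. encounters and association ------------------------------
            nact = 0
            for i in range(ncap):
                if 0 <= species[i] < RING and born[i] == 0:
                    active[nact] = i
                    nact += 1
            ncand = 0
            cand_cap = cand_a.shape[0]
            for ii in range(nact):
                i = active[ii]
                spi = species[i]
                if ncand >= cand_cap:
                    break
                for jj in range(nact):
                    j = active[jj]
                    spj = species[j]
                    if j == i or ncand >= cand_cap:
                        continue
                    if spi + spj + 2 > 9:
                        continue  # snapped configuration would self-overlap
                    dsq = 0.0
                    for ax in range(3):
                        dd = pos[i, ax] - pos[j, ax]
                        if periodic[ax]:
                            dd -= box[ax] * np.round(dd / box[ax])
                        dsq += dd * dd
                    cut = reach[spi] + reach[spj] + w_dist
                    if dsq > cut * cut:
                        continue
                    # donor end of i vs acceptor end of j
                    ai = pos[i] + _qrot(quat[i], ends[spi, 0, 0])
                    aj = pos[j] + _qrot(quat[j], ends[spj, 1, 0])
                    d = ai - aj
                    _min_image(d, box, periodic)
                    if d[0] * d[0] + d[1] * d[1] + d[2] * d[2] > w_dist * w_dist:
                        continue
                    ci = _qrot(quat[i], ends[spi, 0, 1])
                    cj = _qrot(quat[j], ends[spj, 1, 1])
                    if -(ci[0] * cj[0] + ci[1] * cj[1] + ci[2] * cj[2]) < cos_align:
                        continue
                    ti = _qrot(quat[i], ends[spi, 0, 2])
                    tj = _qrot(quat[j], ends[spj, 1, 2])
                    if ti[0] * tj[0] + ti[1] * tj[1] + ti[2] * tj[2] < cos_tors:
                        continue
                    cand_a[ncand] = i
                    cand_b[ncand] = j
                    ncand += 1
            # randomized processing order; one attempt per patch per step
            for c in range(ncand - 1, 0, -1):
                r = np.random.randint(0, c + 1)
                cand_a[c], cand_a[r] = cand_a[r], cand_a[c]
                cand_b[c], cand_b[r] = cand_b[r], cand_b[c]
            reacted = np.zeros(ncap, dtype=np.uint8)
            for c in range(ncand):
                i = cand_a[c]
                j = cand_b[c]
                if reacted[i] or reacted[j]:
                    continue  # one attempt per patch pair owner per step
                spi = species[i]
                spj = species[j]
                if spi < 0 or spj < 0 or spi == RING or spj == RING:
                    continue  # consumed earlier this step
                if spi + spj + 2 > 9:
                    continue
                reacted[i] = 1
                reacted[j] = 1
                if np.random.random() >= p_assoc:
                    continue
                spn = spi + spj + 1  # species of merged chain
                # hold the larger fragment; i is the donor-side fragment and
                # occupies the leading member indices of the merged chain
                if spi + 1 >= spj + 1:
                    qh = _qmul(quat[i], gq[spi, 0])
                    ph = pos[i] + _qrot(quat[i], gp[spi, 0])
                    qn = _qnormalize(_qmul(qh, _qconj(gq[spn, 0])))
                    pn = ph - _qrot(qn, gp[spn, 0])
                else:
                    k0 = spi + 1  # first member index of fragment j
                    qh = _qmul(quat[j], gq[spj, 0])
                    ph = pos[j] + _qrot(quat[j], gp[spj, 0])
                    qn = _qnormalize(_qmul(qh, _qconj(gq[spn, k0])))
                    pn = ph - _qrot(qn, gp[spn, k0])
                if _pose_blocked(
                    spn, pn, qn, beads, nbead, brad, stype, center, r_s, wall, box, 0.3
                ):
                    continue  # snap would bury beads in the core/wall: revert
                species[i] = spn
                pos[i] = pn
                quat[i] = qn
                species[j] = -1

        # --- 5. grand-canonical exchange ------------------------------------
        if gcmc_on and (step % gcmc_every == 0):
            # exchange region: frame of width w at the four lateral x/y faces
            w = gcmc_width
            n_in = 0
            for i in range(ncap):
                if species[i] == 0:
                    x = pos[i, 0]
                    y = pos[i, 1]
                    if x < w or x > box[0] - w or y < w or y > box[1] - w:
                        n_in += 1
            # two symmetric exchange attempts: each picks insertion or
            # deletion with probability 1/2 (reversible pair w.r.t. the
            # ideal grand-canonical measure, stationary count Poisson(N̄))
            for _attempt in range(2):
                if np.random.random() < 0.5:
                    if np.random.random() < min(1.0, gcmc_nbar / (n_in + 1.0)):
                        slot = -1
                        for t in range(ncap):
                            if species[t] < 0:
                                slot = t
                                break
                        if slot >= 0:
                            while True:
                                x = np.random.random() * box[0]
                                y = np.random.random() * box[1]
                                if x < w or x > box[0] - w or y < w or y > box[1] - w:
                                    break
                            species[slot] = 0
                            pos[slot, 0] = x
                            pos[slot, 1] = y
                            pos[slot, 2] = np.random.random() * box[2]
                            quat[slot] = _rand_quat()
                            n_in += 1
                else:
                    acc_del = 1.0 if gcmc_nbar <= 0.0 else min(1.0, n_in / gcmc_nbar)
                    if n_in > 0 and np.random.random() < acc_del:
                        pick = np.random.randint(0, n_in)
                        seen = 0
                        for i in range(ncap):
                            if species[i] == 0:
                                x = pos[i, 0]
                                y = pos[i, 1]
                                if x < w or x > box[0] - w or y < w or y > box[1] - w:
                                    if seen == pick:
                                        species[i] = -1
                                        n_in -= 1
                                        break
                                    seen += 1

        # --- record ---------------------------------------------------------
        if (step + 1) % record_every == 0:
            for s in range(10):
                rec_counts[n_rec, s] = 0
            for i in range(ncap):
                if species[i] >= 0:
                    rec_counts[n_rec, species[i]] += 1
            if stype != SCAFFOLD_NONE:
                rec_occupancy[n_rec] = _count_bound(
                    species, pos, quat, ncap, chg, nchg, stype, center, r_s, dr_s, nmem
                )
            n_rec += 1
    return n_rec


@njit(cache=True)
def seed_engine(seed):
    np.random.seed(seed)
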