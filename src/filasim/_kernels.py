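"""Compiled inner loop of the dynamics (numba).

``advance_block`` integrates up to ``nsteps`` time steps on a frozen
topology (no new vertices or fibers) with a cached steric pair list,
mirroring :meth:`filasim.world.World.step` exactly: same forces, same
linearly-implicit solve (per-fiber symmetric pentadiagonal LDL^T), same
growth and length projection.  It returns early when accumulated vertex
motion endangers the pair-list skin so the caller can refresh the cache.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def build_candidates(X, fiber_of, arc, seg_valid, reach, seg_len_max,
                     exclusion, periodic, Lx, Ly,
                     out_p, out_s):
    """Uniform-grid broad phase emitting (point, segment) candidates whose
    current point-to-segment distance is <= ``reach``.

    Returns the number of candidates written to ``out_p``/``out_s`` (or -1
    if capacity was exceeded).  Cell size is ``reach + seg_len_max`` so a
    3x3 neighborhood always covers every segment whose interior is within
    reach of a point.  Deterministic emission order (by point, then by the
    grid scan order)."""
    N = X.shape[0]
    if N < 2:
        return 0
    cell = reach + seg_len_max
    if periodic:
        xmin = -Lx / 2.0
        ymin = -Ly / 2.0
        nx = max(1, int(Lx / cell))
        ny = max(1, int(Ly / cell))
        cx = Lx / nx
        cy = Ly / ny
    else:
        xmin = X[0, 0]
        ymin = X[0, 1]
        xmax = xmin
        ymax = ymin
        for i in range(N):
            if X[i, 0] < xmin:
                xmin = X[i, 0]
            if X[i, 0] > xmax:
                xmax = X[i, 0]
            if X[i, 1] < ymin:
                ymin = X[i, 1]
            if X[i, 1] > ymax:
                ymax = X[i, 1]
        nx = int((xmax - xmin) / cell) + 1
        ny = int((ymax - ymin) / cell) + 1
        cx = cell
        cy = cell
    ncell = nx * ny
    counts = np.zeros(ncell + 1, dtype=np.int64)
    ci = np.empty(N, dtype=np.int64)
    for i in range(N):
        x = X[i, 0]
        y = X[i, 1]
        if periodic:
            x = x - Lx * np.floor((x - xmin) / Lx) - xmin
            y = y - Ly * np.floor((y - ymin) / Ly) - ymin
            gx = int(x / cx)
            gy = int(y / cy)
            if gx >= nx:
                gx = nx - 1
            if gy >= ny:
                gy = ny - 1
        else:
            gx = int((x - xmin) / cx)
            gy = int((y - ymin) / cy)
        c = gy * nx + gx
        ci[i] = c
        counts[c + 1] += 1
    for c in range(ncell):
        counts[c + 1] += counts[c]
    order = np.empty(N, dtype=np.int64)
    fill = counts[:-1].copy()
    for i in range(N):
        order[fill[ci[i]]] = i
        fill[ci[i]] += 1
    cap = out_p.shape[0]
    m = 0
    reach2 = reach * reach
    for p in range(N):
        c = ci[p]
        gy = c // nx
        gx = c - gy * nx
        for dgy in range(-1, 2):
            qy = gy + dgy
            if periodic:
                qy = qy % ny
            elif qy < 0 or qy >= ny:
                continue
            for dgx in range(-1, 2):
                qx = gx + dgx
                if periodic:
                    qx = qx % nx
                elif qx < 0 or qx >= nx:
                    continue
                qc = qy * nx + qx
                for k in range(counts[qc], counts[qc + 1]):
                    s = order[k]
                    if s >= N - 1 or not seg_valid[s]:
                        continue
                    if fiber_of[p] == fiber_of[s]:
                        da = arc[p] - arc[s]
                        if -exclusion <= da <= exclusion:
                            continue
                    abx = X[s + 1, 0] - X[s, 0]
                    aby = X[s + 1, 1] - X[s, 1]
                    apx = X[p, 0] - X[s, 0]
                    apy = X[p, 1] - X[s, 1]
                    if periodic:
                        abx -= Lx * np.round(abx / Lx)
                        aby -= Ly * np.round(aby / Ly)
                        apx -= Lx * np.round(apx / Lx)
                        apy -= Ly * np.round(apy / Ly)
                    ab2 = abx * abx + aby * aby
                    if ab2 < 1e-24:
                        ab2 = 1e-24
                    t = (apx * abx + apy * aby) / ab2
                    if t < 0.0:
                        t = 0.0
                    elif t > 1.0:
                        t = 1.0
                    dx = apx - t * abx
                    dy = apy - t * aby
                    if dx * dx + dy * dy <= reach2:
                        if m >= cap:
                            return -1
                        out_p[m] = p
                        out_s[m] = s
                        m += 1
    return m


@njit(cache=True, fastmath=True)
def prune_candidates(X, pts, segs, reach2, periodic, Lx, Ly, keep):
    """Mark (point, segment) candidates whose current point-to-segment
    squared distance is within ``reach2``."""
    for q in range(pts.shape[0]):
        p = pts[q]
        s = segs[q]
        abx = X[s + 1, 0] - X[s, 0]
        aby = X[s + 1, 1] - X[s, 1]
        apx = X[p, 0] - X[s, 0]
        apy = X[p, 1] - X[s, 1]
        if periodic:
            abx -= Lx * np.round(abx / Lx)
            aby -= Ly * np.round(aby / Ly)
            apx -= Lx * np.round(apx / Lx)
            apy -= Ly * np.round(apy / Ly)
        ab2 = abx * abx + aby * aby
        if ab2 < 1e-24:
            ab2 = 1e-24
        t = (apx * abx + apy * aby) / ab2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        dx = apx - t * abx
        dy = apy - t * aby
        keep[q] = dx * dx + dy * dy <= reach2


@njit(cache=True)
def _block_ldl_solve(Mxx, Mxy, Myy, C1xx, C1xy, C1yy, c2, bx, by, n,
                     Dxx, Dxy, Dyy, L1, L2):
    """Solve the SPD block-pentadiagonal system of one fiber in place.

    Blocks are 2x2: diagonal ``M_i`` (symmetric), first-neighbor coupling
    ``C1_i = A[i, i+1]`` (symmetric), second-neighbor ``c2_i * I``.
    ``bx, by``: RHS components, overwritten with the solution.
    ``Dxx/Dxy/Dyy`` (length n) and ``L1, L2`` ((n, 4) row-major 2x2) are
    scratch.  Block LDL^T: D_i = M_i - L1_{i-1} D_{i-1} L1_{i-1}^T
    - L2_{i-2} D_{i-2} L2_{i-2}^T, etc.
    """
    for i in range(n):
        dxx = Mxx[i]
        dxy = Mxy[i]
        dyy = Myy[i]
        if i >= 1:
            a0 = L1[i - 1, 0]
            a1 = L1[i - 1, 1]
            a2 = L1[i - 1, 2]
            a3 = L1[i - 1, 3]
            pxx = Dxx[i - 1]
            pxy = Dxy[i - 1]
            pyy = Dyy[i - 1]
            # T = L1 * D  (2x2 * sym 2x2)
            t0 = a0 * pxx + a1 * pxy
            t1 = a0 * pxy + a1 * pyy
            t2 = a2 * pxx + a3 * pxy
            t3 = a2 * pxy + a3 * pyy
            # subtract T * L1^T
            dxx -= t0 * a0 + t1 * a1
            dxy -= t0 * a2 + t1 * a3
            dyy -= t2 * a2 + t3 * a3
        if i >= 2:
            a0 = L2[i - 2, 0]
            a1 = L2[i - 2, 1]
            a2 = L2[i - 2, 2]
            a3 = L2[i - 2, 3]
            pxx = Dxx[i - 2]
            pxy = Dxy[i - 2]
            pyy = Dyy[i - 2]
            t0 = a0 * pxx + a1 * pxy
            t1 = a0 * pxy + a1 * pyy
            t2 = a2 * pxx + a3 * pxy
            t3 = a2 * pxy + a3 * pyy
            dxx -= t0 * a0 + t1 * a1
            dxy -= t0 * a2 + t1 * a3
            dyy -= t2 * a2 + t3 * a3
        Dxx[i] = dxx
        Dxy[i] = dxy
        Dyy[i] = dyy
        det = dxx * dyy - dxy * dxy
        ixx = dyy / det
        ixy = -dxy / det
        iyy = dxx / det
        if i + 1 < n:
            # E = C1_i (symmetric) minus L2_{i-1} D_{i-1} L1_{i-1}^T
            exx = C1xx[i]
            exy = C1xy[i]
            eyx = C1xy[i]
            eyy = C1yy[i]
            if i >= 1:
                a0 = L2[i - 1, 0]
                a1 = L2[i - 1, 1]
                a2 = L2[i - 1, 2]
                a3 = L2[i - 1, 3]
                pxx = Dxx[i - 1]
                pxy = Dxy[i - 1]
                pyy = Dyy[i - 1]
                b0 = L1[i - 1, 0]
                b1 = L1[i - 1, 1]
                b2 = L1[i - 1, 2]
                b3 = L1[i - 1, 3]
                t0 = a0 * pxx + a1 * pxy
                t1 = a0 * pxy + a1 * pyy
                t2 = a2 * pxx + a3 * pxy
                t3 = a2 * pxy + a3 * pyy
                exx -= t0 * b0 + t1 * b1
                exy -= t0 * b2 + t1 * b3
                eyx -= t2 * b0 + t3 * b1
                eyy -= t2 * b2 + t3 * b3
            # L1_i = E * D_i^{-1}
            L1[i, 0] = exx * ixx + exy * ixy
            L1[i, 1] = exx * ixy + exy * iyy
            L1[i, 2] = eyx * ixx + eyy * ixy
            L1[i, 3] = eyx * ixy + eyy * iyy
        if i + 2 < n:
            L2[i, 0] = c2[i] * ixx
            L2[i, 1] = c2[i] * ixy
            L2[i, 2] = c2[i] * ixy
            L2[i, 3] = c2[i] * iyy
    # forward: L z = b
    for i in range(n):
        zx = bx[i]
        zy = by[i]
        if i >= 1:
            zx -= L1[i - 1, 0] * bx[i - 1] + L1[i - 1, 1] * by[i - 1]
            zy -= L1[i - 1, 2] * bx[i - 1] + L1[i - 1, 3] * by[i - 1]
        if i >= 2:
            zx -= L2[i - 2, 0] * bx[i - 2] + L2[i - 2, 1] * by[i - 2]
            zy -= L2[i - 2, 2] * bx[i - 2] + L2[i - 2, 3] * by[i - 2]
        bx[i] = zx
        by[i] = zy
    # backward: x_i = D_i^{-1} z_i - L1_i^T x_{i+1} - L2_i^T x_{i+2}
    for i in range(n - 1, -1, -1):
        det = Dxx[i] * Dyy[i] - Dxy[i] * Dxy[i]
        xx = (Dyy[i] * bx[i] - Dxy[i] * by[i]) / det
        xy = (-Dxy[i] * bx[i] + Dxx[i] * by[i]) / det
        if i + 1 < n:
            xx -= L1[i, 0] * bx[i + 1] + L1[i, 2] * by[i + 1]
            xy -= L1[i, 1] * bx[i + 1] + L1[i, 3] * by[i + 1]
        if i + 2 < n:
            xx -= L2[i, 0] * bx[i + 2] + L2[i, 2] * by[i + 2]
            xy -= L2[i, 1] * bx[i + 2] + L2[i, 3] * by[i + 2]
        bx[i] = xx
        by[i] = xy


@njit(cache=True, fastmath=True)
def advance_block(X, acc, offsets, nv, term_len, growing,
                  joints, A_main_h, A_off1_h, A_off2_h,
                  K, l0, k_stretch, gamma, dt, noise_coeff,
                  pairs_i, pairs_j, steric_on, K_push, K_pull, d0, dm,
                  periodic, Lx, Ly,
                  b_gv, b_ax, b_ay, k_b,
                  lk_gm, lk_gd, lk_ma, lk_mb, k_link, kappa, lk_phi0,
                  v0, f_s, monomer_cap, total_len_in,
                  xi, nsteps, skin_half):
    """Advance up to ``nsteps`` steps; returns (steps_done, total_length).

    ``A_*_h`` are the halved diagonals of the linearized bending operator
    (the Crank-Nicolson half is premultiplied).  Mutates ``X``, ``acc``
    (accumulated per-vertex displacement since the last pair refresh) and
    ``term_len`` in place.
    """
    N = X.shape[0]
    F = np.empty((N, 2))
    Dg = np.empty(N)
    X0 = np.empty((N, 2))
    nfib = nv.shape[0]
    nmax = 0
    for f in range(nfib):
        if nv[f] > nmax:
            nmax = nv[f]
    Mxx = np.empty(nmax)
    Mxy = np.empty(nmax)
    Myy = np.empty(nmax)
    C1xx = np.empty(nmax)
    C1xy = np.empty(nmax)
    C1yy = np.empty(nmax)
    c2loc = np.empty(nmax)
    Dxx_s = np.empty(nmax)
    Dxy_s = np.empty(nmax)
    Dyy_s = np.empty(nmax)
    L1_s = np.empty((nmax, 4))
    L2_s = np.empty((nmax, 4))
    ks2 = 0.5 * k_stretch
    tip_fx = np.empty(nfib)
    tip_fy = np.empty(nfib)
    total_len = total_len_in
    gdt = gamma / dt
    steps_done = 0

    for step in range(nsteps):
        for i in range(N):
            X0[i, 0] = X[i, 0]
            X0[i, 1] = X[i, 1]
            F[i, 0] = 0.0
            F[i, 1] = 0.0
            Dg[i] = 0.0
        # ---- bending (exact angle gradient) ----
        for jj in range(joints.shape[0]):
            j = joints[jj]
            ax = X[j, 0] - X[j - 1, 0]
            ay = X[j, 1] - X[j - 1, 1]
            bx = X[j + 1, 0] - X[j, 0]
            by = X[j + 1, 1] - X[j, 1]
            cr = ax * by - ay * bx
            dtp = ax * bx + ay * by
            theta = np.arctan2(cr, dtp)
            coef = K * theta / l0
            lmin2 = 0.49 * l0 * l0
            a2 = ax * ax + ay * ay
            if a2 < lmin2:
                a2 = lmin2
            b2 = bx * bx + by * by
            if b2 < lmin2:
                b2 = lmin2
            gax = coef * (-ay) / a2
            gay = coef * ax / a2
            gbx = coef * (-by) / b2
            gby = coef * bx / b2
            F[j - 1, 0] -= gax
            F[j - 1, 1] -= gay
            F[j, 0] += gax + gbx
            F[j, 1] += gay + gby
            F[j + 1, 0] -= gbx
            F[j + 1, 1] -= gby
        # ---- stretching springs (rest length l0, terminal term_len) ----
        for f in range(nfib):
            s = offsets[f]
            n = nv[f]
            for i in range(1, n):
                dx = X[s + i, 0] - X[s + i - 1, 0]
                dy = X[s + i, 1] - X[s + i - 1, 1]
                ln = np.sqrt(dx * dx + dy * dy)
                if ln < 1e-12:
                    ln = 1e-12
                rest = term_len[f] if i == n - 1 else l0
                w = k_stretch * (ln - rest) / ln
                fx = w * dx
                fy = w * dy
                F[s + i - 1, 0] += fx
                F[s + i - 1, 1] += fy
                F[s + i, 0] -= fx
                F[s + i, 1] -= fy
        # ---- steric: point vs segment (pairs_j = segment left vertex) ----
        if steric_on:
            for q in range(pairs_i.shape[0]):
                p = pairs_i[q]
                sL = pairs_j[q]
                abx = X[sL + 1, 0] - X[sL, 0]
                aby = X[sL + 1, 1] - X[sL, 1]
                apx = X[p, 0] - X[sL, 0]
                apy = X[p, 1] - X[sL, 1]
                if periodic:
                    abx -= Lx * np.round(abx / Lx)
                    aby -= Ly * np.round(aby / Ly)
                    apx -= Lx * np.round(apx / Lx)
                    apy -= Ly * np.round(apy / Ly)
                ab2 = abx * abx + aby * aby
                if ab2 < 1e-24:
                    ab2 = 1e-24
                t = (apx * abx + apy * aby) / ab2
                if t < 0.0:
                    t = 0.0
                elif t > 1.0:
                    t = 1.0
                dx = apx - t * abx          # P - Q
                dy = apy - t * aby
                d = np.sqrt(dx * dx + dy * dy)
                if d > dm:
                    continue
                if d < 1e-12:
                    d = 1e-12
                if d < d0:
                    k = K_push
                else:
                    k = K_pull
                w = -k * (d - d0) / d       # force on P along (P-Q)
                fx = w * dx
                fy = w * dy
                F[p, 0] += fx
                F[p, 1] += fy
                F[sL, 0] -= (1.0 - t) * fx
                F[sL, 1] -= (1.0 - t) * fy
                F[sL + 1, 0] -= t * fx
                F[sL + 1, 1] -= t * fy
                Dg[p] += k
                Dg[sL] += k * (1.0 - t)
                Dg[sL + 1] += k * t
        # ---- binder springs (force on fiber only) ----
        for bq in range(b_gv.shape[0]):
            g = b_gv[bq]
            dx = b_ax[bq] - X[g, 0]
            dy = b_ay[bq] - X[g, 1]
            if periodic:
                dx -= Lx * np.round(dx / Lx)
                dy -= Ly * np.round(dy / Ly)
            F[g, 0] += k_b * dx
            F[g, 1] += k_b * dy
            Dg[g] += k_b
        # ---- branch links: Hookean + angular spring ----
        for lq in range(lk_gm.shape[0]):
            gm = lk_gm[lq]
            gd = lk_gd[lq]
            dx = X[gm, 0] - X[gd, 0]
            dy = X[gm, 1] - X[gd, 1]
            if periodic:
                dx -= Lx * np.round(dx / Lx)
                dy -= Ly * np.round(dy / Ly)
            F[gd, 0] += k_link * dx
            F[gd, 1] += k_link * dy
            F[gm, 0] -= k_link * dx
            F[gm, 1] -= k_link * dy
            Dg[gd] += k_link
            Dg[gm] += k_link
            ma = lk_ma[lq]
            mb = lk_mb[lq]
            ax = X[mb, 0] - X[ma, 0]
            ay = X[mb, 1] - X[ma, 1]
            bx = X[gd + 1, 0] - X[gd, 0]
            by = X[gd + 1, 1] - X[gd, 1]
            cr = ax * by - ay * bx
            dtp = ax * bx + ay * by
            phi = np.arctan2(cr, dtp)
            dphi = phi - lk_phi0[lq]
            while dphi > np.pi:
                dphi -= 2 * np.pi
            while dphi < -np.pi:
                dphi += 2 * np.pi
            coef = kappa * dphi
            lmin2 = 0.49 * l0 * l0
            a2 = ax * ax + ay * ay
            if a2 < lmin2:
                a2 = lmin2
            b2 = bx * bx + by * by
            if b2 < lmin2:
                b2 = lmin2
            gax = coef * (-ay) / a2
            gay = coef * ax / a2
            gbx = coef * (-by) / b2
            gby = coef * bx / b2
            Dg[ma] += kappa / a2
            Dg[mb] += kappa / a2
            Dg[gd] += kappa / b2
            Dg[gd + 1] += kappa / b2
            F[ma, 0] -= gax
            F[ma, 1] -= gay
            F[mb, 0] += gax
            F[mb, 1] += gay
            F[gd, 0] += gbx
            F[gd, 1] += gby
            F[gd + 1, 0] -= gbx
            F[gd + 1, 1] -= gby
        # ---- record explicit tip forces for the growth law ----
        for f in range(nfib):
            if growing[f]:
                tip = offsets[f] + nv[f] - 1
                tip_fx[f] = F[tip, 0]
                tip_fy[f] = F[tip, 1]
        # ---- add thermal noise, then the per-fiber implicit solve ----
        if noise_coeff > 0.0:
            for i in range(N):
                F[i, 0] += noise_coeff * xi[step, i, 0]
                F[i, 1] += noise_coeff * xi[step, i, 1]
        for f in range(nfib):
            s = offsets[f]
            n = nv[f]
            for i in range(n):
                Mxx[i] = gdt + A_main_h[s + i] + Dg[s + i]
                Myy[i] = Mxx[i]
                Mxy[i] = 0.0
                c2loc[i] = A_off2_h[s + i]
            for i in range(n - 1):
                dx = X[s + i + 1, 0] - X[s + i, 0]
                dy = X[s + i + 1, 1] - X[s + i, 1]
                ln = np.sqrt(dx * dx + dy * dy)
                if ln < 1e-12:
                    ln = 1e-12
                tx = dx / ln
                ty = dy / ln
                sxx = ks2 * tx * tx
                sxy = ks2 * tx * ty
                syy = ks2 * ty * ty
                Mxx[i] += sxx
                Mxy[i] += sxy
                Myy[i] += syy
                Mxx[i + 1] += sxx
                Mxy[i + 1] += sxy
                Myy[i + 1] += syy
                C1xx[i] = A_off1_h[s + i] - sxx
                C1xy[i] = -sxy
                C1yy[i] = A_off1_h[s + i] - syy
            _block_ldl_solve(Mxx, Mxy, Myy, C1xx, C1xy, C1yy, c2loc,
                             F[s:s + n, 0], F[s:s + n, 1], n,
                             Dxx_s, Dxy_s, Dyy_s, L1_s, L2_s)
        for i in range(N):
            X[i, 0] += F[i, 0]
            X[i, 1] += F[i, 1]
        # ---- force-dependent tip growth ----
        for f in range(nfib):
            if not growing[f]:
                continue
            tip = offsets[f] + nv[f] - 1
            tx = X[tip, 0] - X[tip - 1, 0]
            ty = X[tip, 1] - X[tip - 1, 1]
            tn = np.sqrt(tx * tx + ty * ty)
            if tn < 1e-12:
                tn = 1e-12
            tx /= tn
            ty /= tn
            ft = tip_fx[f] * tx + tip_fy[f] * ty
            if ft < 0.0:
                arg = ft / f_s
                if arg < -50.0:
                    arg = -50.0
                v = v0 * np.exp(arg)
            else:
                v = v0
            if monomer_cap > 0.0:
                fac = 1.0 - total_len / monomer_cap
                if fac < 0.0:
                    fac = 0.0
                v *= fac
            adv = v * dt
            X[tip, 0] += adv * tx
            X[tip, 1] += adv * ty
            term_len[f] += adv
            total_len += adv
        # ---- accumulate true per-vertex displacement for the skin test ----
        maxacc2 = 0.0
        for i in range(N):
            acc[i, 0] += X[i, 0] - X0[i, 0]
            acc[i, 1] += X[i, 1] - X0[i, 1]
            a2 = acc[i, 0] * acc[i, 0] + acc[i, 1] * acc[i, 1]
            if a2 > maxacc2:
                maxacc2 = a2
        steps_done += 1
        if maxacc2 > skin_half * skin_half:
            break
    return steps_done, total_len
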