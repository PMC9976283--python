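"""Molecular integrals over contracted Cartesian Gaussians.

McMurchie-Davidson scheme: 1-D Hermite expansion coefficients E_t^{ij} for
overlap-like integrals, Hermite Coulomb integrals R_tuv with Boys-function
bases for nuclear attraction and electron repulsion. Kernels are compiled
with numba; electron-repulsion integrals are stored as a dense symmetric
matrix over packed index pairs (pq, rs), which makes the Coulomb build a
single matrix-vector product.

All quantities in atomic units (Bohr, Hartree).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .basis import COMP_LX, COMP_LY, COMP_LZ, PackedBasis

# ---------------------------------------------------------------- Boys


@njit(cache=True)
def boys(mmax: int, T: float, F: np.ndarray) -> None:
    """Boys functions F_0..F_mmax(T) into F (length >= mmax+1)."""
    if T < 1e-13:
        for m in range(mmax + 1):
            F[m] = 1.0 / (2 * m + 1)
    elif T < 35.0:
        e = math.exp(-T)
        term = 1.0 / (2 * mmax + 1)
        s = term
        k = 1
        while True:
            term *= 2.0 * T / (2 * mmax + 2 * k + 1)
            s += term
            if term < 1e-17 * s:
                break
            k += 1
        F[mmax] = e * s
        for m in range(mmax - 1, -1, -1):
            F[m] = (2.0 * T * F[m + 1] + e) / (2 * m + 1)
    else:
        F[0] = 0.5 * math.sqrt(math.pi / T)
        e = math.exp(-T)
        for m in range(1, mmax + 1):
            F[m] = ((2 * m - 1) * F[m - 1] - e) / (2.0 * T)


# ------------------------------------------------- Hermite expansions


@njit(cache=True)
def _fill_E(E: np.ndarray, la: int, lb: int, xab: float, a: float, b: float) -> None:
    """1-D Hermite expansion coefficients E[i, j, t] for exponents a, b.

    ``xab`` is A_x - B_x. E must be zeroed over the used region beforehand.
    """
    p = a + b
    mu = a * b / p
    E[0, 0, 0] = math.exp(-mu * xab * xab)
    xpa = -b / p * xab
    xpb = a / p * xab
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                i0, j0, x0 = i - 1, j, xpa
            else:
                i0, j0, x0 = i, j - 1, xpb
            for t in range(i + j + 1):
                v = 0.0
                if t >= 1:
                    v += E[i0, j0, t - 1] / (2.0 * p)
                v += x0 * E[i0, j0, t]
                if t + 1 <= i0 + j0:
                    v += (t + 1) * E[i0, j0, t + 1]
                E[i, j, t] = v


@njit(cache=True)
def _fill_R(R: np.ndarray, L: int, alpha: float, x: float, y: float, z: float,
            F: np.ndarray) -> None:
    """Hermite Coulomb integrals R[m, t, u, v]; F holds Boys values."""
    for m in range(L + 1):
        R[m, 0, 0, 0] = (-2.0 * alpha) ** m * F[m]
    for t in range(1, L + 1):
        for m in range(L + 1 - t):
            v = x * R[m + 1, t - 1, 0, 0]
            if t > 1:
                v += (t - 1) * R[m + 1, t - 2, 0, 0]
            R[m, t, 0, 0] = v
    for t in range(L + 1):
        for u in range(1, L + 1 - t):
            for m in range(L + 1 - t - u):
                v = y * R[m + 1, t, u - 1, 0]
                if u > 1:
                    v += (u - 1) * R[m + 1, t, u - 2, 0]
                R[m, t, u, 0] = v
    for t in range(L + 1):
        for u in range(L + 1 - t):
            for w in range(1, L + 1 - t - u):
                for m in range(L + 1 - t - u - w):
                    v = z * R[m + 1, t, u, w - 1]
                    if w > 1:
                        v += (w - 1) * R[m + 1, t, u, w - 2]
                    R[m, t, u, w] = v


# ------------------------------------------------- one-electron matrices


@njit(cache=True)
def _one_electron_kernel(shell_l, shell_nprim, shell_pstart, shell_center,
                         shell_ao_start, prim_exp, prim_coef, comp_scale,
                         comp_lx, comp_ly, comp_lz,
                         Zs, Zcoords, nbf,
                         S, T, V, M):
    """Fill overlap S, kinetic T, nuclear attraction V and dipole M (3, n, n)."""
    nshell = shell_l.shape[0]
    maxl = 0
    for i in range(nshell):
        if shell_l[i] > maxl:
            maxl = shell_l[i]
    # E buffers sized for kinetic (+2 on the ket index)
    Ex = np.zeros((maxl + 1, maxl + 3, 2 * maxl + 5))
    Ey = np.zeros_like(Ex)
    Ez = np.zeros_like(Ex)
    Lmax = 2 * maxl
    F = np.zeros(Lmax + 1)
    R = np.zeros((Lmax + 1, Lmax + 1, Lmax + 1, Lmax + 1))
    nnuc = Zs.shape[0]

    for isha in range(nshell):
        la = shell_l[isha]
        A = shell_center[isha]
        na = (la + 1) * (la + 2) // 2
        for ishb in range(isha + 1):
            lb = shell_l[ishb]
            B = shell_center[ishb]
            nb = (lb + 1) * (lb + 2) // 2
            ao_a = shell_ao_start[isha]
            ao_b = shell_ao_start[ishb]
            xab = A[0] - B[0]
            yab = A[1] - B[1]
            zab = A[2] - B[2]
            Sblk = np.zeros((na, nb))
            Tblk = np.zeros((na, nb))
            Vblk = np.zeros((na, nb))
            Mblk = np.zeros((3, na, nb))
            for pa in range(shell_nprim[isha]):
                ia = shell_pstart[isha] + pa
                a = prim_exp[ia]
                ca = prim_coef[ia]
                for pb in range(shell_nprim[ishb]):
                    ib = shell_pstart[ishb] + pb
                    b = prim_exp[ib]
                    cb = prim_coef[ib]
                    p = a + b
                    cc = ca * cb
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    Ex[:la + 1, :lb + 3, :la + lb + 3] = 0.0
                    Ey[:la + 1, :lb + 3, :la + lb + 3] = 0.0
                    Ez[:la + 1, :lb + 3, :la + lb + 3] = 0.0
                    _fill_E(Ex, la, lb + 2, xab, a, b)
                    _fill_E(Ey, la, lb + 2, yab, a, b)
                    _fill_E(Ez, la, lb + 2, zab, a, b)
                    sp = math.sqrt(math.pi / p)
                    ov3 = sp * sp * sp
                    for ka in range(na):
                        ax = comp_lx[la, ka]
                        ay = comp_ly[la, ka]
                        az = comp_lz[la, ka]
                        for kb in range(nb):
                            bx = comp_lx[lb, kb]
                            by = comp_ly[lb, kb]
                            bz = comp_lz[lb, kb]
                            sx = Ex[ax, bx, 0]
                            sy = Ey[ay, by, 0]
                            sz = Ez[az, bz, 0]
                            Sblk[ka, kb] += cc * ov3 * sx * sy * sz
                            # dipole (about the origin)
                            dx = Ex[ax, bx, 1] + Px * sx if ax + bx >= 1 else Px * sx
                            dy = Ey[ay, by, 1] + Py * sy if ay + by >= 1 else Py * sy
                            dz = Ez[az, bz, 1] + Pz * sz if az + bz >= 1 else Pz * sz
                            Mblk[0, ka, kb] += cc * ov3 * dx * sy * sz
                            Mblk[1, ka, kb] += cc * ov3 * sx * dy * sz
                            Mblk[2, ka, kb] += cc * ov3 * sx * sy * dz
                            # kinetic, 1-D pieces
                            tx = -2.0 * b * b * Ex[ax, bx + 2, 0] + b * (2 * bx + 1) * sx
                            if bx >= 2:
                                tx -= 0.5 * bx * (bx - 1) * Ex[ax, bx - 2, 0]
                            ty = -2.0 * b * b * Ey[ay, by + 2, 0] + b * (2 * by + 1) * sy
                            if by >= 2:
                                ty -= 0.5 * by * (by - 1) * Ey[ay, by - 2, 0]
                            tz = -2.0 * b * b * Ez[az, bz + 2, 0] + b * (2 * bz + 1) * sz
                            if bz >= 2:
                                tz -= 0.5 * bz * (bz - 1) * Ez[az, bz - 2, 0]
                            Tblk[ka, kb] += cc * ov3 * (tx * sy * sz + sx * ty * sz + sx * sy * tz)
                    # nuclear attraction
                    L = la + lb
                    for inuc in range(nnuc):
                        Cx = Zcoords[inuc, 0]
                        Cy = Zcoords[inuc, 1]
                        Cz = Zcoords[inuc, 2]
                        xpc = Px - Cx
                        ypc = Py - Cy
                        zpc = Pz - Cz
                        r2 = xpc * xpc + ypc * ypc + zpc * zpc
                        boys(L, p * r2, F)
                        R[:L + 1, :L + 1, :L + 1, :L + 1] = 0.0
                        _fill_R(R, L, p, xpc, ypc, zpc, F)
                        pref = -Zs[inuc] * 2.0 * math.pi / p * cc
                        for ka in range(na):
                            ax = comp_lx[la, ka]
                            ay = comp_ly[la, ka]
                            az = comp_lz[la, ka]
                            for kb in range(nb):
                                bx = comp_lx[lb, kb]
                                by = comp_ly[lb, kb]
                                bz = comp_lz[lb, kb]
                                acc = 0.0
                                for t in range(ax + bx + 1):
                                    ext = Ex[ax, bx, t]
                                    for u in range(ay + by + 1):
                                        eyu = Ey[ay, by, u]
                                        for w in range(az + bz + 1):
                                            acc += ext * eyu * Ez[az, bz, w] * R[0, t, u, w]
                                Vblk[ka, kb] += pref * acc
            # scatter with component scales
            for ka in range(na):
                i = ao_a + ka
                for kb in range(nb):
                    j = ao_b + kb
                    if ishb == isha and j > i:
                        continue
                    sc = comp_scale[i] * comp_scale[j]
                    S[i, j] = Sblk[ka, kb] * sc
                    S[j, i] = S[i, j]
                    T[i, j] = Tblk[ka, kb] * sc
                    T[j, i] = T[i, j]
                    V[i, j] = Vblk[ka, kb] * sc
                    V[j, i] = V[i, j]
                    for d in range(3):
                        M[d, i, j] = Mblk[d, ka, kb] * sc
                        M[d, j, i] = M[d, i, j]


def one_electron_matrices(basis: PackedBasis, Zs: np.ndarray, Zcoords: np.ndarray):
    """Overlap, kinetic, nuclear-attraction and dipole matrices (a.u.)."""
    n = basis.nbf
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    M = np.zeros((3, n, n))
    _one_electron_kernel(
        basis.shell_l, basis.shell_nprim, basis.shell_pstart, basis.shell_center,
        basis.shell_ao_start, basis.prim_exp, basis.prim_coef, basis.comp_scale,
        COMP_LX, COMP_LY, COMP_LZ,
        np.asarray(Zs, float), np.asarray(Zcoords, float).reshape(-1, 3), n,
        S, T, V, M)
    return S, T, V, M


# ------------------------------------------------------------- ERI


@njit(cache=True)
def _pair_data(shell_l, shell_nprim, shell_pstart, shell_center, prim_exp, prim_coef):
    """Precompute primitive-pair quantities and Hermite E tables per shell pair.

    Returns flat arrays describing every (shell i >= shell j) pair: exponents
    p, centers P, coefficient products, and E tables stored contiguously.
    """
    nshell = shell_l.shape[0]
    npairs = nshell * (nshell + 1) // 2
    pair_i = np.empty(npairs, np.int32)
    pair_j = np.empty(npairs, np.int32)
    pair_pp_start = np.empty(npairs, np.int64)
    pair_np = np.empty(npairs, np.int32)
    pair_e_start = np.empty(npairs, np.int64)

    # count sizes
    tot_pp = 0
    tot_e = 0
    k = 0
    for i in range(nshell):
        for j in range(i + 1):
            pair_i[k] = i
            pair_j[k] = j
            npp = shell_nprim[i] * shell_nprim[j]
            pair_pp_start[k] = tot_pp
            pair_np[k] = npp
            pair_e_start[k] = tot_e
            esz = 3 * (shell_l[i] + 1) * (shell_l[j] + 1) * (shell_l[i] + shell_l[j] + 1)
            tot_pp += npp
            tot_e += npp * esz
            k += 1

    pp_p = np.empty(tot_pp)
    pp_P = np.empty((tot_pp, 3))
    pp_cc = np.empty(tot_pp)
    e_tab = np.zeros(tot_e)

    maxl = 0
    for i in range(nshell):
        if shell_l[i] > maxl:
            maxl = shell_l[i]
    Ebuf = np.zeros((maxl + 1, maxl + 1, 2 * maxl + 1))

    k = 0
    for i in range(nshell):
        la = shell_l[i]
        A = shell_center[i]
        for j in range(i + 1):
            lb = shell_l[j]
            B = shell_center[j]
            nt = la + lb + 1
            esz1 = (la + 1) * (lb + 1) * nt
            pp0 = pair_pp_start[k]
            e0 = pair_e_start[k]
            q = 0
            for pa in range(shell_nprim[i]):
                ia = shell_pstart[i] + pa
                a = prim_exp[ia]
                ca = prim_coef[ia]
                for pb in range(shell_nprim[j]):
                    ib = shell_pstart[j] + pb
                    b = prim_exp[ib]
                    cb = prim_coef[ib]
                    p = a + b
                    idx = pp0 + q
                    pp_p[idx] = p
                    pp_P[idx, 0] = (a * A[0] + b * B[0]) / p
                    pp_P[idx, 1] = (a * A[1] + b * B[1]) / p
                    pp_P[idx, 2] = (a * A[2] + b * B[2]) / p
                    pp_cc[idx] = ca * cb
                    for d in range(3):
                        Ebuf[:la + 1, :lb + 1, :nt] = 0.0
                        _fill_E(Ebuf, la, lb, A[d] - B[d], a, b)
                        off = e0 + q * 3 * esz1 + d * esz1
                        for ii in range(la + 1):
                            for jj in range(lb + 1):
                                for t in range(nt):
                                    e_tab[off + (ii * (lb + 1) + jj) * nt + t] = Ebuf[ii, jj, t]
                    q += 1
            k += 1
    return (pair_i, pair_j, pair_pp_start, pair_np, pair_e_start,
            pp_p, pp_P, pp_cc, e_tab)


@njit(cache=True)
def _prim_schwarz(pair_i, pair_j, pair_pp_start, pair_np, pair_e_start,
                  pp_p, pp_P, pp_cc, e_tab, shell_l,
                  comp_lx, comp_ly, comp_lz):
    """sqrt(max |(ab|ab)|) for every primitive pair (screening bound)."""
    npp_tot = pp_p.shape[0]
    qprim = np.zeros(npp_tot)
    maxl = 0
    for i in range(shell_l.shape[0]):
        if shell_l[i] > maxl:
            maxl = shell_l[i]
    Lmax = 4 * maxl
    ncmax = (maxl + 1) * (maxl + 2) // 2
    F = np.zeros(Lmax + 1)
    R = np.zeros((Lmax + 1, Lmax + 1, Lmax + 1, Lmax + 1))
    Dbuf = np.zeros((ncmax, ncmax, 2 * maxl + 1, 2 * maxl + 1, 2 * maxl + 1))
    block = np.zeros((ncmax, ncmax, ncmax, ncmax))
    dummy_q = np.ones(1)
    nsp = pair_i.shape[0]
    for sp in range(nsp):
        i = pair_i[sp]
        j = pair_j[sp]
        la = shell_l[i]
        lb = shell_l[j]
        na = (la + 1) * (la + 2) // 2
        nb = (lb + 1) * (lb + 2) // 2
        esz = 3 * (la + 1) * (lb + 1) * (la + lb + 1)
        pp0 = pair_pp_start[sp]
        e0 = pair_e_start[sp]
        for u in range(pair_np[sp]):
            k = pp0 + u
            _eri_quartet(la, lb, la, lb,
                         1, pp_p[k:k + 1], pp_P[k:k + 1], pp_cc[k:k + 1],
                         e_tab[e0 + u * esz:e0 + (u + 1) * esz], dummy_q,
                         1, pp_p[k:k + 1], pp_P[k:k + 1], pp_cc[k:k + 1],
                         e_tab[e0 + u * esz:e0 + (u + 1) * esz], dummy_q,
                         comp_lx, comp_ly, comp_lz, F, R, Dbuf, block, 0.0)
            qmax = 0.0
            for ka in range(na):
                for kb in range(nb):
                    val = abs(block[ka, kb, ka, kb])
                    if val > qmax:
                        qmax = val
            qprim[k] = math.sqrt(qmax)
    return qprim


@njit(cache=True)
def _eri_quartet(la, lb, lc, ld,
                 npp_ab, pp_p_ab, pp_P_ab, pp_cc_ab, e_ab, q_ab,
                 npp_cd, pp_p_cd, pp_P_cd, pp_cc_cd, e_cd, q_cd,
                 comp_lx, comp_ly, comp_lz, F, R, Dbuf, block, prim_thresh):
    """Contracted ERI block (na, nb, nc, nd) for one shell quartet.

    ``e_ab``/``e_cd`` are the flattened per-primitive-pair Hermite tables
    produced by _pair_data (layout: [prim_pair, dim, i, j, t]).
    """
    na = (la + 1) * (la + 2) // 2
    nb = (lb + 1) * (lb + 2) // 2
    nc = (lc + 1) * (lc + 2) // 2
    nd = (ld + 1) * (ld + 2) // 2
    ntab = la + lb + 1
    ntcd = lc + ld + 1
    esz_ab = (la + 1) * (lb + 1) * ntab
    esz_cd = (lc + 1) * (ld + 1) * ntcd
    L = la + lb + lc + ld
    block[:na, :nb, :nc, :nd] = 0.0

    for u1 in range(npp_ab):
        p = pp_p_ab[u1]
        Pxx = pp_P_ab[u1, 0]
        Pyy = pp_P_ab[u1, 1]
        Pzz = pp_P_ab[u1, 2]
        ccab = pp_cc_ab[u1]
        qa = q_ab[u1]
        eab0 = u1 * 3 * esz_ab
        for u2 in range(npp_cd):
            if qa * q_cd[u2] < prim_thresh:
                continue
            q = pp_p_cd[u2]
            Qx = pp_P_cd[u2, 0]
            Qy = pp_P_cd[u2, 1]
            Qz = pp_P_cd[u2, 2]
            cc = ccab * pp_cc_cd[u2]
            ecd0 = u2 * 3 * esz_cd
            alpha = p * q / (p + q)
            xpq = Pxx - Qx
            ypq = Pyy - Qy
            zpq = Pzz - Qz
            r2 = xpq * xpq + ypq * ypq + zpq * zpq
            boys(L, alpha * r2, F)
            R[:L + 1, :L + 1, :L + 1, :L + 1] = 0.0
            _fill_R(R, L, alpha, xpq, ypq, zpq, F)
            pref = cc * 2.0 * math.pi ** 2.5 / (p * q * math.sqrt(p + q))

            # ket-side contraction: Dbuf[kc, kd, t, u, v]
            for kc in range(nc):
                cx = comp_lx[lc, kc]
                cy = comp_ly[lc, kc]
                cz = comp_lz[lc, kc]
                for kd in range(nd):
                    dx = comp_lx[ld, kd]
                    dy = comp_ly[ld, kd]
                    dz = comp_lz[ld, kd]
                    for t in range(la + lb + 1):
                        for u in range(la + lb + 1 - t):
                            for v in range(la + lb + 1 - t - u):
                                acc = 0.0
                                for tt in range(cx + dx + 1):
                                    e1 = e_cd[ecd0 + 0 * esz_cd + (cx * (ld + 1) + dx) * ntcd + tt]
                                    if e1 == 0.0:
                                        continue
                                    for uu in range(cy + dy + 1):
                                        e2 = e1 * e_cd[ecd0 + 1 * esz_cd + (cy * (ld + 1) + dy) * ntcd + uu]
                                        if e2 == 0.0:
                                            continue
                                        for vv in range(cz + dz + 1):
                                            e3 = e2 * e_cd[ecd0 + 2 * esz_cd + (cz * (ld + 1) + dz) * ntcd + vv]
                                            if ((tt + uu + vv) & 1) == 1:
                                                e3 = -e3
                                            acc += e3 * R[0, t + tt, u + uu, v + vv]
                                Dbuf[kc, kd, t, u, v] = acc

            # bra side
            for ka in range(na):
                ax = comp_lx[la, ka]
                ay = comp_ly[la, ka]
                az = comp_lz[la, ka]
                for kb in range(nb):
                    bx = comp_lx[lb, kb]
                    by = comp_ly[lb, kb]
                    bz = comp_lz[lb, kb]
                    for kc in range(nc):
                        for kd in range(nd):
                            acc = 0.0
                            for t in range(ax + bx + 1):
                                e1 = e_ab[eab0 + 0 * esz_ab + (ax * (lb + 1) + bx) * ntab + t]
                                if e1 == 0.0:
                                    continue
                                for u in range(ay + by + 1):
                                    e2 = e1 * e_ab[eab0 + 1 * esz_ab + (ay * (lb + 1) + by) * ntab + u]
                                    if e2 == 0.0:
                                        continue
                                    for v in range(az + bz + 1):
                                        e3 = e2 * e_ab[eab0 + 2 * esz_ab + (az * (lb + 1) + bz) * ntab + v]
                                        acc += e3 * Dbuf[kc, kd, t, u, v]
                            block[ka, kb, kc, kd] += pref * acc


@njit(cache=True)
def _eri_build(shell_l, shell_nprim, shell_pstart, shell_center, shell_ao_start,
               prim_exp, prim_coef, comp_scale, comp_lx, comp_ly, comp_lz,
               nbf, screen_thresh):
    """Dense ERI supermatrix V[pq, rs] over packed pair indices (p >= q)."""
    (pair_i, pair_j, pair_pp_start, pair_np, pair_e_start,
     pp_p, pp_P, pp_cc, e_tab) = _pair_data(
        shell_l, shell_nprim, shell_pstart, shell_center, prim_exp, prim_coef)
    qprim = _prim_schwarz(pair_i, pair_j, pair_pp_start, pair_np, pair_e_start,
                          pp_p, pp_P, pp_cc, e_tab, shell_l,
                          comp_lx, comp_ly, comp_lz)
    prim_thresh = screen_thresh * 0.01
    nsp = pair_i.shape[0]
    M = nbf * (nbf + 1) // 2
    V = np.zeros((M, M))

    maxl = 0
    for i in range(shell_l.shape[0]):
        if shell_l[i] > maxl:
            maxl = shell_l[i]
    Lmax = 4 * maxl
    ncmax = (maxl + 1) * (maxl + 2) // 2
    F = np.zeros(Lmax + 1)
    R = np.zeros((Lmax + 1, Lmax + 1, Lmax + 1, Lmax + 1))
    Dbuf = np.zeros((ncmax, ncmax, 2 * maxl + 1, 2 * maxl + 1, 2 * maxl + 1))
    block = np.zeros((ncmax, ncmax, ncmax, ncmax))

    # Schwarz bounds sqrt((ab|ab)) per shell pair
    Q = np.zeros(nsp)
    for sp in range(nsp):
        i = pair_i[sp]
        j = pair_j[sp]
        la = shell_l[i]
        lb = shell_l[j]
        na = (la + 1) * (la + 2) // 2
        nb = (lb + 1) * (lb + 2) // 2
        pp0 = pair_pp_start[sp]
        npp = pair_np[sp]
        e0 = pair_e_start[sp]
        esz = 3 * (la + 1) * (lb + 1) * (la + lb + 1)
        _eri_quartet(la, lb, la, lb,
                     npp, pp_p[pp0:pp0 + npp], pp_P[pp0:pp0 + npp], pp_cc[pp0:pp0 + npp],
                     e_tab[e0:e0 + npp * esz], qprim[pp0:pp0 + npp],
                     npp, pp_p[pp0:pp0 + npp], pp_P[pp0:pp0 + npp], pp_cc[pp0:pp0 + npp],
                     e_tab[e0:e0 + npp * esz], qprim[pp0:pp0 + npp],
                     comp_lx, comp_ly, comp_lz, F, R, Dbuf, block, prim_thresh)
        qmax = 0.0
        for ka in range(na):
            for kb in range(nb):
                val = abs(block[ka, kb, ka, kb])
                if val > qmax:
                    qmax = val
        Q[sp] = math.sqrt(qmax)

    for sp1 in range(nsp):
        i = pair_i[sp1]
        j = pair_j[sp1]
        la = shell_l[i]
        lb = shell_l[j]
        na = (la + 1) * (la + 2) // 2
        nb = (lb + 1) * (lb + 2) // 2
        ao_a = shell_ao_start[i]
        ao_b = shell_ao_start[j]
        pp0a = pair_pp_start[sp1]
        nppa = pair_np[sp1]
        e0a = pair_e_start[sp1]
        esza = 3 * (la + 1) * (lb + 1) * (la + lb + 1)
        for sp2 in range(sp1 + 1):
            if Q[sp1] * Q[sp2] < screen_thresh:
                continue
            k = pair_i[sp2]
            l = pair_j[sp2]
            lc = shell_l[k]
            ld = shell_l[l]
            nc = (lc + 1) * (lc + 2) // 2
            nd = (ld + 1) * (ld + 2) // 2
            ao_c = shell_ao_start[k]
            ao_d = shell_ao_start[l]
            pp0b = pair_pp_start[sp2]
            nppb = pair_np[sp2]
            e0b = pair_e_start[sp2]
            eszb = 3 * (lc + 1) * (ld + 1) * (lc + ld + 1)
            _eri_quartet(la, lb, lc, ld,
                         nppa, pp_p[pp0a:pp0a + nppa], pp_P[pp0a:pp0a + nppa],
                         pp_cc[pp0a:pp0a + nppa], e_tab[e0a:e0a + nppa * esza],
                         qprim[pp0a:pp0a + nppa],
                         nppb, pp_p[pp0b:pp0b + nppb], pp_P[pp0b:pp0b + nppb],
                         pp_cc[pp0b:pp0b + nppb], e_tab[e0b:e0b + nppb * eszb],
                         qprim[pp0b:pp0b + nppb],
                         comp_lx, comp_ly, comp_lz, F, R, Dbuf, block, prim_thresh)
            for ka in range(na):
                bi = ao_a + ka
                for kb in range(nb):
                    bj = ao_b + kb
                    if bj > bi:
                        continue
                    pq = bi * (bi + 1) // 2 + bj
                    for kc in range(nc):
                        bk = ao_c + kc
                        for kd in range(nd):
                            bl = ao_d + kd
                            if bl > bk:
                                continue
                            rs = bk * (bk + 1) // 2 + bl
                            val = (block[ka, kb, kc, kd]
                                   * comp_scale[bi] * comp_scale[bj]
                                   * comp_scale[bk] * comp_scale[bl])
                            V[pq, rs] = val
                            V[rs, pq] = val
    return V


def eri_supermatrix(basis: PackedBasis, screen_thresh: float = 1e-12) -> np.ndarray:
    """Electron-repulsion integrals as a dense (pq, rs) pair supermatrix."""
    return _eri_build(
        basis.shell_l, basis.shell_nprim, basis.shell_pstart, basis.shell_center,
        basis.shell_ao_start, basis.prim_exp, basis.prim_coef, basis.comp_scale,
        COMP_LX, COMP_LY, COMP_LZ, basis.nbf, screen_thresh)


@njit(cache=True)
def _exchange_from_supermatrix(V, D, nbf, K):
    """K_pr = sum_qs (pq|rs) D_qs from the packed-pair supermatrix."""
    M = nbf * (nbf + 1) // 2
    K[:, :] = 0.0
    pq = 0
    for p in range(nbf):
        for q in range(p + 1):
            rs = 0
            for r in range(nbf):
                for s in range(r + 1):
                    v = V[pq, rs]
                    if v != 0.0:
                        if p == q:
                            v *= 0.5
                        if r == s:
                            v *= 0.5
                        K[p, r] += v * D[q, s]
                        K[p, s] += v * D[q, r]
                        K[q, r] += v * D[p, s]
                        K[q, s] += v * D[p, r]
                    rs += 1
            pq += 1


def coulomb_exchange(V: np.ndarray, D: np.ndarray):
    """Coulomb and exchange matrices from the ERI supermatrix and density D."""
    nbf = D.shape[0]
    iu = np.tril_indices(nbf)
    dvec = D[iu] * 2.0
    dvec[np.arange(nbf) * (np.arange(nbf) + 3) // 2] *= 0.5  # undouble diagonal
    jvec = V @ dvec
    J = np.zeros_like(D)
    J[iu] = jvec
    J = J + J.T - np.diag(np.diag(J))
    K = np.zeros_like(D)
    _exchange_from_supermatrix(V, D, nbf, K)
    return J, K
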