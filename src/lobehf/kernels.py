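"""Numba-compiled numerical kernels.

Everything here operates on flat float64/int arrays so that a single
uniform s-Gaussian expression serves every integral class — the point of
the lobe-function construction.  The two-electron kernel consumes
precomputed pair tables (pair overlap, pair center, combined exponent) and
reduces each primitive quadruple to a handful of multiplies, one square
root and one error-function evaluation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Rational error-function approximation (Abramowitz-Stegun 7.1.26 family):
# max absolute deviation ~1.5e-7, and exact saturation to 1 for x >= 4
# where 1 - erf(4) ~ 1.5e-8.
_C0 = 0.3275911
_C1 = 0.254829592
_C2 = -0.284496736
_C3 = 1.421413741
_C4 = -1.453152027
_C5 = 1.061405429

#: erf argument beyond which the kernel returns exactly 1
ERF_SATURATION = 4.0


@njit(cache=True)
def erf_approx_scalar(x: float) -> float:
    if x >= ERF_SATURATION:
        return 1.0
    t = 1.0 / (1.0 + _C0 * x)
    poly = t * (_C1 + t * (_C2 + t * (_C3 + t * (_C4 + t * _C5))))
    return 1.0 - poly * math.exp(-x * x)


@njit(cache=True)
def f11_half(x: float) -> float:
    """F11(1/2, 3/2, -x) = sqrt(pi) erf(sqrt(x)) / (2 sqrt(x)).

    A short Taylor branch below x = 0.09 extends the x -> 0 limit (value 1)
    with full relative accuracy; elsewhere the rational erf approximation is
    used.  Max relative error ~2.7e-7 over all x >= 0.
    """
    if x < 0.09:
        return 1.0 + x * (-1.0 / 3.0 + x * (0.1 + x * (-1.0 / 42.0
                  + x * (1.0 / 216.0 - x / 1320.0))))
    s = math.sqrt(x)
    return 0.8862269254527580 * erf_approx_scalar(s) / s  # sqrt(pi)/2


@njit(cache=True)
def boys0(t: float) -> float:
    """F0(t) with machine-precision erf (one-electron integrals)."""
    if t < 1e-14:
        return 1.0 - t / 3.0
    s = math.sqrt(t)
    return 0.8862269254527580 * math.erf(s) / s


# ------------------------------------------------------------- one-electron

@njit(cache=True)
def smoothstep_weight(d: float, r_cl: float, r_cu: float) -> float:
    """Coulomb cut-off weight 1 + 2x^3 - 3x^2 on [r_cl, r_cu] (Bohr here)."""
    if d <= r_cl:
        return 1.0
    if d >= r_cu:
        return 0.0
    x = (d - r_cl) / (r_cu - r_cl)
    return 1.0 + 2.0 * x ** 3 - 3.0 * x ** 2


@njit(cache=True)
def one_electron_matrices(off, coeff, alpha, center, nuc_pos, nuc_chg,
                          orb_atom_pos, r_cl, r_cu):
    """Overlap, kinetic and nuclear-attraction matrices over lobe orbitals.

    All primitives are s-Gaussians, so S, T and V use the same three closed
    forms regardless of the parent shell's angular momentum.  Each nuclear
    contribution to V is weighted by the same smoothstep Coulomb cut-off as
    the ERIs (distance: density center -- the atomic mean of the two parent
    atoms -- to nucleus), so the screened electrostatics stays consistent
    between neutral groups.  Pass r_cu = inf to disable.
    """
    n = len(off) - 1
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    n_nuc = len(nuc_chg)
    for i in range(n):
        for j in range(i, n):
            cx = 0.5 * (orb_atom_pos[i, 0] + orb_atom_pos[j, 0])
            cy = 0.5 * (orb_atom_pos[i, 1] + orb_atom_pos[j, 1])
            cz = 0.5 * (orb_atom_pos[i, 2] + orb_atom_pos[j, 2])
            s = 0.0
            t = 0.0
            v = 0.0
            for a in range(off[i], off[i + 1]):
                ca = coeff[a]
                aa = alpha[a]
                ax, ay, az = center[a, 0], center[a, 1], center[a, 2]
                for b in range(off[j], off[j + 1]):
                    cb = coeff[b]
                    ab = alpha[b]
                    p = aa + ab
                    mu = aa * ab / p
                    dx = ax - center[b, 0]
                    dy = ay - center[b, 1]
                    dz = az - center[b, 2]
                    r2 = dx * dx + dy * dy + dz * dz
                    pre = ca * cb * (np.pi / p) ** 1.5 * math.exp(-mu * r2)
                    s += pre
                    t += pre * mu * (3.0 - 2.0 * mu * r2)
                    px = (aa * ax + ab * center[b, 0]) / p
                    py = (aa * ay + ab * center[b, 1]) / p
                    pz = (aa * az + ab * center[b, 2]) / p
                    pre_v = ca * cb * 2.0 * np.pi / p * math.exp(-mu * r2)
                    for k in range(n_nuc):
                        wx = cx - nuc_pos[k, 0]
                        wy = cy - nuc_pos[k, 1]
                        wz = cz - nuc_pos[k, 2]
                        w = smoothstep_weight(
                            math.sqrt(wx * wx + wy * wy + wz * wz),
                            r_cl, r_cu)
                        if w == 0.0:
                            continue
                        qx = px - nuc_pos[k, 0]
                        qy = py - nuc_pos[k, 1]
                        qz = pz - nuc_pos[k, 2]
                        v -= w * nuc_chg[k] * pre_v * boys0(
                            p * (qx * qx + qy * qy + qz * qz))
            S[i, j] = S[j, i] = s
            T[i, j] = T[j, i] = t
            V[i, j] = V[j, i] = v
    return S, T, V


@njit(cache=True)
def dipole_matrices(off, coeff, alpha, center):
    """Electronic position-operator matrices <i| r |j> (3, n, n)."""
    n = len(off) - 1
    D = np.zeros((3, n, n))
    for i in range(n):
        for j in range(i, n):
            dx = 0.0
            dy = 0.0
            dz = 0.0
            for a in range(off[i], off[i + 1]):
                for b in range(off[j], off[j + 1]):
                    aa = alpha[a]
                    ab = alpha[b]
                    p = aa + ab
                    mu = aa * ab / p
                    rx = center[a, 0] - center[b, 0]
                    ry = center[a, 1] - center[b, 1]
                    rz = center[a, 2] - center[b, 2]
                    r2 = rx * rx + ry * ry + rz * rz
                    s = coeff[a] * coeff[b] * (np.pi / p) ** 1.5 * math.exp(
                        -mu * r2)
                    dx += s * (aa * center[a, 0] + ab * center[b, 0]) / p
                    dy += s * (aa * center[a, 1] + ab * center[b, 1]) / p
                    dz += s * (aa * center[a, 2] + ab * center[b, 2]) / p
            D[0, i, j] = D[0, j, i] = dx
            D[1, i, j] = D[1, j, i] = dy
            D[2, i, j] = D[2, j, i] = dz
    return D


# ---------------------------------------------------------------- pair tables

@njit(cache=True)
def build_pair_table(off, coeff, alpha, center, pair_i, pair_j):
    """Primitive pair tables for a list of orbital pairs.

    Returns per-primitive-pair arrays: offsets into the flat arrays, the
    pair overlap O (with the sqrt(2) pi^(5/4) kernel prefactor), the pair
    center, and the combined exponent.
    """
    npair = len(pair_i)
    counts = np.empty(npair + 1, dtype=np.int64)
    counts[0] = 0
    for p in range(npair):
        i = pair_i[p]
        j = pair_j[p]
        counts[p + 1] = counts[p] + (off[i + 1] - off[i]) * (off[j + 1] - off[j])
    ntot = counts[npair]
    O = np.empty(ntot)
    cen = np.empty((ntot, 3))
    psum = np.empty(ntot)
    pref = math.sqrt(2.0) * np.pi ** 1.25
    for p in range(npair):
        i = pair_i[p]
        j = pair_j[p]
        k = counts[p]
        for a in range(off[i], off[i + 1]):
            aa = alpha[a]
            ca = coeff[a]
            for b in range(off[j], off[j + 1]):
                ab = alpha[b]
                ps = aa + ab
                dx = center[a, 0] - center[b, 0]
                dy = center[a, 1] - center[b, 1]
                dz = center[a, 2] - center[b, 2]
                r2 = dx * dx + dy * dy + dz * dz
                O[k] = pref * ca * coeff[b] / ps ** 1.5 * math.exp(
                    -aa * ab / ps * r2)
                cen[k, 0] = (aa * center[a, 0] + ab * center[b, 0]) / ps
                cen[k, 1] = (aa * center[a, 1] + ab * center[b, 1]) / ps
                cen[k, 2] = (aa * center[a, 2] + ab * center[b, 2]) / ps
                psum[k] = ps
                k += 1
    return counts, O, cen, psum


@njit(cache=True)
def eri_from_pairs(poff, O, cen, psum, quad_p, quad_q):
    """Contracted ERIs for a list of (pair, pair) index combinations.

    Each primitive quadruple is O_ab * O_cd * sqrt(P) * F11(1/2,3/2,-P d^2)
    with P the reduced combined exponent and d the pair-center distance.
    """
    nq = len(quad_p)
    out = np.empty(nq)
    for q in range(nq):
        p1 = quad_p[q]
        p2 = quad_q[q]
        acc = 0.0
        for a in range(poff[p1], poff[p1 + 1]):
            Oa = O[a]
            pa = psum[a]
            ax, ay, az = cen[a, 0], cen[a, 1], cen[a, 2]
            for b in range(poff[p2], poff[p2 + 1]):
                pb = psum[b]
                P = pa * pb / (pa + pb)
                dx = ax - cen[b, 0]
                dy = ay - cen[b, 1]
                dz = az - cen[b, 2]
                x = P * (dx * dx + dy * dy + dz * dz)
                acc += Oa * O[b] * math.sqrt(P) * f11_half(x)
        out[q] = acc
    return out


@njit(cache=True)
def density_relevances(aoff, acoeff, aalpha, acenter, pair_i, pair_j):
    """r(rho_ij): analytic integral of the absolute orbital-pair product.

    Uses the sign-definite (per-lobe, anisotropic) representation: every
    term is a positive Gaussian-product integral, evaluated axis by axis.
    """
    npair = len(pair_i)
    out = np.zeros(npair)
    for p in range(npair):
        i = pair_i[p]
        j = pair_j[p]
        acc = 0.0
        for a in range(aoff[i], aoff[i + 1]):
            ca = acoeff[a]
            for b in range(aoff[j], aoff[j + 1]):
                term = ca * acoeff[b]
                for k in range(3):
                    s = aalpha[a, k] + aalpha[b, k]
                    d = acenter[a, k] - acenter[b, k]
                    term *= math.sqrt(np.pi / s) * math.exp(
                        -aalpha[a, k] * aalpha[b, k] / s * d * d)
                acc += term
        out[p] = acc
    return out


# ------------------------------------------------------------------ screening

@njit(cache=True)
def select_eri_quads(pc, rel, r_cu_bohr, comb_threshold, d_floor_bohr):
    """Enumerate surviving (pair, pair) combinations.

    pc: (npair, 3) density centers in Bohr; rel: per-pair relevances.
    Keeps p <= q with center distance below the upper Coulomb cut-off and
    combined relevance rel_p * rel_q / max(d, floor) above threshold.
    Returns (p_idx, q_idx, distance_bohr).
    """
    npair = len(rel)
    # two passes: count then fill
    count = 0
    for p in range(npair):
        for q in range(p, npair):
            dx = pc[p, 0] - pc[q, 0]
            dy = pc[p, 1] - pc[q, 1]
            dz = pc[p, 2] - pc[q, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d >= r_cu_bohr:
                continue
            df = d if d > d_floor_bohr else d_floor_bohr
            if rel[p] * rel[q] / df > comb_threshold:
                count += 1
    p_idx = np.empty(count, dtype=np.int64)
    q_idx = np.empty(count, dtype=np.int64)
    dist = np.empty(count)
    k = 0
    for p in range(npair):
        for q in range(p, npair):
            dx = pc[p, 0] - pc[q, 0]
            dy = pc[p, 1] - pc[q, 1]
            dz = pc[p, 2] - pc[q, 2]
            d = math.sqrt(dx * dx + dy * dy + dz * dz)
            if d >= r_cu_bohr:
                continue
            df = d if d > d_floor_bohr else d_floor_bohr
            if rel[p] * rel[q] / df > comb_threshold:
                p_idx[k] = p
                q_idx[k] = q
                dist[k] = d
                k += 1
    return p_idx, q_idx, dist


# ----------------------------------------------------------------- Fock build

@njit(cache=True)
def fock_two_electron(n, qi, qj, qk, ql, vals, P):
    """G = J - K/2 from a canonical unique-ERI list.

    Each stored quadruple (i<=j, k<=l, (ij)<=(kl)) is expanded over its
    distinct index permutations; every ordered permutation (a,b,c,d)
    contributes J[a,b] += P[c,d] v and K[a,c] += P[b,d] v.
    """
    J = np.zeros((n, n))
    K = np.zeros((n, n))
    for t in range(len(vals)):
        i = qi[t]
        j = qj[t]
        k = qk[t]
        l = ql[t]
        v = vals[t]
        same_pair = i == k and j == l
        for s in range(2):
            if s == 1 and i == j:
                break
            bi = j if s == 1 else i
            bj = i if s == 1 else j
            for r in range(2):
                if r == 1 and k == l:
                    break
                ki = l if r == 1 else k
                kj = k if r == 1 else l
                J[bi, bj] += P[ki, kj] * v
                K[bi, ki] += P[bj, kj] * v
                if not same_pair:
                    J[ki, kj] += P[bi, bj] * v
                    K[ki, bi] += P[kj, bj] * v
    return J - 0.5 * K
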