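"""Numba kernels for the anisotropic repulsion forces and the integrator.

The interaction has compact support: a pair can only interact when the
centre distance is below the semi-major axis ``a`` (the normalised
squared distance satisfies ``r_ij^2 >= ||d||^2 / a^2``).  The cell-list
kernels bin particles on a uniform periodic grid of bin size >= a and
visit each unordered pair once, accumulating both body frames (r_ij and
r_ji differ, so a pair contributes separately to each cell).  An
all-pairs kernel is kept as the small-system fallback and as the
brute-force oracle used by the tests.

The pair loops are written flat (no helper calls) — with numba the
layered version compiles to code several times slower.
"""

import numpy as np
from numba import njit

# half of the neighbour-offset stencil; the other half is covered by the
# symmetric pair visit.  Self-bin pairs are enumerated with q > p.
_HALF_OFFSETS_2D = np.array([(0, 1), (1, -1), (1, 0), (1, 1)], dtype=np.int64)
_HALF_OFFSETS_3D = np.array(
    [
        (0, 0, 1),
        (0, 1, -1), (0, 1, 0), (0, 1, 1),
        (1, -1, -1), (1, -1, 0), (1, -1, 1),
        (1, 0, -1), (1, 0, 0), (1, 0, 1),
        (1, 1, -1), (1, 1, 0), (1, 1, 1),
    ],
    dtype=np.int64,
)


@njit(cache=True)
def phi_scalar(s):
    if s >= 1.0:
        return 0.0
    return np.exp(-1.0 / (1.0 - s)) / s


@njit(cache=True)
def phi_prime_scalar(s):
    if s >= 1.0:
        return 0.0
    u = 1.0 - s
    E = np.exp(-1.0 / u)
    return E * (-1.0 / (s * s) - 1.0 / (s * u * u))


@njit(cache=True)
def _sorted_bins(pos, L, nb):
    """Counting sort of particles into nb^d periodic bins.

    Returns (order, start, binidx): the particles of bin b are
    order[start[b]:start[b+1]].
    """
    N, dim = pos.shape
    binsz = L / nb
    nbins = nb ** dim
    binidx = np.empty(N, np.int64)
    count = np.zeros(nbins + 1, np.int64)
    for i in range(N):
        idx = 0
        for k in range(dim):
            c = int(pos[i, k] / binsz)
            if c >= nb:
                c = nb - 1
            elif c < 0:
                c = 0
            idx = idx * nb + c
        binidx[i] = idx
        count[idx + 1] += 1
    for b in range(nbins):
        count[b + 1] += count[b]
    order = np.empty(N, np.int64)
    fill = count[:nbins].copy()
    for i in range(N):
        b = binidx[i]
        order[fill[b]] = i
        fill[b] += 1
    return order, count, binidx


@njit(cache=True, fastmath=True)
def forces_cell_list_2d(pos, ori, L, nb, a2, b2, e2, eps):
    N = pos.shape[0]
    V = np.zeros(N)
    gx = np.zeros((N, 2))
    gw = np.zeros((N, 2))
    order, start, _ = _sorted_bins(pos, L, nb)
    offsets = _HALF_OFFSETS_2D
    n_off = offsets.shape[0]
    nbins = nb * nb
    halfL = 0.5 * L
    for b in range(nbins):
        s0 = start[b]
        s1 = start[b + 1]
        if s0 == s1:
            continue
        c1 = b % nb
        c0 = b // nb
        for m in range(-1, n_off):
            if m < 0:
                t0, t1 = s0, s1
            else:
                n0 = (c0 + offsets[m, 0]) % nb
                n1 = (c1 + offsets[m, 1]) % nb
                t0 = start[n0 * nb + n1]
                t1 = start[n0 * nb + n1 + 1]
            for p in range(s0, s1):
                i = order[p]
                xi0 = pos[i, 0]
                xi1 = pos[i, 1]
                q0 = p + 1 if m < 0 else t0
                for q in range(q0, t1):
                    j = order[q]
                    d0 = pos[j, 0] - xi0
                    if d0 > halfL:
                        d0 -= L
                    elif d0 < -halfL:
                        d0 += L
                    d1 = pos[j, 1] - xi1
                    if d1 > halfL:
                        d1 -= L
                    elif d1 < -halfL:
                        d1 += L
                    dd = d0 * d0 + d1 * d1
                    if dd >= a2:
                        continue
                    # frame of i
                    proj = d0 * ori[i, 0] + d1 * ori[i, 1]
                    s = (dd - e2 * proj * proj) / b2
                    if s < eps:
                        s = eps
                    if s < 1.0:
                        u = 1.0 - s
                        E = np.exp(-1.0 / u)
                        V[i] += E / s
                        fp = E * (-1.0 / (s * s) - 1.0 / (s * u * u))
                        cx = 2.0 * fp / b2
                        cw = -2.0 * fp * e2 * proj / b2
                        gx[i, 0] += cx * (e2 * proj * ori[i, 0] - d0)
                        gx[i, 1] += cx * (e2 * proj * ori[i, 1] - d1)
                        gw[i, 0] += cw * d0
                        gw[i, 1] += cw * d1
                    # frame of j (displacement reversed)
                    proj = -(d0 * ori[j, 0] + d1 * ori[j, 1])
                    s = (dd - e2 * proj * proj) / b2
                    if s < eps:
                        s = eps
                    if s < 1.0:
                        u = 1.0 - s
                        E = np.exp(-1.0 / u)
                        V[j] += E / s
                        fp = E * (-1.0 / (s * s) - 1.0 / (s * u * u))
                        cx = 2.0 * fp / b2
                        cw = -2.0 * fp * e2 * proj / b2
                        gx[j, 0] += cx * (e2 * proj * ori[j, 0] + d0)
                        gx[j, 1] += cx * (e2 * proj * ori[j, 1] + d1)
                        gw[j, 0] -= cw * d0
                        gw[j, 1] -= cw * d1
    return V, gx, gw


@njit(cache=True, fastmath=True)
def forces_cell_list_3d(pos, ori, L, nb, a2, b2, e2, eps):
    N = pos.shape[0]
    V = np.zeros(N)
    gx = np.zeros((N, 3))
    gw = np.zeros((N, 3))
    order, start, _ = _sorted_bins(pos, L, nb)
    offsets = _HALF_OFFSETS_3D
    n_off = offsets.shape[0]
    nbins = nb * nb * nb
    halfL = 0.5 * L
    for b in range(nbins):
        s0 = start[b]
        s1 = start[b + 1]
        if s0 == s1:
            continue
        c2 = b % nb
        c1 = (b // nb) % nb
        c0 = b // (nb * nb)
        for m in range(-1, n_off):
            if m < 0:
                t0, t1 = s0, s1
            else:
                n0 = (c0 + offsets[m, 0]) % nb
                n1 = (c1 + offsets[m, 1]) % nb
                n2 = (c2 + offsets[m, 2]) % nb
                nbin = (n0 * nb + n1) * nb + n2
                t0 = start[nbin]
                t1 = start[nbin + 1]
            for p in range(s0, s1):
                i = order[p]
                xi0 = pos[i, 0]
                xi1 = pos[i, 1]
                xi2 = pos[i, 2]
                q0 = p + 1 if m < 0 else t0
                for q in range(q0, t1):
                    j = order[q]
                    d0 = pos[j, 0] - xi0
                    if d0 > halfL:
                        d0 -= L
                    elif d0 < -halfL:
                        d0 += L
                    d1 = pos[j, 1] - xi1
                    if d1 > halfL:
                        d1 -= L
                    elif d1 < -halfL:
                        d1 += L
                    d2 = pos[j, 2] - xi2
                    if d2 > halfL:
                        d2 -= L
                    elif d2 < -halfL:
                        d2 += L
                    dd = d0 * d0 + d1 * d1 + d2 * d2
                    if dd >= a2:
                        continue
                    proj = d0 * ori[i, 0] + d1 * ori[i, 1] + d2 * ori[i, 2]
                    s = (dd - e2 * proj * proj) / b2
                    if s < eps:
                        s = eps
                    if s < 1.0:
                        u = 1.0 - s
                        E = np.exp(-1.0 / u)
                        V[i] += E / s
                        fp = E * (-1.0 / (s * s) - 1.0 / (s * u * u))
                        cx = 2.0 * fp / b2
                        cw = -2.0 * fp * e2 * proj / b2
                        gx[i, 0] += cx * (e2 * proj * ori[i, 0] - d0)
                        gx[i, 1] += cx * (e2 * proj * ori[i, 1] - d1)
                        gx[i, 2] += cx * (e2 * proj * ori[i, 2] - d2)
                        gw[i, 0] += cw * d0
                        gw[i, 1] += cw * d1
                        gw[i, 2] += cw * d2
                    proj = -(d0 * ori[j, 0] + d1 * ori[j, 1] + d2 * ori[j, 2])
                    s = (dd - e2 * proj * proj) / b2
                    if s < eps:
                        s = eps
                    if s < 1.0:
                        u = 1.0 - s
                        E = np.exp(-1.0 / u)
                        V[j] += E / s
                        fp = E * (-1.0 / (s * s) - 1.0 / (s * u * u))
                        cx = 2.0 * fp / b2
                        cw = -2.0 * fp * e2 * proj / b2
                        gx[j, 0] += cx * (e2 * proj * ori[j, 0] + d0)
                        gx[j, 1] += cx * (e2 * proj * ori[j, 1] + d1)
                        gx[j, 2] += cx * (e2 * proj * ori[j, 2] + d2)
                        gw[j, 0] -= cw * d0
                        gw[j, 1] -= cw * d1
                        gw[j, 2] -= cw * d2
    return V, gx, gw


@njit(cache=True, fastmath=True)
def forces_allpairs(pos, ori, L, a2, b2, e2, eps):
    """O(N^2) evaluation; the oracle for the cell-list kernels."""
    N, dim = pos.shape
    V = np.zeros(N)
    gx = np.zeros((N, dim))
    gw = np.zeros((N, dim))
    halfL = 0.5 * L
    for i in range(N):
        for j in range(i + 1, N):
            dd = 0.0
            d0 = d1 = d2 = 0.0
            d0 = pos[j, 0] - pos[i, 0]
            if d0 > halfL:
                d0 -= L
            elif d0 < -halfL:
                d0 += L
            d1 = pos[j, 1] - pos[i, 1]
            if d1 > halfL:
                d1 -= L
            elif d1 < -halfL:
                d1 += L
            dd = d0 * d0 + d1 * d1
            if dim == 3:
                d2 = pos[j, 2] - pos[i, 2]
                if d2 > halfL:
                    d2 -= L
                elif d2 < -halfL:
                    d2 += L
                dd += d2 * d2
            if dd >= a2:
                continue
            for (k, sgn) in ((i, 1.0), (j, -1.0)):
                proj = sgn * (d0 * ori[k, 0] + d1 * ori[k, 1])
                if dim == 3:
                    proj += sgn * d2 * ori[k, 2]
                s = (dd - e2 * proj * proj) / b2
                if s < eps:
                    s = eps
                if s >= 1.0:
                    continue
                u = 1.0 - s
                E = np.exp(-1.0 / u)
                V[k] += E / s
                fp = E * (-1.0 / (s * s) - 1.0 / (s * u * u))
                cx = 2.0 * fp / b2
                cw = -2.0 * fp * e2 * proj / b2
                gx[k, 0] += cx * (e2 * proj * ori[k, 0] - sgn * d0)
                gx[k, 1] += cx * (e2 * proj * ori[k, 1] - sgn * d1)
                gw[k, 0] += cw * sgn * d0
                gw[k, 1] += cw * sgn * d1
                if dim == 3:
                    gx[k, 2] += cx * (e2 * proj * ori[k, 2] - sgn * d2)
                    gw[k, 2] += cw * sgn * d2
    return V, gx, gw


@njit(cache=True)
def _forces(pos, ori, L, nb, a2, b2, e2, eps):
    if nb >= 3 and pos.shape[0] > 32:
        if pos.shape[1] == 2:
            return forces_cell_list_2d(pos, ori, L, nb, a2, b2, e2, eps)
        return forces_cell_list_3d(pos, ori, L, nb, a2, b2, e2, eps)
    return forces_allpairs(pos, ori, L, a2, b2, e2, eps)


@njit(cache=True)
def integrate_chunk(pos, ori, L, nb, a, b, e2, eps, c, alpha, beta, dt,
                    n_steps):
    """n_steps explicit Euler steps, in place.

    Per step: forces; x += dt*(c w - alpha grad_x V) wrapped into [0, L);
    w += dt*(-beta P_perp grad_w V) then renormalised.  Returns the
    index of the first cell whose state went non-finite, or -1.
    """
    N, dim = pos.shape
    a2 = a * a
    b2 = b * b
    for _ in range(n_steps):
        V, gx, gw = _forces(pos, ori, L, nb, a2, b2, e2, eps)
        for i in range(N):
            dot = 0.0
            for k in range(dim):
                dot += gw[i, k] * ori[i, k]
            norm2 = 0.0
            finite = True
            for k in range(dim):
                x = pos[i, k] + dt * (c * ori[i, k] - alpha * gx[i, k])
                x = x % L
                if x >= L or x < 0.0:
                    x = 0.0
                pos[i, k] = x
                if not np.isfinite(x):
                    finite = False
                w = ori[i, k] + dt * (-beta * (gw[i, k] - dot * ori[i, k]))
                ori[i, k] = w
                norm2 += w * w
            if not (finite and norm2 > 0.0 and np.isfinite(norm2)):
                return i
            inv = 1.0 / np.sqrt(norm2)
            for k in range(dim):
                ori[i, k] *= inv
    return -1


def n_bins(L, a):
    """Bins per side for the cell list (bin size >= interaction cutoff a)."""
    return int(L // a)


def compute_forces(pos, ori, L, a, b, e2, eps):
    """Tension V_i and its gradients for every cell.

    Dispatches to a periodic cell-list kernel when the box admits at
    least three bins of size >= a, otherwise to the all-pairs loop.
    Returns ``(V, grad_x, grad_w)`` where the gradients are with respect
    to the cell's own position and (unconstrained) orientation.
    """
    pos = np.ascontiguousarray(pos)
    ori = np.ascontiguousarray(ori)
    return _forces(pos, ori, L, n_bins(L, a), a * a, b * b, e2, eps)
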