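"""Numba kernels for the fast-iterative anisotropic eikonal solver.

The anisotropic problem |grad T|_M = 1 is reduced per element to an
isotropic unit-speed problem by mapping vertex coordinates through the
symmetric square root of the element metric.  Each local update computes the
first-arrival time at one tetrahedron vertex from the other three via the
standard plane-wave face update, with edge and vertex fallbacks when the
characteristic foot leaves the face.
"""

import numpy as np
from numba import njit

INF = np.inf


@njit(cache=True, inline="always")
def _dot(a, b):
    return a[0] * b[0] + a[1] * b[1] + a[2] * b[2]


@njit(cache=True)
def _vertex_update(p, a, ta):
    d0 = p[0] - a[0]
    d1 = p[1] - a[1]
    d2 = p[2] - a[2]
    return ta + np.sqrt(d0 * d0 + d1 * d1 + d2 * d2)


@njit(cache=True)
def _edge_update(p, a, b, ta, tb):
    """First arrival at p from a linear front on edge (a, b)."""
    u = p - a
    e = b - a
    dT = tb - ta
    A2 = _dot(e, e)
    B = _dot(e, u)
    C = _dot(u, u)
    best = INF
    aa = A2 * (A2 - dT * dT)
    bb = -2.0 * B * (A2 - dT * dT)
    cc = B * B - dT * dT * C
    if abs(aa) > 1e-14:
        disc = bb * bb - 4.0 * aa * cc
        if disc >= 0.0:
            sq = np.sqrt(disc)
            for sgn in (-1.0, 1.0):
                lam = (-bb + sgn * sq) / (2.0 * aa)
                if 0.0 < lam < 1.0:
                    w2 = C - 2.0 * B * lam + lam * lam * A2
                    if w2 > 0.0:
                        w = np.sqrt(w2)
                        # stationarity of the unsquared condition
                        if abs(dT * w - (B - lam * A2)) <= 1e-6 * (1.0 + abs(B)):
                            t = ta + lam * dT + w
                            if t < best:
                                best = t
    return best


@njit(cache=True)
def _face_update(p, a, b, c, ta, tb, tc):
    """Plane-wave update through face (a, b, c) in unit-speed coordinates."""
    e1 = b - a
    e2 = c - a
    g1 = tb - ta
    g2 = tc - ta
    g11 = _dot(e1, e1)
    g12 = _dot(e1, e2)
    g22 = _dot(e2, e2)
    det = g11 * g22 - g12 * g12
    if det <= 1e-14:
        return INF
    w1 = (g22 * g1 - g12 * g2) / det
    w2 = (g11 * g2 - g12 * g1) / det
    q = g1 * w1 + g2 * w2
    disc = 1.0 - q
    if disc < 0.0:
        return INF
    t_amp = np.sqrt(disc)
    n0 = w1 * e1 + w2 * e2
    m = np.empty(3)
    m[0] = e1[1] * e2[2] - e1[2] * e2[1]
    m[1] = e1[2] * e2[0] - e1[0] * e2[2]
    m[2] = e1[0] * e2[1] - e1[1] * e2[0]
    mn = np.sqrt(_dot(m, m))
    if mn < 1e-14:
        return INF
    m /= mn
    pa = p - a
    tmax = max(ta, max(tb, tc))
    best = INF
    for sgn in (-1.0, 1.0):
        n = n0 + sgn * t_amp * m
        tp = ta + _dot(n, pa)
        if tp < tmax:
            continue
        # characteristic foot: solve pa = lam1*e1 + lam2*e2 + tau*n
        a00, a01, a02 = e1[0], e2[0], n[0]
        a10, a11, a12 = e1[1], e2[1], n[1]
        a20, a21, a22 = e1[2], e2[2], n[2]
        d = (a00 * (a11 * a22 - a12 * a21)
             - a01 * (a10 * a22 - a12 * a20)
             + a02 * (a10 * a21 - a11 * a20))
        if abs(d) < 1e-14:
            continue
        lam1 = (pa[0] * (a11 * a22 - a12 * a21)
                - a01 * (pa[1] * a22 - a12 * pa[2])
                + a02 * (pa[1] * a21 - a11 * pa[2])) / d
        lam2 = (a00 * (pa[1] * a22 - a12 * pa[2])
                - pa[0] * (a10 * a22 - a12 * a20)
                + a02 * (a10 * pa[2] - pa[1] * a20)) / d
        tau = (a00 * (a11 * pa[2] - pa[1] * a21)
               - a01 * (a10 * pa[2] - pa[1] * a20)
               + pa[0] * (a10 * a21 - a11 * a20)) / d
        eps = 1e-9
        if tau > 0.0 and lam1 >= -eps and lam2 >= -eps and lam1 + lam2 <= 1.0 + eps:
            if tp < best:
                best = tp
    return best


@njit(cache=True)
def _local_solve(node, tet_id, Y, tets, T):
    """Minimal arrival at ``node`` through tetrahedron ``tet_id``."""
    lp = -1
    for i in range(4):
        if tets[tet_id, i] == node:
            lp = i
            break
    p = Y[tet_id, lp]
    others = np.empty(3, dtype=np.int64)
    k = 0
    for i in range(4):
        if i != lp:
            others[k] = i
            k += 1
    t_o = np.empty(3)
    for i in range(3):
        t_o[i] = T[tets[tet_id, others[i]]]

    best = INF
    for i in range(3):
        if np.isfinite(t_o[i]):
            t = _vertex_update(p, Y[tet_id, others[i]], t_o[i])
            if t < best:
                best = t
    for i in range(3):
        for j in range(i + 1, 3):
            if np.isfinite(t_o[i]) and np.isfinite(t_o[j]):
                t = _edge_update(p, Y[tet_id, others[i]], Y[tet_id, others[j]],
                                 t_o[i], t_o[j])
                if t < best:
                    best = t
    if np.isfinite(t_o[0]) and np.isfinite(t_o[1]) and np.isfinite(t_o[2]):
        t = _face_update(p, Y[tet_id, others[0]], Y[tet_id, others[1]],
                         Y[tet_id, others[2]], t_o[0], t_o[1], t_o[2])
        if t < best:
            best = t
    return best


@njit(cache=True)
def fim_solve(Y, tets, adj_off, adj_tet, T0, tol, max_pops):
    """Label-correcting worklist solver.

    Y: (M, 4, 3) metric-transformed vertex coordinates per tetrahedron.
    tets: (M, 4) vertex ids. adj_off/adj_tet: CSR node-to-tet adjacency.
    T0: initial times (finite at sources, inf elsewhere).  Returns T.
    """
    n = len(T0)
    T = T0.copy()
    in_list = np.zeros(n, dtype=np.bool_)
    queue = np.empty(n * 4, dtype=np.int64)
    head = 0
    tail = 0
    cap = len(queue)

    # seed: every node sharing a tetrahedron with a source
    for v in range(n):
        if np.isfinite(T[v]):
            for k in range(adj_off[v], adj_off[v + 1]):
                t = adj_tet[k]
                for i in range(4):
                    w = tets[t, i]
                    if not in_list[w]:
                        in_list[w] = True
                        queue[tail] = w
                        tail = (tail + 1) % cap

    pops = 0
    while head != tail and pops < max_pops:
        v = queue[head]
        head = (head + 1) % cap
        in_list[v] = False
        pops += 1

        best = INF
        for k in range(adj_off[v], adj_off[v + 1]):
            t = _local_solve(v, adj_tet[k], Y, tets, T)
            if t < best:
                best = t
        if best < T[v] - tol:
            T[v] = best
            for k in range(adj_off[v], adj_off[v + 1]):
                tt = adj_tet[k]
                for i in range(4):
                    w = tets[tt, i]
                    if w != v and not in_list[w]:
                        in_list[w] = True
                        queue[tail] = w
                        tail = (tail + 1) % cap
                        if tail == head:  # should not happen; queue sized 4n
                            return T
    return T
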