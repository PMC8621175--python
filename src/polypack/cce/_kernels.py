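"""Numba kernels for the orientation scan of the crystal-similarity norm.

At each candidate orientation the operations are grouped by symmetry
element (``elem_id``); the score of the orientation is the *largest*
per-element mean-squared mismatch, and the scan minimizes that score.
Element grouping allows early rejection of an orientation as soon as one
element already exceeds the running best.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def _euler_zyz(a, b, g, R):
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    R[0, 0] = ca * cb * cg - sa * sg
    R[0, 1] = -ca * cb * sg - sa * cg
    R[0, 2] = ca * sb
    R[1, 0] = sa * cb * cg + ca * sg
    R[1, 1] = -sa * cb * sg + ca * cg
    R[1, 2] = sa * sb
    R[2, 0] = -sb * cg
    R[2, 1] = sb * sg
    R[2, 2] = cb


@njit(cache=True, fastmath=True)
def _orientation_score(neigh, ops, elem_id, R, M, cutoff):
    """Worst per-element mean-squared mismatch at one orientation.

    Returns early with a value > ``cutoff`` as soon as any element
    exceeds it (the caller only needs scores below the running best).
    """
    k = neigh.shape[0]
    m = ops.shape[0]
    worst = 0.0
    o = 0
    while o < m:
        elem = elem_id[o]
        acc = 0.0
        cnt = 0
        while o < m and elem_id[o] == elem:
            for r in range(3):
                for c in range(3):
                    s = 0.0
                    for u in range(3):
                        for v in range(3):
                            s += R[r, u] * ops[o, u, v] * R[c, v]
                    M[r, c] = s
            for j in range(k):
                y0 = M[0, 0] * neigh[j, 0] + M[0, 1] * neigh[j, 1] + M[0, 2] * neigh[j, 2]
                y1 = M[1, 0] * neigh[j, 0] + M[1, 1] * neigh[j, 1] + M[1, 2] * neigh[j, 2]
                y2 = M[2, 0] * neigh[j, 0] + M[2, 1] * neigh[j, 1] + M[2, 2] * neigh[j, 2]
                dmin = 1e300
                for l in range(k):
                    d0 = y0 - neigh[l, 0]
                    d1 = y1 - neigh[l, 1]
                    d2 = y2 - neigh[l, 2]
                    d = d0 * d0 + d1 * d1 + d2 * d2
                    if d < dmin:
                        dmin = d
                acc += dmin
            cnt += k
            o += 1
        mean = acc / cnt
        if mean > worst:
            worst = mean
            if worst > cutoff:
                return worst
    return worst


@njit(cache=True, fastmath=True)
def scan_norm_3d(neigh, ops, elem_id, angles, early2):
    """Minimize the worst-element mismatch over candidate orientations.

    neigh : (k, 3) normalized neighbor vectors
    ops : (m, 3, 3) symmetry operations in the canonical frame
    elem_id : (m,) element index per operation (sorted, contiguous)
    angles : (n, 3) zyz Euler angle triples to evaluate
    early2 : stop as soon as the running minimum falls below this value
             (squared-norm scale); pass a negative number to disable.

    Returns (best score, index of best angle triple).
    """
    R = np.empty((3, 3))
    M = np.empty((3, 3))
    best = 1e300
    besti = -1
    for t in range(angles.shape[0]):
        _euler_zyz(angles[t, 0], angles[t, 1], angles[t, 2], R)
        score = _orientation_score(neigh, ops, elem_id, R, M, best)
        if score < best:
            best = score
            besti = t
            if early2 >= 0.0 and best <= early2:
                return best, besti
    return best, besti


@njit(cache=True, fastmath=True)
def scan_norm_3d_topk(neigh, ops, elem_id, angles, kbest):
    """Like :func:`scan_norm_3d` but tracks the ``kbest`` best orientations."""
    R = np.empty((3, 3))
    M = np.empty((3, 3))
    vals = np.full(kbest, 1e300)
    idxs = np.full(kbest, -1, dtype=np.int64)
    for t in range(angles.shape[0]):
        _euler_zyz(angles[t, 0], angles[t, 1], angles[t, 2], R)
        score = _orientation_score(neigh, ops, elem_id, R, M, vals[kbest - 1])
        if score < vals[kbest - 1]:
            pos = kbest - 1
            while pos > 0 and vals[pos - 1] > score:
                vals[pos] = vals[pos - 1]
                idxs[pos] = idxs[pos - 1]
                pos -= 1
            vals[pos] = score
            idxs[pos] = t
    return vals, idxs


@njit(cache=True, fastmath=True)
def scan_norm_2d(neigh, ops, elem_id, angles, early2):
    """2-D analog of :func:`scan_norm_3d`; orientation is a single angle.

    Proper 2-D rotations commute, so a single angle (typically just 0)
    suffices; the element grouping matches the 3-D convention.
    """
    k = neigh.shape[0]
    m = ops.shape[0]
    best = 1e300
    besti = -1
    for t in range(angles.shape[0]):
        ca, sa = np.cos(angles[t]), np.sin(angles[t])
        worst = 0.0
        o = 0
        while o < m:
            elem = elem_id[o]
            acc = 0.0
            cnt = 0
            while o < m and elem_id[o] == elem:
                a00 = ca * ops[o, 0, 0] - sa * ops[o, 1, 0]
                a01 = ca * ops[o, 0, 1] - sa * ops[o, 1, 1]
                a10 = sa * ops[o, 0, 0] + ca * ops[o, 1, 0]
                a11 = sa * ops[o, 0, 1] + ca * ops[o, 1, 1]
                m00 = a00 * ca - a01 * sa
                m01 = a00 * sa + a01 * ca
                m10 = a10 * ca - a11 * sa
                m11 = a10 * sa + a11 * ca
                for j in range(k):
                    y0 = m00 * neigh[j, 0] + m01 * neigh[j, 1]
                    y1 = m10 * neigh[j, 0] + m11 * neigh[j, 1]
                    dmin = 1e300
                    for l in range(k):
                        d0 = y0 - neigh[l, 0]
                        d1 = y1 - neigh[l, 1]
                        d = d0 * d0 + d1 * d1
                        if d < dmin:
                            dmin = d
                    acc += dmin
                cnt += k
                o += 1
            mean = acc / cnt
            if mean > worst:
                worst = mean
        if worst < best:
            best = worst
            besti = t
            if early2 >= 0.0 and best <= early2:
                return best, besti
    return best, besti
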