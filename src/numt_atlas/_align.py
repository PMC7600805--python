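"""Low-level alignment kernels (numba-compiled).

Sequences are handled as uint8 code arrays: A=0, C=1, G=2, T=3, N=4.
Scores are integers; gap costs are passed as positive magnitudes, so a gap of
length L scores -(gap_open + gap_extend * L). An N in either sequence scores
as a mismatch, which means a run of >=10 Ns exceeds the default x-drop of 20
and terminates extension on its own.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

NEG = np.int64(-(10**15))


def encode(seq: str) -> np.ndarray:
    """Map a DNA string to uint8 codes; anything outside ACGT becomes N."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_LETTERS = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


@njit(cache=True)
def xdrop_extend(a, b, match, mismatch, gap_open, gap_extend, xdrop):  # pragma: no cover
    """Affine-gap x-drop extension of a local alignment anchored at (0, 0).

    Extends over prefixes of ``a`` and ``b``; cells whose best score falls
    more than ``xdrop`` below the running maximum are pruned.  Returns
    ``(best_score, a_consumed, b_consumed)`` for the best match-ending cell.
    """
    la = a.shape[0]
    lb = b.shape[0]
    best = np.int64(0)
    besti = 0
    bestj = 0
    if la == 0 or lb == 0:
        return best, besti, bestj

    width = la + 1
    M_prev = np.empty(width, dtype=np.int64)
    Ix_prev = np.empty(width, dtype=np.int64)
    Iy_prev = np.empty(width, dtype=np.int64)
    M_cur = np.empty(width, dtype=np.int64)
    Ix_cur = np.empty(width, dtype=np.int64)
    Iy_cur = np.empty(width, dtype=np.int64)

    # row 0: only horizontal gaps from the anchor
    M_prev[0] = 0
    Ix_prev[0] = NEG
    Iy_prev[0] = NEG
    phi = 0
    for i in range(1, la + 1):
        g = -np.int64(gap_open + gap_extend * i)
        if g < best - xdrop:
            break
        M_prev[i] = NEG
        Ix_prev[i] = g
        Iy_prev[i] = NEG
        phi = i
    plo = 0

    for j in range(1, lb + 1):
        first_alive = -1
        last_alive = -1
        i = plo
        while i <= la:
            # diagonal predecessor (j-1, i-1)
            if i - 1 >= plo and i - 1 <= phi:
                d = M_prev[i - 1]
                if Ix_prev[i - 1] > d:
                    d = Ix_prev[i - 1]
                if Iy_prev[i - 1] > d:
                    d = Iy_prev[i - 1]
            else:
                d = NEG
            if d <= NEG:
                m = NEG
            else:
                if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                    m = d + match
                else:
                    m = d + mismatch
            # horizontal: gap in b, consumes a[i-1]; from current row i-1
            if i - 1 >= plo and i >= 1 and i - 1 <= (last_alive if last_alive >= 0 else -1):
                ix = M_cur[i - 1] - (gap_open + gap_extend)
                t = Ix_cur[i - 1] - gap_extend
                if t > ix:
                    ix = t
            else:
                ix = NEG
            # vertical: gap in a, from (j-1, i)
            if i >= plo and i <= phi:
                iy = M_prev[i] - (gap_open + gap_extend)
                t = Iy_prev[i] - gap_extend
                if t > iy:
                    iy = t
            else:
                iy = NEG

            v = m
            if ix > v:
                v = ix
            if iy > v:
                v = iy
            if v < best - xdrop:
                M_cur[i] = NEG
                Ix_cur[i] = NEG
                Iy_cur[i] = NEG
                if first_alive >= 0 and i > phi + 1:
                    break
            else:
                M_cur[i] = m
                Ix_cur[i] = ix
                Iy_cur[i] = iy
                if first_alive < 0:
                    first_alive = i
                last_alive = i
                if m > best:
                    best = m
                    besti = i
                    bestj = j
            i += 1
        if first_alive < 0:
            break
        plo = first_alive
        phi = last_alive
        M_prev, M_cur = M_cur, M_prev
        Ix_prev, Ix_cur = Ix_cur, Ix_prev
        Iy_prev, Iy_cur = Iy_cur, Iy_prev
    return best, besti, bestj


@njit(cache=True)
def sw_local(a, b, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Full affine-gap Smith-Waterman with traceback.

    Returns ``(score, matches, mismatches, gap_cols, a0, a1, b0, b1)`` for
    the best local alignment (0-based half-open ranges in each sequence).
    Score 0 means no positive-scoring alignment exists.
    """
    la = a.shape[0]
    lb = b.shape[0]
    BAD = np.int32(-(10**9))
    Mp = np.zeros(la + 1, dtype=np.int32)
    Ixp = np.full(la + 1, BAD, dtype=np.int32)
    Iyp = np.full(la + 1, BAD, dtype=np.int32)
    Mc = np.zeros(la + 1, dtype=np.int32)
    Ixc = np.full(la + 1, BAD, dtype=np.int32)
    Iyc = np.full(la + 1, BAD, dtype=np.int32)
    # M pointers: 0 = fresh start, 1 = from M, 2 = from Ix, 3 = from Iy
    pM = np.zeros((lb + 1, la + 1), dtype=np.int8)
    pIx = np.zeros((lb + 1, la + 1), dtype=np.int8)  # 0 = open, 1 = extend
    pIy = np.zeros((lb + 1, la + 1), dtype=np.int8)
    best = np.int32(0)
    bi = 0
    bj = 0
    for j in range(1, lb + 1):
        Mc[0] = 0
        Ixc[0] = BAD
        Iyc[0] = BAD
        bc = b[j - 1]
        for i in range(1, la + 1):
            if a[i - 1] == bc and a[i - 1] < 4:
                s = match
            else:
                s = mismatch
            d = Mp[i - 1]
            pk = 1
            if Ixp[i - 1] > d:
                d = Ixp[i - 1]
                pk = 2
            if Iyp[i - 1] > d:
                d = Iyp[i - 1]
                pk = 3
            # prefer a fresh start whenever the best predecessor is <= 0:
            # same score, minimal path, so the traceback decomposition is exact
            if d <= 0:
                d = 0
                pk = 0
            m = d + s
            if m < 0:
                m = 0
                pk = 0
            Mc[i] = m
            pM[j, i] = pk
            o = Mc[i - 1] - (gap_open + gap_extend)
            e = Ixc[i - 1] - gap_extend
            if o >= e:
                Ixc[i] = o
                pIx[j, i] = 0
            else:
                Ixc[i] = e
                pIx[j, i] = 1
            o = Mp[i] - (gap_open + gap_extend)
            e = Iyp[i] - gap_extend
            if o >= e:
                Iyc[i] = o
                pIy[j, i] = 0
            else:
                Iyc[i] = e
                pIy[j, i] = 1
            if m > best:
                best = m
                bi = i
                bj = j
        Mp, Mc = Mc, Mp
        Ixp, Ixc = Ixc, Ixp
        Iyp, Iyc = Iyc, Iyp
    matches = 0
    mismatches = 0
    gap_cols = 0
    i = bi
    j = bj
    k = 0  # in M
    while i > 0 and j > 0:
        if k == 0:
            pk = pM[j, i]
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
            if pk == 0:
                break
            k = 0 if pk == 1 else (1 if pk == 2 else 2)
        elif k == 1:
            pk = pIx[j, i]
            gap_cols += 1
            i -= 1
            k = 0 if pk == 0 else 1
        else:
            pk = pIy[j, i]
            gap_cols += 1
            j -= 1
            k = 0 if pk == 0 else 2
    return best, matches, mismatches, gap_cols, i, bi, j, bj


@njit(cache=True)
def banded_global_stats(a, b, match, mismatch, gap_open, gap_extend, pad):  # pragma: no cover
    """Banded affine global alignment of ``a`` vs ``b`` with traceback.

    The band covers diagonals ``d = i - j`` between ``min(0, la-lb) - pad``
    and ``max(0, la-lb) + pad``.  Returns
    ``(score, matches, mismatches, gap_cols, dmin, dmax)`` where dmin/dmax
    bound the diagonals traversed by the optimal path.
    """
    la = a.shape[0]
    lb = b.shape[0]
    dlo = min(0, la - lb) - pad
    dhi = max(0, la - lb) + pad
    W = dhi - dlo + 1

    M = np.full((lb + 1, W), NEG, dtype=np.int64)
    Ix = np.full((lb + 1, W), NEG, dtype=np.int64)
    Iy = np.full((lb + 1, W), NEG, dtype=np.int64)
    # pointers: for M, which matrix the diagonal step came from (0/1/2);
    # for Ix/Iy, 0 = opened from M, 1 = extension
    pM = np.zeros((lb + 1, W), dtype=np.int8)
    pIx = np.zeros((lb + 1, W), dtype=np.int8)
    pIy = np.zeros((lb + 1, W), dtype=np.int8)

    # cell (j, i) stored at column i - j - dlo
    M[0, -dlo] = 0
    for j in range(0, lb + 1):
        ilo = max(0, j + dlo)
        ihi = min(la, j + dhi)
        for i in range(ilo, ihi + 1):
            c = i - j - dlo
            if i == 0 and j == 0:
                continue
            # M: diagonal from (j-1, i-1), same band column c
            if i >= 1 and j >= 1:
                pm = M[j - 1, c]
                pk = 0
                if Ix[j - 1, c] > pm:
                    pm = Ix[j - 1, c]
                    pk = 1
                if Iy[j - 1, c] > pm:
                    pm = Iy[j - 1, c]
                    pk = 2
                if pm > NEG:
                    if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                        M[j, c] = pm + match
                    else:
                        M[j, c] = pm + mismatch
                    pM[j, c] = pk
            # Ix: gap in b (consume a[i-1]) from (j, i-1) = column c-1
            if i >= 1 and c - 1 >= 0:
                op = M[j, c - 1]
                ex = Ix[j, c - 1]
                if op > NEG or ex > NEG:
                    o = op - (gap_open + gap_extend)
                    e = ex - gap_extend
                    if o >= e:
                        Ix[j, c] = o
                        pIx[j, c] = 0
                    else:
                        Ix[j, c] = e
                        pIx[j, c] = 1
            # Iy: gap in a (consume b[j-1]) from (j-1, i) = column c+1
            if j >= 1 and c + 1 < W:
                op = M[j - 1, c + 1]
                ex = Iy[j - 1, c + 1]
                if op > NEG or ex > NEG:
                    o = op - (gap_open + gap_extend)
                    e = ex - gap_extend
                    if o >= e:
                        Iy[j, c] = o
                        pIy[j, c] = 0
                    else:
                        Iy[j, c] = e
                        pIy[j, c] = 1

    cend = la - lb - dlo
    score = M[lb, cend]
    k = 0
    if Ix[lb, cend] > score:
        score = Ix[lb, cend]
        k = 1
    if Iy[lb, cend] > score:
        score = Iy[lb, cend]
        k = 2

    matches = 0
    mismatches = 0
    gap_cols = 0
    dmin = la - lb
    dmax = la - lb
    i = la
    j = lb
    while i > 0 or j > 0:
        d = i - j
        if d < dmin:
            dmin = d
        if d > dmax:
            dmax = d
        c = i - j - dlo
        if k == 0:
            nk = pM[j, c]
            if a[i - 1] == b[j - 1] and a[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
            k = nk
        elif k == 1:
            nk = 0 if pIx[j, c] == 0 else 1
            gap_cols += 1
            i -= 1
            k = nk
        else:
            nk = 0 if pIy[j, c] == 0 else 2
            gap_cols += 1
            j -= 1
            k = nk
    return score, matches, mismatches, gap_cols, dmin, dmax
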