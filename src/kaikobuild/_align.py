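"""Numba alignment kernels.

Two dynamic programs live here:

* a plain Smith-Waterman local alignment with linear gaps, used by the EST
  identity-linkage rule and by duplication screening;
* a four-state splice-aware local alignment (match, target gap, query gap,
  intron) in the est2genome tradition: the intron state consumes genome
  only, entry jumps ``min_intron`` columns at once (so the minimum intron
  length is enforced exactly), and a GT..AG bonus is split between donor
  and acceptor.

Both kernels fill int8 pointer matrices and trace back inside numba,
returning op codes; callers derive blocks and statistics.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# op codes shared by both tracebacks
OP_MATCH = 0
OP_MISMATCH = 1
OP_GAP_Q = 2     # consumes target only (deletion from query)
OP_GAP_T = 3     # consumes query only (insertion in query)
OP_INTRON = 4    # consumes target only, intron state

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for i, b in enumerate(b"ACGT"):
    _BASE_CODE[b] = i


def encode(seq: str) -> np.ndarray:
    """A=0 C=1 G=2 T=3; anything else becomes -1 and matches nothing."""
    return _BASE_CODE[np.frombuffer(seq.upper().encode(), dtype=np.uint8)]


@njit(cache=True)
def sw_align(q, t, match, mismatch, gap):  # pragma: no cover - numba
    """Smith-Waterman with linear gap cost; returns the best local path.

    Returns (score, q_start, q_end, t_start, t_end, ops), spans 0-based
    half-open on query/target.
    """
    m, n = len(q), len(t)
    H = np.zeros((m + 1, n + 1), dtype=np.float32)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 left, 3 up
    best = np.float32(0.0)
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        qa = q[i - 1]
        for j in range(1, n + 1):
            ta = t[j - 1]
            s = match if (qa == ta and qa >= 0) else mismatch
            v = H[i - 1, j - 1] + s
            p = np.int8(1)
            if H[i, j - 1] + gap > v:
                v = H[i, j - 1] + gap
                p = 2
            if H[i - 1, j] + gap > v:
                v = H[i - 1, j] + gap
                p = 3
            if v <= 0.0:
                v = np.float32(0.0)
                p = 0
            H[i, j] = v
            ptr[i, j] = p
            if v > best:
                best = v
                bi = i
                bj = j
    ops = np.empty(m + n, dtype=np.int8)
    k = 0
    i, j = bi, bj
    while i > 0 and j > 0 and ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            qa = q[i - 1]
            ops[k] = OP_MATCH if (qa == t[j - 1] and qa >= 0) else OP_MISMATCH
            i -= 1
            j -= 1
        elif p == 2:
            ops[k] = OP_GAP_Q
            j -= 1
        else:
            ops[k] = OP_GAP_T
            i -= 1
        k += 1
    return best, i, bi, j, bj, ops[:k][::-1].copy()


@njit(cache=True)
def splice_align_kernel(
    q, t, match, mismatch, gap_open, gap_ext,
    intron_open, intron_ext, splice_bonus, min_intron,
):  # pragma: no cover - numba
    """Local splice-aware DP.

    Returns (score, q_start, q_end, t_start, t_end, ops) with 0-based
    half-open query/target spans of the best local alignment.
    """
    m, n = len(q), len(t)
    NEG = -1e9
    half = splice_bonus / 2.0

    # acceptor bonus usable at M[i][j] coming from intron: t[j-3..j-2] == AG
    # donor bonus at intron entry ending column j: t[j0..j0+1] == GT
    acc_bonus = np.zeros(n + 1, dtype=np.float64)
    for j in range(3, n + 1):
        if t[j - 3] == 0 and t[j - 2] == 2:
            acc_bonus[j] = half
    don_bonus = np.zeros(n + 1, dtype=np.float64)
    for j in range(min_intron + 1, n + 1):
        j0 = j - min_intron
        if j0 + 1 < n and t[j0] == 2 and t[j0 + 1] == 3:
            don_bonus[j] = half

    Mp = np.full(n + 1, NEG, dtype=np.float64)
    Mc = np.full(n + 1, NEG, dtype=np.float64)
    Xp = np.full(n + 1, NEG, dtype=np.float64)
    Xc = np.full(n + 1, NEG, dtype=np.float64)
    Yp = np.full(n + 1, NEG, dtype=np.float64)
    Yc = np.full(n + 1, NEG, dtype=np.float64)
    Ip = np.full(n + 1, NEG, dtype=np.float64)
    Ic = np.full(n + 1, NEG, dtype=np.float64)

    # packed pointers: bits 0-2 = M predecessor (0 start, 1 M, 2 X, 3 Y, 4 I)
    # bit 3 = X extends, bit 4 = Y extends, bit 5 = I extends
    ptr = np.zeros((m + 1, n + 1), dtype=np.uint8)

    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        Mc[0] = NEG
        Xc[0] = NEG
        Yc[0] = NEG
        Ic[0] = NEG
        qa = q[i - 1]
        for j in range(1, n + 1):
            s = match if (qa == t[j - 1] and qa >= 0) else mismatch

            # M: diagonal step from any state at (i-1, j-1), or local start
            v = 0.0
            p = 0
            if Mp[j - 1] > v:
                v = Mp[j - 1]
                p = 1
            if Xp[j - 1] > v:
                v = Xp[j - 1]
                p = 2
            if Yp[j - 1] > v:
                v = Yp[j - 1]
                p = 3
            iacc = Ip[j - 1] + acc_bonus[j]
            if iacc > v:
                v = iacc
                p = 4
            mv = v + s
            Mc[j] = mv

            # X: gap consuming target (same row, horizontal)
            xv = Mc[j - 1] - gap_open
            code = p
            if Xc[j - 1] - gap_ext > xv:
                xv = Xc[j - 1] - gap_ext
                code |= 8
            Xc[j] = xv

            # Y: gap consuming query (vertical)
            yv = Mp[j] - gap_open
            if Yp[j] - gap_ext > yv:
                yv = Yp[j] - gap_ext
                code |= 16
            Yc[j] = yv

            # I: intron, consumes target only; entry jumps min_intron cols
            iv = Ic[j - 1] - intron_ext
            ienter = False
            if j > min_intron:
                ev = Mc[j - min_intron] - intron_open + don_bonus[j]
                if ev > iv:
                    iv = ev
                    ienter = True
            if not ienter:
                code |= 32
            Ic[j] = iv
            ptr[i, j] = code

            if mv > best:
                best = mv
                bi = i
                bj = j
        Mp, Mc = Mc, Mp
        Xp, Xc = Xc, Xp
        Yp, Yc = Yc, Yp
        Ip, Ic = Ic, Ip

    # traceback (path length bounded by m + n + introns re-emitted in jumps)
    ops = np.empty(2 * (m + n) + 8, dtype=np.int8)
    k = 0
    i, j = bi, bj
    state = 1  # M
    while i > 0 and j > 0:
        code = ptr[i, j]
        if state == 1:
            p = code & 7
            qa = q[i - 1]
            ops[k] = OP_MATCH if (qa == t[j - 1] and qa >= 0) else OP_MISMATCH
            k += 1
            i -= 1
            j -= 1
            if p == 0:
                break
            state = p
        elif state == 2:
            ops[k] = OP_GAP_Q
            k += 1
            j -= 1
            state = 2 if code & 8 else 1
        elif state == 3:
            ops[k] = OP_GAP_T
            k += 1
            i -= 1
            state = 3 if code & 16 else 1
        else:  # intron
            if code & 32:
                ops[k] = OP_INTRON
                k += 1
                j -= 1
            else:  # entry: account for the min_intron-column jump
                for _ in range(min_intron):
                    ops[k] = OP_INTRON
                    k += 1
                j -= min_intron
                state = 1
    return best, i, bi, j, bj, ops[:k][::-1].copy()
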