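"""Affine-gap alignment kernels (Gotoh three-state DP), numba-compiled.

One kernel serves three modes:

* ``LOCAL`` (0)      — Smith–Waterman; score clamped at zero.
* ``GLOBAL`` (1)     — Needleman–Wunsch; terminal gaps penalised.
* ``SEMIGLOBAL`` (2) — end-gap-free: alignment may start on either
  sequence's first row/column and end on a last row/column for free.

Tie-breaks are fixed so traceback is deterministic: at equal score the
diagonal move wins over the vertical ("up", consuming sequence *a*) which
wins over the horizontal ("left", consuming *b*); among equal-scoring end
cells the one reached first in row-major scan order wins.

A gap of length L costs ``gap_open + L * gap_extend``.
"""

import numpy as np
from numba import njit

LOCAL = 0
GLOBAL = 1
SEMIGLOBAL = 2

# op codes on the traceback path
OP_DIAG = 0  # consume one symbol of a and one of b
OP_UP = 1    # consume one symbol of a (gap in b)
OP_LEFT = 2  # consume one symbol of b (gap in a)

_NEG = -(10 ** 9)


@njit(cache=True)
def align_kernel(a, b, sub, gap_open, gap_extend, mode):
    """Align integer-encoded sequences.

    Returns (score, a_start, a_end, b_start, b_end, ops, n_ops) where
    ops[:n_ops] is the path in OP_* codes from (a_start, b_start).
    """
    m = a.shape[0]
    n = b.shape[0]
    go = gap_open + gap_extend  # cost of the first residue of a gap
    ge = gap_extend

    M = np.full((m + 1, n + 1), _NEG, np.int64)
    Ix = np.full((m + 1, n + 1), _NEG, np.int64)  # gap in b, vertical
    Iy = np.full((m + 1, n + 1), _NEG, np.int64)  # gap in a, horizontal
    # pointers: state entered from (0=M, 1=Ix, 2=Iy, 3=fresh start)
    pM = np.zeros((m + 1, n + 1), np.int8)
    pX = np.zeros((m + 1, n + 1), np.int8)
    pY = np.zeros((m + 1, n + 1), np.int8)

    M[0, 0] = 0
    pM[0, 0] = 3
    if mode == GLOBAL:
        for i in range(1, m + 1):
            Ix[i, 0] = -(go + (i - 1) * ge)
            pX[i, 0] = 1 if i > 1 else 0
        for j in range(1, n + 1):
            Iy[0, j] = -(go + (j - 1) * ge)
            pY[0, j] = 2 if j > 1 else 0
    else:
        for i in range(1, m + 1):
            M[i, 0] = 0
            pM[i, 0] = 3
        for j in range(1, n + 1):
            M[0, j] = 0
            pM[0, j] = 3

    best = 0 if mode == LOCAL else _NEG
    bi = 0
    bj = 0
    bstate = 0

    for i in range(1, m + 1):
        ai = a[i - 1]
        for j in range(1, n + 1):
            s = sub[ai, b[j - 1]]
            # --- M: diagonal entry; prefer M > Ix > Iy among prior states
            prev = M[i - 1, j - 1]
            ptr = 0
            if Ix[i - 1, j - 1] > prev:
                prev = Ix[i - 1, j - 1]
                ptr = 1
            if Iy[i - 1, j - 1] > prev:
                prev = Iy[i - 1, j - 1]
                ptr = 2
            if mode == LOCAL and prev < 0:
                # fresh start: the optimal local path never has a
                # negative-scoring prefix, so starting here dominates
                prev = 0
                ptr = 3
            v = prev + s
            M[i, j] = v
            pM[i, j] = ptr

            # --- Ix: vertical, consume a[i-1]
            vx = M[i - 1, j] - go
            px = 0
            if Ix[i - 1, j] - ge > vx:
                vx = Ix[i - 1, j] - ge
                px = 1
            if Iy[i - 1, j] - go > vx:
                vx = Iy[i - 1, j] - go
                px = 2
            Ix[i, j] = vx
            pX[i, j] = px

            # --- Iy: horizontal, consume b[j-1]
            vy = M[i, j - 1] - go
            py = 0
            if Ix[i, j - 1] - go > vy:
                vy = Ix[i, j - 1] - go
                py = 1
            if Iy[i, j - 1] - ge > vy:
                vy = Iy[i, j - 1] - ge
                py = 2
            Iy[i, j] = vy
            pY[i, j] = py

            if mode == LOCAL:
                if M[i, j] > best:
                    best = M[i, j]
                    bi = i
                    bj = j
                    bstate = 0

    if mode == GLOBAL:
        best = M[m, n]
        bstate = 0
        if Ix[m, n] > best:
            best = Ix[m, n]
            bstate = 1
        if Iy[m, n] > best:
            best = Iy[m, n]
            bstate = 2
        bi = m
        bj = n
    elif mode == SEMIGLOBAL:
        # best over last row and last column, any state, row-major priority
        for j in range(0, n + 1):
            for st in range(3):
                v = M[m, j] if st == 0 else (Ix[m, j] if st == 1 else Iy[m, j])
                if v > best:
                    best = v
                    bi = m
                    bj = j
                    bstate = st
        for i in range(0, m + 1):
            for st in range(3):
                v = M[i, n] if st == 0 else (Ix[i, n] if st == 1 else Iy[i, n])
                if v > best:
                    best = v
                    bi = i
                    bj = n
                    bstate = st

    ops = np.empty(m + n, np.int8)
    k = m + n  # fill backwards
    i = bi
    j = bj
    state = bstate
    if mode == LOCAL and best <= 0:
        return 0, 0, 0, 0, 0, ops, 0

    while True:
        if i == 0 and j == 0:
            break
        if mode != GLOBAL and (i == 0 or j == 0) and state == 0 and pM[i, j] == 3:
            break
        if state == 0:
            ptr = pM[i, j]
            k -= 1
            ops[k] = OP_DIAG
            i -= 1
            j -= 1
            if ptr == 3:
                break
            state = ptr
        elif state == 1:
            ptr = pX[i, j]
            k -= 1
            ops[k] = OP_UP
            i -= 1
            state = ptr
        else:
            ptr = pY[i, j]
            k -= 1
            ops[k] = OP_LEFT
            j -= 1
            state = ptr

    n_ops = m + n - k
    out = np.empty(n_ops, np.int8)
    for t in range(n_ops):
        out[t] = ops[k + t]
    return best, i, bi, j, bj, out, n_ops


@njit(cache=True)
def ungapped_extend(a, b, qpos, spos, k, sub, xdrop):
    """X-drop ungapped extension of an exact k-mer seed.

    Returns (score, q0, q1, s0, s1): the best-scoring gapless extension
    of the seed at a[qpos:qpos+k] == b[spos:spos+k], half-open coords.
    """
    m = a.shape[0]
    n = b.shape[0]
    score = 0
    for t in range(k):
        score += sub[a[qpos + t], b[spos + t]]

    # extend right
    best = score
    q1 = qpos + k
    s1 = spos + k
    run = score
    i = qpos + k
    j = spos + k
    while i < m and j < n:
        run += sub[a[i], b[j]]
        i += 1
        j += 1
        if run > best:
            best = run
            q1 = i
            s1 = j
        elif best - run > xdrop:
            break

    # extend left
    score = best
    q0 = qpos
    s0 = spos
    run = best
    i = qpos - 1
    j = spos - 1
    while i >= 0 and j >= 0:
        run += sub[a[i], b[j]]
        if run > score:
            score = run
            q0 = i
            s0 = j
        elif score - run > xdrop:
            break
        i -= 1
        j -= 1

    return score, q0, q1, s0, s1
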