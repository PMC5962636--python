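"""Numba kernels: banded affine local alignment and pileup accumulation.

Scoring convention (shared with the test oracle): match +1, mismatch -2,
and a gap of length n costs 5 + 2*(n-1) (open -5 charged on the first
gapped base, extension -2 on each further base).  N (code 4) mismatches
every base, including another N.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -2
GAP_OPEN = -5  # cost of the first base of a gap
GAP_EXT = -2

NEG = np.int32(-(10**8))


@njit(cache=True)
def sw_banded(q, s, dlo, dhi):
    """Local affine-gap alignment of q vs s restricted to diagonals
    d = j - i in [dlo, dhi] (0-based; full matrix when dlo=-len(q),
    dhi=len(s)).

    Returns (score, qstart, qend, sstart, send, n_match, aln_len),
    intervals 0-based half-open.  Ties for the best cell resolve to the
    smallest (i, then j); traceback prefers diagonal, then subject gap,
    then query gap.
    """
    n = len(q)
    m = len(s)
    B = dhi - dlo + 1
    H_prev = np.full(B + 2, NEG, np.int32)
    H_cur = np.full(B + 2, NEG, np.int32)
    F_prev = np.full(B + 2, NEG, np.int32)
    F_cur = np.full(B + 2, NEG, np.int32)
    ptr = np.zeros((n + 1, B), np.uint8)   # 0 stop, 1 diag, 2 E(left), 3 F(up)
    eptr = np.zeros((n + 1, B), np.uint8)  # 1 = E opened from H
    fptr = np.zeros((n + 1, B), np.uint8)  # 1 = F opened from H

    # row 0: empty query prefix; H=0 on valid cells (local start anywhere)
    for k in range(B):
        j = 0 + dlo + k
        if 0 <= j <= m:
            H_prev[k + 1] = 0

    best = np.int32(0)
    bi = 0
    bk = 0
    for i in range(1, n + 1):
        qc = q[i - 1]
        E = NEG
        for k in range(B):
            j = i + dlo + k
            if j < 0 or j > m:
                H_cur[k + 1] = NEG
                F_cur[k + 1] = NEG
                continue
            if j == 0:
                H_cur[k + 1] = 0
                F_cur[k + 1] = NEG
                E = NEG
                continue
            sc = s[j - 1]
            sub = MATCH if (qc == sc and qc < 4) else MISMATCH
            # E: gap consuming subject (left neighbour, same row, k-1)
            e_open = H_cur[k] + GAP_OPEN
            e_ext = E + GAP_EXT
            E = e_open if e_open >= e_ext else e_ext
            eopened = 1 if e_open >= e_ext else 0
            # F: gap consuming query (up neighbour, prev row, k+1)
            f_open = H_prev[k + 2] + GAP_OPEN
            f_ext = F_prev[k + 2] + GAP_EXT
            F = f_open if f_open >= f_ext else f_ext
            fopened = 1 if f_open >= f_ext else 0
            F_cur[k + 1] = F
            diag = H_prev[k + 1] + sub
            h = np.int32(0)
            p = np.uint8(0)
            if diag > h:
                h = diag
                p = np.uint8(1)
            if E > h:
                h = E
                p = np.uint8(2)
            if F > h:
                h = F
                p = np.uint8(3)
            H_cur[k + 1] = h
            ptr[i, k] = p
            eptr[i, k] = eopened
            fptr[i, k] = fopened
            if h > best:
                best = h
                bi = i
                bk = k
        tmp = H_prev
        H_prev = H_cur
        H_cur = tmp
        tmp = F_prev
        F_prev = F_cur
        F_cur = tmp

    if best <= 0:
        return 0, 0, 0, 0, 0, 0, 0

    # traceback
    i = bi
    k = bk
    qe = bi
    se = bi + dlo + bk
    n_match = 0
    aln_len = 0
    state = 0  # 0 = in H, 2 = in E, 3 = in F
    while True:
        j = i + dlo + k
        if state == 0:
            p = ptr[i, k]
            if p == 0:
                break
            if p == 1:
                if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                    n_match += 1
                aln_len += 1
                i -= 1
                # diag keeps k (j-i stays)
            elif p == 2:
                state = 2
            else:
                state = 3
        elif state == 2:
            # consume one subject base (gap in query)
            aln_len += 1
            opened = eptr[i, k]
            k -= 1
            if opened == 1:
                state = 0
        else:
            # consume one query base (gap in subject)
            aln_len += 1
            opened = fptr[i, k]
            i -= 1
            k += 1
            if opened == 1:
                state = 0
        if i == 0:
            break
    qs = i
    ss = i + dlo + k
    return int(best), qs, qe, ss, se, n_match, aln_len


# pileup op codes (package-local, independent of edlib's cigar letters):
# 0 = match/mismatch (consumes target + evidence)
# 1 = deletion: target base absent from evidence (consumes target)
# 2 = insertion: evidence base absent from target (consumes evidence)
OP_M = 0
OP_DEL = 1
OP_INS = 2


@njit(cache=True)
def add_alignment(votes, ins_count, ins_base, ops, lens, ev, t0):
    """Accumulate one evidence alignment into a pileup over the target.

    votes: (L, 5) int32 columns [A, C, G, T, deletion];
    ins_count: (L+1,) insertion events before target position t;
    ins_base: (L+1, 4) votes for the first inserted base.
    """
    t = t0
    e = 0
    for x in range(len(ops)):
        op = ops[x]
        ln = lens[x]
        if op == OP_M:
            for _ in range(ln):
                b = ev[e]
                if b < 4:
                    votes[t, b] += 1
                t += 1
                e += 1
        elif op == OP_DEL:
            for _ in range(ln):
                votes[t, 4] += 1
                t += 1
        else:
            ins_count[t] += 1
            b = ev[e]
            if b < 4:
                ins_base[t, b] += 1
            e += ln


@njit(cache=True)
def correct_from_pileup(orig, votes, ins_count, ins_base):
    """Majority-vote consensus of a pileup over the original read.

    Ties keep the original base (a base whose column majority agrees with
    the original is never changed).  An insertion is emitted when more
    than half of the covering alignments support one, taking the modal
    first base.  Returns (corrected codes, per-base support = column
    depth, kept mask length bookkeeping).
    """
    L = len(orig)
    out = np.empty(L * 2 + 16, np.uint8)
    sup = np.empty(L * 2 + 16, np.int32)
    w = 0
    for t in range(L + 1):
        depth_here = 0
        if t < L:
            for b in range(5):
                depth_here += votes[t, b]
        else:
            for b in range(5):
                depth_here += votes[t - 1, b]
        if ins_count[t] * 2 > depth_here and depth_here > 0:
            bb = 0
            bv = -1
            for b in range(4):
                if ins_base[t, b] > bv:
                    bv = ins_base[t, b]
                    bb = b
            out[w] = bb
            sup[w] = ins_count[t]
            w += 1
        if t == L:
            break
        depth = 0
        for b in range(5):
            depth += votes[t, b]
        ob = orig[t]
        best_b = ob
        best_v = votes[t, ob] if ob < 4 else -1
        for b in range(5):
            if votes[t, b] > best_v:
                best_v = votes[t, b]
                best_b = b
        if best_b < 4:
            out[w] = best_b
            sup[w] = depth
            w += 1
        # best_b == 4: deletion wins, base dropped
    return out[:w], sup[:w]


@njit(cache=True)
def depth_error_accumulate(depth, errs, ops, lens, ev, t0, tseq):
    """Per-reference-position depth and error-event counts for one read."""
    t = t0
    e = 0
    for x in range(len(ops)):
        op = ops[x]
        ln = lens[x]
        if op == OP_M:
            for _ in range(ln):
                depth[t] += 1
                if ev[e] != tseq[t] or ev[e] >= 4:
                    errs[t] += 1
                t += 1
                e += 1
        elif op == OP_DEL:
            for _ in range(ln):
                depth[t] += 1
                errs[t] += 1
                t += 1
        else:
            if t < len(errs):
                errs[t] += ln
            e += ln
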