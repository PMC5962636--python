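"""Independent oracles for the test suite.

Everything here is deliberately implemented from scratch (plain dynamic
programming, numba-compiled for speed) so that it shares no code with
the package's alignment backends: edit distances are computed by
textbook DP rather than edlib, and optimal local alignment scores come
from biotite.  Brute-force re-implementations of the adapter-removal
and clustering rules use these DPs with the same documented tie-break
rules as the package.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from walkseq.io import revcomp

_CODE = np.full(256, 4, np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def enc(s: str) -> np.ndarray:
    return _CODE[np.frombuffer(s.encode(), np.uint8)]


@njit(cache=True)
def _ed_global(a, b):
    n, m = len(a), len(b)
    prev = np.arange(m + 1)
    cur = np.empty(m + 1, np.int64)
    for i in range(1, n + 1):
        cur[0] = i
        ai = a[i - 1]
        for j in range(1, m + 1):
            c = 0 if (ai == b[j - 1] and ai < 4) else 1
            v = prev[j - 1] + c
            if prev[j] + 1 < v:
                v = prev[j] + 1
            if cur[j - 1] + 1 < v:
                v = cur[j - 1] + 1
            cur[j] = v
        prev, cur = cur, prev
    return prev[m]


@njit(cache=True)
def _ed_infix_row(pat, text):
    """Last DP row of semiglobal alignment (pattern inside text, both
    text ends free): row[j] = min edits of pat vs a text substring
    ending at j."""
    n, m = len(pat), len(text)
    prev = np.zeros(m + 1, np.int64)
    cur = np.empty(m + 1, np.int64)
    for i in range(1, n + 1):
        cur[0] = i
        pi = pat[i - 1]
        for j in range(1, m + 1):
            c = 0 if (pi == text[j - 1] and pi < 4) else 1
            v = prev[j - 1] + c
            if prev[j] + 1 < v:
                v = prev[j] + 1
            if cur[j - 1] + 1 < v:
                v = cur[j - 1] + 1
            cur[j] = v
        prev, cur = cur, prev
    return prev


@njit(cache=True)
def _ed_prefix_row(pat, text):
    """row[j] = min edits of pat vs text[:j] (global in pattern, free
    text end)."""
    n, m = len(pat), len(text)
    prev = np.arange(m + 1)
    cur = np.empty(m + 1, np.int64)
    for i in range(1, n + 1):
        cur[0] = i
        pi = pat[i - 1]
        for j in range(1, m + 1):
            c = 0 if (pi == text[j - 1] and pi < 4) else 1
            v = prev[j - 1] + c
            if prev[j] + 1 < v:
                v = prev[j] + 1
            if cur[j - 1] + 1 < v:
                v = cur[j - 1] + 1
            cur[j] = v
        prev, cur = cur, prev
    return prev


def ed_global(a: str, b: str) -> int:
    return int(_ed_global(enc(a), enc(b)))


def ed_infix(pat: str, text: str) -> int:
    """Minimum edit distance of pat against any substring of text."""
    return int(_ed_infix_row(enc(pat), enc(text)).min())


def infix_best_interval(pat: str, text: str, max_ed: int
                        ) -> tuple[int, int, int] | None:
    """Best infix occurrence with the package's tie-breaks: minimal
    edits, then smallest start, then largest end.  Start positions are
    recovered by a reverse-pattern scan."""
    row = _ed_infix_row(enc(pat), enc(text))
    ed = int(row.min())
    if ed > max_ed:
        return None
    # ends achieving the optimum
    ends = np.flatnonzero(row == ed)
    # starts: align reversed pattern against reversed text
    row_r = _ed_infix_row(enc(pat[::-1]), enc(text[::-1]))
    starts = len(text) - np.flatnonzero(row_r == ed)
    start = int(starts.min())
    # largest end compatible with this start: check all ends by global DP
    best_end = None
    for e in ends:
        if e <= start:
            continue
        if ed_global(pat, text[start:int(e)]) == ed:
            best_end = int(e)
    if best_end is None:
        # fall back: smallest start overall may pair with a different end
        best_end = int(ends.max())
    return start, best_end, ed


def prefix_partial_best(seq: str, variants: list[str], min_match: int,
                        rate: float, prefix: bool) -> tuple[int, int, int] | None:
    """Oracle for end-partial adapter matches, mirroring the documented
    rule: for each adapter-orientation variant and matched length L,
    the minimal-edit alignment of the adapter suffix (prefix for the
    read end) against a read prefix (suffix); valid when edits <=
    floor(rate*L); winner trims the most bases, then largest L, then
    the earlier variant."""
    best = None
    for vi, v in enumerate(variants):
        la = len(v)
        region_len = min(len(seq), la + 20)
        region = seq[:region_len] if prefix else seq[-region_len:][::-1]
        for L in range(min_match, la + 1):
            part = v[la - L:] if prefix else v[:L][::-1]
            row = _ed_prefix_row(enc(part), enc(region))
            ed = int(row.min())
            if ed > int(rate * L):
                continue
            m = int(np.flatnonzero(row == ed).max())
            if m == 0:
                continue
            cand = (m, L, -vi)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    return best[0], best[1], -best[2]


def oracle_trim_walking(seq: str, adapter: str, rate: float, min_match: int
                        ) -> str:
    """Brute-force re-implementation of walking-adapter removal."""
    variants = [adapter, revcomp(adapter)]
    k_full = [int(rate * len(v)) for v in variants]
    while True:
        # full infix occurrences first
        best = None
        for vi, (v, k) in enumerate(zip(variants, k_full)):
            if not seq:
                continue
            got = infix_best_interval(v, seq, k)
            if got is None:
                continue
            s, e, ed = got
            cand = (ed, s, -e, vi)
            if best is None or cand < best[0]:
                best = (cand, (s, e))
        if best is not None:
            s, e = best[1]
            seq = seq[:s] + seq[e:]
            continue
        p = prefix_partial_best(seq, variants, min_match, rate, prefix=True)
        if p is not None and p[0] > 0:
            seq = seq[p[0]:]
            continue
        p = prefix_partial_best(seq, variants, min_match, rate, prefix=False)
        if p is not None and p[0] > 0:
            seq = seq[:len(seq) - p[0]]
            continue
        return seq


def oracle_global_identity(a: str, b: str) -> float:
    L = max(len(a), len(b))
    return max(1 - ed_global(a, b) / L, 1 - ed_global(a, revcomp(b)) / L)


def oracle_containment_identity(shorter: str, longer: str) -> float:
    return max(1 - ed_infix(shorter, longer) / len(shorter),
               1 - ed_infix(revcomp(shorter), longer) / len(shorter))


def oracle_cluster_round1(reads, min_identity: float, min_ratio: float,
                          min_size: int):
    """Greedy round-1 clustering, re-implemented with the DP identity.
    Returns (partition as list of member-id lists, discarded ids)."""
    ordered = sorted(reads, key=lambda r: (-len(r.seq), r.id))
    reps, members = [], []
    for r in ordered:
        placed = False
        for ci, rep in enumerate(reps):
            ratio = min(len(r.seq), len(rep.seq)) / max(len(r.seq), len(rep.seq))
            if ratio < min_ratio:
                continue
            if oracle_global_identity(r.seq, rep.seq) >= min_identity:
                members[ci].append(r.id)
                placed = True
                break
        if not placed:
            reps.append(r)
            members.append([r.id])
    retained = [m for m in members if len(m) >= min_size]
    discarded = [x for m in members if len(m) < min_size for x in m]
    return retained, discarded


def oracle_cluster_round2(rep_reads, memberships, min_identity: float):
    """Greedy containment merging of retained-cluster representatives."""
    order = sorted(range(len(rep_reads)),
                   key=lambda i: (-len(rep_reads[i].seq), rep_reads[i].id))
    merged: list[list[int]] = []
    for i in order:
        placed = False
        for grp in merged:
            rep = rep_reads[grp[0]]
            if oracle_containment_identity(rep_reads[i].seq, rep.seq) \
                    >= min_identity:
                grp.append(i)
                placed = True
                break
        if not placed:
            merged.append([i])
    return [sorted(x for i in grp for x in memberships[i]) for grp in merged]


def sw_oracle_score(q: str, s: str) -> int:
    """Optimal local affine alignment score via biotite (match +1,
    mismatch -2, gap of length n costs 5 + 2*(n-1)); max over strands."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign
    mat = np.full((4, 4), -2, dtype=np.int32)
    np.fill_diagonal(mat, 1)
    M = balign.SubstitutionMatrix(bseq.NucleotideSequence.alphabet_unamb,
                                  bseq.NucleotideSequence.alphabet_unamb, mat)
    best = 0
    ivals = None
    for rc in (False, True):
        qq = revcomp(q) if rc else q
        alns = balign.align_optimal(bseq.NucleotideSequence(qq),
                                    bseq.NucleotideSequence(s), M,
                                    gap_penalty=(-5, -2), local=True,
                                    max_number=1)
        if alns and alns[0].score > best:
            best = int(alns[0].score)
            tr = alns[0].trace
            qcol = tr[:, 0][tr[:, 0] >= 0]
            scol = tr[:, 1][tr[:, 1] >= 0]
            q0, q1 = int(qcol.min()), int(qcol.max()) + 1
            if rc:
                q0, q1 = len(q) - q1, len(q) - q0
            ivals = (q0, q1, int(scol.min()), int(scol.max()) + 1, rc)
    return best, ivals
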