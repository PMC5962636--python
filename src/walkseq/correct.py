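"""Overlap-based error correction and low-support trimming of long reads.

The stage stands in for the published workflow's correction step: reads
of at least 700 bp are corrected from a pileup of their overlapping
reads (overlaps of at least 700 bp on both reads, both orientations),
by per-column majority vote including indels; all eligible reads are
corrected.  Trimming then removes low-support (< 2) end runs, drops
reads falling under 700 bp, and applies one more walking-adapter pass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np

from . import _kernels
from .align import encode, parse_cigar
from .io import PipelineConfig, Read, revcomp
from .preprocess import trim_walking_adapter

log = logging.getLogger("walkseq")

#: acceptance threshold for a verified raw-read overlap.  Two reads at
#: the raw nanopore error rate differ by ~22-26% of aligned bases
#: (estimated identity 0.74-0.78); pairs sharing only part of the
#: implied span (e.g. a common cassette region plus unrelated flanks)
#: score around 0.55-0.65 and would poison the pileup, so the floor
#: sits between the two populations.
MIN_OVERLAP_IDENTITY = 0.70


@dataclass(slots=True)
class OverlapRecord:
    """A verified pairwise overlap.  ``offset`` places the oriented b
    read (forward for strand '+', reverse-complemented for '-') in a's
    forward coordinates: a[p] pairs with oriented_b[p - offset].  The
    verification alignment path (oriented-b segment vs a segment) is
    kept so correction does not re-align."""

    a_id: str
    b_id: str
    strand: str
    a_start: int
    a_end: int
    b_start: int          # forward-frame interval on b
    b_end: int
    identity: float
    offset: int
    ops: np.ndarray | None = None
    lens: np.ndarray | None = None

    def flipped(self, len_a: int, len_b: int) -> "OverlapRecord":
        """The same overlap viewed with b as the target.

        Swapping roles transposes the alignment (insertions become
        deletions); the reverse orientation additionally reverses the
        path, since both segments are seen reverse-complemented.
        """
        if self.strand == "+":
            off = -self.offset
        else:
            off = self.offset - len_a + len_b
        ops = lens = None
        if self.ops is not None:
            swap = np.array([_kernels.OP_M, _kernels.OP_INS, _kernels.OP_DEL],
                            np.uint8)
            ops = swap[self.ops]
            lens = self.lens
            if self.strand == "-":
                ops = ops[::-1]
                lens = lens[::-1]
        return OverlapRecord(self.b_id, self.a_id, self.strand,
                             self.b_start, self.b_end,
                             self.a_start, self.a_end, self.identity, off,
                             ops, lens)


@dataclass(slots=True)
class CorrectedRead:
    read: Read
    source_id: str
    support: np.ndarray | None
    n_evidence: int
    isolated: bool = False


def _pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mers per position; -1 where the window contains N."""
    n = len(codes)
    if n < k:
        return np.empty(0, np.int64)
    v = np.zeros(n - k + 1, np.int64)
    for t in range(k):
        v = (v << 2) | codes[t:n - k + 1 + t]
    has_n = np.cumsum(np.concatenate(([0], (codes >= 4).astype(np.int64))))
    bad = (has_n[k:] - has_n[:-k]) > 0
    v[bad] = -1
    return v


class _KmerIndex:
    """Sorted flat index of all forward k-mers of a read set."""

    def __init__(self, codes_list: list[np.ndarray], k: int,
                 max_bucket: int = 600):
        kms, rids, poss = [], [], []
        for i, codes in enumerate(codes_list):
            v = _pack_kmers(codes, k)
            ok = v >= 0
            kms.append(v[ok])
            rids.append(np.full(int(ok.sum()), i, np.int32))
            poss.append(np.flatnonzero(ok).astype(np.int32))
        km = np.concatenate(kms) if kms else np.empty(0, np.int64)
        order = np.argsort(km, kind="stable")
        self.km = km[order]
        self.rid = np.concatenate(rids)[order] if kms else np.empty(0, np.int32)
        self.pos = np.concatenate(poss)[order] if kms else np.empty(0, np.int32)
        # mask out overly repetitive words
        if len(self.km):
            uniq, start, counts = np.unique(self.km, return_index=True,
                                            return_counts=True)
            big = counts > max_bucket
            self._uniq = uniq
            self._start = start
            self._count = np.where(big, 0, counts)
        else:
            self._uniq = np.empty(0, np.int64)
            self._start = self._count = np.empty(0, np.int64)

    def lookup_many(self, kmers: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All (hit index ranges expanded) for a query k-mer array.
        Returns (query positions repeated, read ids, positions)."""
        if not len(self._uniq) or not len(kmers):
            e = np.empty(0, np.int64)
            return e, e.astype(np.int32), e.astype(np.int32)
        loc = np.searchsorted(self._uniq, kmers)
        loc_c = np.clip(loc, 0, len(self._uniq) - 1)
        found = self._uniq[loc_c] == kmers
        lo = self._start[loc_c]
        cnt = np.where(found, self._count[loc_c], 0)
        total = int(cnt.sum())
        if total == 0:
            e = np.empty(0, np.int64)
            return e, e.astype(np.int32), e.astype(np.int32)
        qrep = np.repeat(np.arange(len(kmers)), cnt)
        base = np.repeat(lo, cnt)
        off = np.arange(total) - np.repeat(np.cumsum(cnt) - cnt, cnt)
        idx = base + off
        return qrep, self.rid[idx], self.pos[idx]


def find_overlaps(reads: list[Read], config: PipelineConfig | None = None,
                  max_candidates_per_read: int = 25) -> list[OverlapRecord]:
    """All-vs-all overlap detection: shared-word candidate pairs on a
    consistent diagonal, verified by global alignment of the implied
    segments; overlaps shorter than the configured minimum on either
    read are dropped."""
    if config is None:
        config = PipelineConfig()
    k = config.corr_kmer
    min_ov = config.corr_min_overlap_bp
    codes = [encode(r.seq) for r in reads]
    lens = np.array([len(c) for c in codes])
    index = _KmerIndex(codes, k)
    pair_info: dict[tuple[int, int, str], list[int]] = {}
    stride = 4
    for i, ci in enumerate(codes):
        li = lens[i]
        ranked: list[tuple[int, int, str, int]] = []  # (count, j, strand, diag)
        for strand in "+-":
            qc = ci if strand == "+" else encode(revcomp(reads[i].seq))
            v = _pack_kmers(qc, k)
            sel = np.arange(0, len(v), stride)
            sel = sel[v[sel] >= 0]
            if not len(sel):
                continue
            qrep, rids, poss = index.lookup_many(v[sel])
            qpos = sel[qrep]
            keep = rids != i
            rids, poss, qpos = rids[keep], poss[keep], qpos[keep]
            if not len(rids):
                continue
            if strand == "+":
                diag = qpos - poss
            else:
                # oriented frame: i forward vs rc(j)
                diag = li - lens[rids] - (qpos.astype(np.int64) - poss)
            order = np.argsort(rids, kind="stable")
            rids_s, diag_s = rids[order], diag[order]
            uk, start, cnts = np.unique(rids_s, return_index=True,
                                        return_counts=True)
            good = np.flatnonzero(cnts >= config.corr_min_shared_kmers)
            if len(good) > max_candidates_per_read:
                good = good[np.argsort(-cnts[good],
                                       kind="stable")[:max_candidates_per_read]]
            for g in good:
                s0 = int(start[g])
                j = int(uk[g])
                d = int(np.median(diag_s[s0:s0 + int(cnts[g])]))
                span = min(li, int(lens[j]) + d) - max(0, d)
                if span < min_ov:
                    continue
                # weight candidates by evidence mass: shared words times
                # the overlap they imply, so long dovetail partners are
                # not crowded out by masses of short common-region hits
                ranked.append((int(cnts[g]) * span, j, strand, d))
        ranked.sort(key=lambda t: (-t[0], t[1], t[2]))
        for w, j, strand, d in ranked[:max_candidates_per_read]:
            a, b = (i, j) if i < j else (j, i)
            if (a, b, strand) in pair_info:
                continue
            if a == i:
                pair_info[(a, b, strand)] = [d]
            else:
                # convert offset to the (a, b) ordering
                if strand == "+":
                    pair_info[(a, b, strand)] = [-d]
                else:
                    pair_info[(a, b, strand)] = [int(lens[i]) - int(lens[j]) - d]

    out: list[OverlapRecord] = []
    for (a, b, strand), (d,) in pair_info.items():
        la, lb = int(lens[a]), int(lens[b])
        t0, t1 = max(0, d), min(la, lb + d)
        span = t1 - t0
        if span < min_ov:
            continue
        ob = reads[b].seq if strand == "+" else revcomp(reads[b].seq)
        seg_t = reads[a].seq[t0:t1]
        seg_e = ob[t0 - d:t1 - d]
        k = int((1 - MIN_OVERLAP_IDENTITY) * span) + 1
        res = edlib.align(seg_e, seg_t, mode="NW", task="path", k=k)
        if res["editDistance"] < 0:
            continue
        ident = 1.0 - res["editDistance"] / max(span, 1)
        if ident < MIN_OVERLAP_IDENTITY:
            continue
        ops, lns = parse_cigar(res["cigar"])
        if strand == "+":
            b0, b1 = t0 - d, t1 - d
        else:
            b0, b1 = lb - (t1 - d), lb - (t0 - d)
        out.append(OverlapRecord(reads[a].id, reads[b].id, strand,
                                 t0, t1, b0, b1, ident, d, ops, lns))
    log.info("find_overlaps: %d verified overlaps from %d reads",
             len(out), len(reads))
    return out


def correct_reads(reads: list[Read], overlaps: list[OverlapRecord],
                  config: PipelineConfig | None = None) -> list[CorrectedRead]:
    """Pileup majority-vote correction of every read >= the minimum
    length.  A base whose column majority agrees with the original is
    never changed; ties keep the original.  Reads without overlaps are
    emitted uncorrected with support 1 and flagged."""
    if config is None:
        config = PipelineConfig()
    by_id = {r.id: r for r in reads}
    lens = {r.id: len(r.seq) for r in reads}
    per_target: dict[str, list[OverlapRecord]] = {}
    for ov in overlaps:
        per_target.setdefault(ov.a_id, []).append(ov)
        per_target.setdefault(ov.b_id, []).append(
            ov.flipped(lens[ov.a_id], lens[ov.b_id]))
    out: list[CorrectedRead] = []
    for r in reads:
        if len(r.seq) < config.corr_min_read_len_bp:
            continue
        evidence = per_target.get(r.id, [])
        evidence.sort(key=lambda o: -(o.a_end - o.a_start) * o.identity)
        evidence = evidence[:config.corr_max_evidence]
        L = len(r.seq)
        orig = encode(r.seq)
        votes = np.zeros((L, 5), np.int32)
        votes[np.arange(L), np.minimum(orig, 4)] += 1   # self
        ins_count = np.zeros(L + 1, np.int32)
        ins_base = np.zeros((L + 1, 4), np.int32)
        for ov in evidence:
            ev_read = by_id[ov.b_id]
            oseq = ev_read.seq if ov.strand == "+" else revcomp(ev_read.seq)
            t0, t1 = ov.a_start, ov.a_end
            e0, e1 = t0 - ov.offset, t1 - ov.offset
            if e0 < 0 or e1 > len(oseq):
                continue
            if ov.ops is not None:
                ops, lns = ov.ops, ov.lens
            else:
                res = edlib.align(oseq[e0:e1], r.seq[t0:t1], mode="NW",
                                  task="path")
                ops, lns = parse_cigar(res["cigar"])
            _kernels.add_alignment(votes, ins_count, ins_base, ops, lns,
                                   encode(oseq[e0:e1]), t0)
        corr, sup = _kernels.correct_from_pileup(orig, votes, ins_count, ins_base)
        seq = "".join("ACGTN"[c] for c in corr)
        if not seq:
            continue
        qual = np.minimum(40, 4 + 6 * sup).astype(int).tolist()
        out.append(CorrectedRead(
            Read(r.id, seq, qual, r.start_time_s), r.id, sup,
            n_evidence=len(evidence), isolated=not evidence))
    log.info("correct_reads: %d/%d reads corrected", len(out), len(reads))
    return out


def trim_low_support(corrected: list[CorrectedRead],
                     config: PipelineConfig | None = None
                     ) -> list[CorrectedRead]:
    """Remove low-support end runs, enforce the minimum read length, and
    run one more walking-adapter pass."""
    if config is None:
        config = PipelineConfig()
    thr = config.corr_min_support
    min_len = config.corr_min_read_len_bp
    kept: list[CorrectedRead] = []
    for cr in corrected:
        sup = cr.support
        if sup is None or not len(sup):
            continue
        good = np.flatnonzero(sup >= thr)
        if not len(good):
            continue
        s, e = int(good[0]), int(good[-1]) + 1
        if e - s < min_len:
            continue
        r = cr.read
        kept.append(CorrectedRead(
            Read(r.id, r.seq[s:e], r.qual[s:e] if r.qual else None,
                 r.start_time_s),
            cr.source_id, sup[s:e], cr.n_evidence, cr.isolated))
    # final walking-adapter pass; positional support is no longer needed
    reads = [cr.read for cr in kept]
    adapter_cfg = config.with_overrides(
        min_read_len_post_trim_bp=min_len)
    trimmed, _ = trim_walking_adapter(reads, adapter_cfg)
    by_id = {cr.read.id: cr for cr in kept}
    out = [CorrectedRead(r, by_id[r.id].source_id, None,
                         by_id[r.id].n_evidence, by_id[r.id].isolated)
           for r in trimmed]
    log.info("trim_low_support: %d -> %d reads", len(corrected), len(out))
    return out


def correction_pipeline(reads: list[Read], config: PipelineConfig | None = None
                        ) -> list[CorrectedRead]:
    """find_overlaps -> correct_reads -> trim_low_support."""
    if config is None:
        config = PipelineConfig()
    overlaps = find_overlaps(reads, config)
    corrected = correct_reads(reads, overlaps, config)
    return trim_low_support(corrected, config)
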