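"""Adapter removal, length filtering and time-based read subsetting.

Walking-adapter removal semantics (matching the published trimming
settings): an occurrence is removed when its edit distance is at most
floor(error_rate * matched adapter length) with matched length >= 5;
matches shorter than the full adapter are only accepted at read ends.
Both orientations are searched.  Removal iterates until no occurrence
remains; reads shorter than 100 bp afterwards are discarded.

Tie-breaking is fixed so that runs are reproducible: full-length infix
occurrences are removed first (smallest edit distance, then leftmost,
then longest, forward orientation before reverse complement); end
partials trim the longest optimal match (largest trim, then largest
matched adapter length, forward before reverse complement).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .io import PLATFORM_ADAPTERS, PipelineConfig, Read, revcomp

log = logging.getLogger("walkseq")


@dataclass(slots=True)
class TrimReport:
    reads_in: int = 0
    reads_out: int = 0
    adapters_removed: int = 0
    bases_trimmed: int = 0
    splits: int = 0
    discarded_short: int = 0
    events: list[tuple] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("reads_in", "reads_out", "adapters_removed",
                 "bases_trimmed", "splits", "discarded_short")}


def _best_full_infix(seq: str, variants: list[str], max_ed: list[int]
                     ) -> tuple[int, int, int, int] | None:
    """Best full-adapter occurrence inside seq.

    Returns (start, end_exclusive, edit_distance, variant_index) of the
    winning occurrence: minimal edit distance, then smallest start, then
    largest end, then lowest variant index (forward before reverse).
    """
    best = None
    for vi, (v, k) in enumerate(zip(variants, max_ed)):
        if not seq:
            continue
        res = edlib.align(v, seq, mode="HW", task="locations", k=k)
        if res["editDistance"] < 0:
            continue
        ed = res["editDistance"]
        locs = res["locations"]
        start = min(l[0] for l in locs)
        end = max(l[1] + 1 for l in locs if l[0] == start)
        cand = (ed, start, -end, vi)
        if best is None or cand < best[0]:
            best = (cand, (start, end, ed, vi))
    return best[1] if best else None


def _best_end_partial(seq: str, variants: list[str], min_match: int,
                      rate: float, prefix: bool) -> tuple[int, int, int] | None:
    """Best partial adapter match at a read end.

    For the read start (prefix=True) the read begins mid-adapter, so a
    suffix of the adapter of length L aligns to a read prefix; for the
    read end, an adapter prefix aligns to a read suffix.  Valid when
    edit distance <= floor(rate * L).  Returns (trim_len, L, variant),
    preferring the largest trim, then the largest L, then forward
    orientation.
    """
    best = None
    for vi, v in enumerate(variants):
        la = len(v)
        region_len = min(len(seq), la + 20)
        region = seq[:region_len] if prefix else seq[-region_len:][::-1]
        for L in range(min_match, la + 1):
            part = v[la - L:] if prefix else v[:L][::-1]
            k = int(rate * L)
            res = edlib.align(part, region, mode="SHW", task="locations", k=k)
            if res["editDistance"] < 0:
                continue
            m = max(l[1] + 1 for l in res["locations"])
            if m == 0:
                continue
            cand = (m, L, -vi)
            if best is None or cand > best:
                best = cand
    if best is None:
        return None
    return best[0], best[1], -best[2]


def trim_walking_adapter(reads: list[Read], config: PipelineConfig
                         ) -> tuple[list[Read], TrimReport]:
    """Remove every walking-adapter occurrence (both orientations),
    iterating until none remains; discard reads < 100 bp afterwards."""
    adapter = config.walking_adapter_seq
    rate = config.walking_adapter_error_rate
    variants = [adapter, revcomp(adapter)]
    k_full = [int(rate * len(v)) for v in variants]
    rep = TrimReport(reads_in=len(reads))
    out: list[Read] = []
    for r in reads:
        seq, qual = r.seq, r.qual
        changed = True
        while changed:
            changed = False
            hit = _best_full_infix(seq, variants, k_full)
            if hit is not None:
                s, e, _, _ = hit
                seq = seq[:s] + seq[e:]
                if qual is not None:
                    qual = qual[:s] + qual[e:]
                rep.adapters_removed += 1
                rep.bases_trimmed += e - s
                changed = True
                continue
            p = _best_end_partial(seq, variants,
                                  config.walking_adapter_min_match_bp, rate,
                                  prefix=True)
            if p is not None and p[0] > 0:
                m = p[0]
                seq, qual = seq[m:], (qual[m:] if qual is not None else None)
                rep.adapters_removed += 1
                rep.bases_trimmed += m
                changed = True
                continue
            p = _best_end_partial(seq, variants,
                                  config.walking_adapter_min_match_bp, rate,
                                  prefix=False)
            if p is not None and p[0] > 0:
                m = p[0]
                seq = seq[:len(seq) - m]
                if qual is not None:
                    qual = qual[:len(qual) - m]
                rep.adapters_removed += 1
                rep.bases_trimmed += m
                changed = True
        if len(seq) >= config.min_read_len_post_trim_bp:
            out.append(Read(r.id, seq, qual, r.start_time_s))
        else:
            rep.discarded_short += 1
    rep.reads_out = len(out)
    log.info("walking-adapter trim: %d -> %d reads, %d occurrences removed",
             rep.reads_in, rep.reads_out, rep.adapters_removed)
    return out, rep


def trim_platform_adapters(reads: list[Read],
                           adapter_set: tuple[str, ...] = PLATFORM_ADAPTERS,
                           config: PipelineConfig | None = None
                           ) -> tuple[list[Read], TrimReport]:
    """Sequencer-adapter removal: end matches at normalized identity
    >= the end threshold trim to the read end when removing >= 4 bp;
    an internal match at normalized identity >= the middle threshold
    splits the read into two suffixed reads."""
    if config is None:
        config = PipelineConfig()
    if not adapter_set:
        raise ValueError("platform adapter set must be non-empty")
    variants = [v for a in adapter_set for v in (a, revcomp(a))]
    end_k = [int((1 - config.platform_end_threshold) * len(v)) for v in variants]
    mid_k = [int((1 - config.platform_middle_threshold) * len(v)) for v in variants]
    end_region = 150
    min_trim = config.platform_adapter_min_trim_bp
    rep = TrimReport(reads_in=len(reads))
    out: list[Read] = []
    for r in reads:
        stack = [(r.id, r.seq, r.qual, 0)]
        parts: list[Read] = []
        while stack:
            rid, seq, qual, depth = stack.pop(0)
            hit = _best_full_infix(seq, variants, mid_k)
            acted = False
            if hit is not None:
                s, e, ed, vi = hit
                near_start = s < end_region
                near_end = len(seq) - e < end_region
                if near_start and s + (e - s) >= min_trim and ed <= end_k[vi] \
                        and not (near_end and len(seq) - s < e):
                    cut = e
                    if cut >= min_trim:
                        seq, qual = seq[cut:], (qual[cut:] if qual else None)
                        rep.adapters_removed += 1
                        rep.bases_trimmed += cut
                        acted = True
                elif near_end and ed <= end_k[vi]:
                    cut = len(seq) - s
                    if cut >= min_trim:
                        seq = seq[:s]
                        qual = qual[:s] if qual else None
                        rep.adapters_removed += 1
                        rep.bases_trimmed += cut
                        acted = True
                elif not near_start and not near_end:
                    rep.splits += 1
                    rep.adapters_removed += 1
                    rep.bases_trimmed += e - s
                    stack.append((f"{rid}/1", seq[:s],
                                  qual[:s] if qual else None, depth + 1))
                    stack.append((f"{rid}/2", seq[e:],
                                  qual[e:] if qual else None, depth + 1))
                    continue
            if acted:
                stack.insert(0, (rid, seq, qual, depth))
                continue
            if len(seq) >= config.min_read_len_post_trim_bp:
                parts.append(Read(rid, seq, qual, r.start_time_s))
            else:
                rep.discarded_short += 1
        out.extend(parts)
    rep.reads_out = len(out)
    log.info("platform-adapter trim: %d -> %d reads (%d splits)",
             rep.reads_in, rep.reads_out, rep.splits)
    return out, rep


def subset_by_time(reads: list[Read], cutoff_h: float) -> list[Read]:
    """Exactly the reads with start_time <= cutoff, in stable order."""
    missing = [r.id for r in reads if r.start_time_s is None]
    if missing:
        raise ValueError(
            f"subset_by_time: {len(missing)} reads lack start times "
            f"(first: {missing[0]!r})")
    cutoff_s = cutoff_h * 3600.0
    return [r for r in reads if r.start_time_s <= cutoff_s]
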