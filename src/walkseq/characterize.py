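"""Insertion-site delineation, junction excision, flank reassembly and
authorization-status calling.

Junction-candidate clusters carry a host-side hit and a vector-side hit
on their representative.  The host-hit boundary adjacent to the vector
overhang is the breakpoint; breakpoints on the same contig and border
side are grouped (+/- 5 bp) and a group is a delineated site only when
the modal position concentrates >= 70% of breakpoints and fewer than 3
distinct insert-fusion partners are involved — the scattered-clip
pattern of PCR-recombination chimeras fails this rule and is emitted as
a chimeric suspect instead (flagged for wet-lab confirmation).

The 100-bp junction window is excised around the midpoint between the
two hits in query coordinates, and its consensus is called across the
supporting reads.  The window is finally searched against the
authorized-junction (and optionally patent) databases: a junction is
"known" when the best hit spans >= 90% of the window, "unknown" when no
hit spans more than 50%, and "ambiguous" in between (left for review).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .align import ConsensusResult, SeqDB, best_hit, consensus_call, map_reads, search
from .annotate import JUNCTION_CANDIDATE, AnnotationRecord
from .cluster import Cluster, containment_identity
from .io import BedInterval, PipelineConfig, Read

log = logging.getLogger("walkseq")


@dataclass(slots=True)
class StatusCall:
    verdict: str                 # known / unknown / ambiguous
    coverage: float
    db_name: str = ""
    subject: str = ""


@dataclass(slots=True)
class InsertionSite:
    contig: str
    side: str                    # LB / RB / NA
    breakpoint: int              # host coordinates, 0-based
    supporting_clusters: list[str]
    n_reads: int
    delineation: str             # delineated / chimeric_suspect
    consensus: ConsensusResult | None = None
    status: StatusCall | None = None
    note: str = ""

    @property
    def name(self) -> str:
        return f"{self.contig}-{self.side}@{self.breakpoint}"

    def to_bed(self, window: int = 100) -> BedInterval:
        half = window // 2
        return BedInterval(self.contig, max(0, self.breakpoint - half),
                           self.breakpoint + half, f"{self.side}",
                           str(len(self.supporting_clusters)), "+")


@dataclass(slots=True)
class _Candidate:
    record: AnnotationRecord
    contig: str
    side: str
    breakpoint: int
    facing: int                  # cassette coordinate adjacent to the fusion
    host_left: bool              # host hit left of vector hit in query coords


def _orient_candidate(rec: AnnotationRecord, host_db: SeqDB,
                      cassette_len: int) -> _Candidate | None:
    h, v = rec.plant_hit, rec.nonhost_hit
    if h is None or v is None:
        return None
    try:
        tags = host_db.tags[host_db.ids.index(h.sid)]
    except ValueError:
        return None
    if tags.get("kind") != "host":
        return None
    host_left = (h.qstart + h.qend) <= (v.qstart + v.qend)
    if host_left:
        bp = h.send if h.strand == "+" else h.sstart
        facing = (v.sstart if v.strand == "+" else v.send)
    else:
        bp = h.sstart if h.strand == "+" else h.send
        facing = (v.send if v.strand == "+" else v.sstart)
    if v.sid == "cassette" or cassette_len > 0:
        side = "LB" if facing < cassette_len / 2 else "RB"
    else:
        side = "NA"
    return _Candidate(rec, h.sid, side, int(bp), int(facing), host_left)


def _distinct_partners(facings: list[int], tol: int = 100) -> int:
    groups: list[int] = []
    for f in sorted(facings):
        if not groups or f - groups[-1] > tol:
            groups.append(f)
        else:
            groups[-1] = f
    return len(groups)


def delineate_sites(junction_records: list[AnnotationRecord], host_db: SeqDB,
                    nonhost_db: SeqDB, config: PipelineConfig | None = None
                    ) -> list[InsertionSite]:
    """Group junction-candidate breakpoints into delineated sites and
    chimeric suspects (permutation-invariant in record order)."""
    if config is None:
        config = PipelineConfig()
    try:
        clen = len(nonhost_db.get("cassette"))
    except ValueError:
        clen = 0
    cands = []
    for rec in sorted(junction_records, key=lambda r: r.cluster_id):
        if rec.fate != JUNCTION_CANDIDATE:
            continue
        c = _orient_candidate(rec, host_db, clen)
        if c is not None:
            cands.append(c)
    sites: list[InsertionSite] = []
    tol = config.site_group_tol_bp
    by_side: dict[tuple[str, str], list[_Candidate]] = {}
    for c in cands:
        by_side.setdefault((c.contig, c.side), []).append(c)
    # split each (contig, side) into positional loci: breakpoints more
    # than site_locus_gap_bp apart belong to different loci, so a
    # chimeric hotspot elsewhere on the contig cannot poison a real site
    groups: list[tuple[str, str, list[_Candidate]]] = []
    for (contig, side), cs in sorted(by_side.items()):
        cs = sorted(cs, key=lambda c: (c.breakpoint, c.record.cluster_id))
        cur = [cs[0]]
        for c in cs[1:]:
            if c.breakpoint - cur[-1].breakpoint > config.site_locus_gap_bp:
                groups.append((contig, side, cur))
                cur = []
            cur.append(c)
        groups.append((contig, side, cur))
    for contig, side, group in groups:
        pos = np.array([c.breakpoint for c in group])
        counts = [(int((np.abs(pos - p) <= tol).sum()), -p) for p in pos]
        n_modal, neg_mode = max(counts)
        mode = -neg_mode
        modal = [c for c in group if abs(c.breakpoint - mode) <= tol]
        rest = [c for c in group if abs(c.breakpoint - mode) > tol]
        concentration = n_modal / len(group)
        partners = _distinct_partners([c.facing for c in group])
        scattered = (concentration < config.site_modal_min_frac
                     or partners >= config.site_max_fusion_partners)
        if scattered:
            sites.append(InsertionSite(
                contig, side, int(np.median(pos)),
                [c.record.cluster_id for c in group],
                sum(c.record.n_reads for c in group), "chimeric_suspect",
                note="scattered clipping / multiple fusion partners; "
                     "requires wet-lab confirmation"))
            continue
        bp = int(np.median([c.breakpoint for c in modal]))
        sites.append(InsertionSite(
            contig, side, bp, [c.record.cluster_id for c in modal],
            sum(c.record.n_reads for c in modal), "delineated"))
        if rest:
            sites.append(InsertionSite(
                contig, side, int(np.median([c.breakpoint for c in rest])),
                [c.record.cluster_id for c in rest],
                sum(c.record.n_reads for c in rest), "chimeric_suspect",
                note="breakpoints off the modal position; "
                     "requires wet-lab confirmation"))
    log.info("delineate: %d delineated, %d suspect",
             sum(s.delineation == "delineated" for s in sites),
             sum(s.delineation == "chimeric_suspect" for s in sites))
    return sites


def excise_junction(rec: AnnotationRecord, rep: Read,
                    window: int = 100) -> tuple[str, bool]:
    """Excise the window around the midpoint between the vector-side and
    host-side hits in query coordinates; clipped windows are flagged."""
    h, v = rec.plant_hit, rec.nonhost_hit
    if h is None or v is None:
        raise ValueError(f"{rec.cluster_id}: junction excision needs both hits")
    first, second = (h, v) if (h.qstart + h.qend) <= (v.qstart + v.qend) else (v, h)
    if second.qstart < first.qend - window:
        raise ValueError(
            f"{rec.cluster_id}: hits overlap by more than the window "
            f"({first.qend - second.qstart} bp): malformed candidate")
    m = (first.qend + second.qstart) // 2
    half = window // 2
    lo, hi = m - half, m + half
    clipped = lo < 0 or hi > len(rep.seq)
    return rep.seq[max(0, lo):hi], clipped


def project_breakpoint(hit, host_pos: int) -> int:
    """Query coordinate corresponding to a host-subject position.

    Extrapolates colinearly from the *nearest* hit boundary: breakpoints
    live at a boundary, and extrapolating from the far one would
    accumulate the alignment's internal indel drift.
    """
    near_start = abs(host_pos - hit.sstart) <= abs(host_pos - hit.send)
    if hit.strand == "+":
        if near_start:
            return hit.qstart + (host_pos - hit.sstart)
        return hit.qend + (host_pos - hit.send)
    if near_start:
        return hit.qend - (host_pos - hit.sstart)
    return hit.qstart + (hit.send - host_pos)


def site_consensus(site: InsertionSite, records_by_cluster: dict[str, AnnotationRecord],
                   clusters_by_id: dict[str, Cluster],
                   reads_by_id: dict[str, Read],
                   config: PipelineConfig | None = None,
                   truth: str | None = None
                   ) -> tuple[ConsensusResult, str]:
    """Junction-window consensus across the site's supporting reads.

    The modal cluster's representative anchors the window, which is
    centred on the delineated breakpoint projected into representative
    coordinates (this removes the few-bp boundary noise that the
    per-cluster midpoint excision carries).  Supporting reads are
    mapped onto the representative and columns below the consensus
    depth threshold stay uncalled (N).  Returns the consensus plus the
    representative's own bases over the same window (the fallback for
    uncalled columns).
    """
    if config is None:
        config = PipelineConfig()
    best_cid = max(site.supporting_clusters,
                   key=lambda cid: (records_by_cluster[cid].n_reads, cid))
    rec = records_by_cluster[best_cid]
    rep = reads_by_id[rec.rep_id]
    window = config.junction_window_bp
    half = window // 2
    m = project_breakpoint(rec.plant_hit, site.breakpoint)
    lo = max(0, m - half)
    hi = min(len(rep.seq), m + half)
    ref = SeqDB([("rep", rep.seq, {})], name="site_rep")
    members = []
    for cid in site.supporting_clusters:
        members.extend(clusters_by_id[cid].members)
    member_reads = [reads_by_id[rid] for rid in dict.fromkeys(members)
                    if rid in reads_by_id]
    hits = map_reads(member_reads, ref, word_size=config.map_word_size, stride=2)
    cons = consensus_call(member_reads, hits, ref, "rep", lo, hi,
                          min_cov=config.consensus_min_cov, truth=truth,
                          fill_uncalled=True)
    return cons, rep.seq[lo:hi]


def assemble_flanks(rep_seqs: dict[str, str],
                    config: PipelineConfig | None = None) -> tuple[str, str]:
    """Greedy overlap merging of a site's representatives (minimum
    overlap 40 bp at >= 94% identity); returns (contig id, sequence) of
    the longest resulting contig."""
    if config is None:
        config = PipelineConfig()
    contigs = dict(rep_seqs)
    if not contigs:
        return "", ""
    merged = True
    while merged and len(contigs) > 1:
        merged = False
        ids = sorted(contigs, key=lambda i: -len(contigs[i]))
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                sa, sb = contigs[a], contigs[b]
                if containment_identity(sb, sa, config.flank_min_identity) \
                        >= config.flank_min_identity:
                    del contigs[b]
                    merged = True
                    break
                joined = _dovetail_merge(sa, sb, config)
                if joined is not None:
                    contigs[a] = joined
                    del contigs[b]
                    merged = True
                    break
            if merged:
                break
    best = max(contigs, key=lambda i: (len(contigs[i]), i))
    return best, contigs[best]


def _dovetail_merge(a: str, b: str, config: PipelineConfig) -> str | None:
    db = SeqDB([("a", a, {})])
    w = min(config.overhang_word_size, config.flank_min_overlap_bp)
    hits = search("b", b, db, w)
    for h in hits[:3]:
        if h.aln_len < config.flank_min_overlap_bp:
            continue
        if h.identity < config.flank_min_identity:
            continue
        if h.strand != "+":
            continue
        tol = 30
        # suffix of a overlaps prefix of b -> a + b tail
        if h.send >= len(a) - tol and h.qstart <= tol:
            return a[:h.sstart] + b[h.qstart:]
        # suffix of b overlaps prefix of a -> b + a tail
        if h.qend >= len(b) - tol and h.sstart <= tol:
            return b[:h.qstart] + a[h.sstart:]
    return None


def order_insert_fragments(internal_records: list[AnnotationRecord],
                           reads_by_id: dict[str, Read],
                           junction_contigs: dict[str, str],
                           nonhost_db: SeqDB,
                           config: PipelineConfig | None = None) -> list[dict]:
    """Arrange insert-internal fragments into a tiling: drop fragments
    contained in another, then place the rest by their best anchoring
    hit (junction contig first, then the vector/construct DB)."""
    if config is None:
        config = PipelineConfig()
    frags = [(r.cluster_id, reads_by_id[r.rep_id].seq) for r in internal_records]
    frags.sort(key=lambda t: (-len(t[1]), t[0]))
    kept: list[tuple[str, str]] = []
    for cid, seq in frags:
        contained = any(
            containment_identity(seq, kseq, config.flank_min_identity)
            >= config.flank_min_identity for _, kseq in kept)
        if not contained:
            kept.append((cid, seq))
    jdb = SeqDB([(n, s, {}) for n, s in junction_contigs.items()],
                name="junctions") if junction_contigs else None
    rows = []
    for cid, seq in kept:
        anchor, pos, strand = "", -1, "."
        if jdb is not None:
            h = best_hit(search(cid, seq, jdb, config.overhang_word_size))
            if h is not None and h.aln_len >= config.flank_min_overlap_bp:
                anchor, pos, strand = f"junction:{h.sid}", h.sstart, h.strand
        if not anchor:
            h = best_hit(search(cid, seq, nonhost_db, config.overhang_word_size))
            if h is not None:
                anchor, pos, strand = f"db:{h.sid}", h.sstart, h.strand
        rows.append({"fragment": cid, "length": len(seq), "anchor": anchor,
                     "position": pos, "strand": strand})
    rows.sort(key=lambda r: (r["anchor"].split(":")[0] != "db",
                             r["anchor"], r["position"]))
    return rows


def call_status(windows: dict[str, str], authorized_db: SeqDB,
                patent_db: SeqDB | None = None,
                config: PipelineConfig | None = None) -> dict[str, StatusCall]:
    """Authorization-status verdict per junction window."""
    if config is None:
        config = PipelineConfig()
    out: dict[str, StatusCall] = {}
    dbs = [("authorized", authorized_db)]
    if patent_db is not None:
        dbs.append(("patent", patent_db))
    for name, seq in windows.items():
        if not seq:
            raise ValueError(f"junction {name}: empty window")
        best_cov, best_db, best_sid = 0.0, "", ""
        for dbname, db in dbs:
            if len(db) == 0:
                continue
            h = best_hit(search(name, seq, db, config.status_word_size))
            if h is not None and h.qcov > best_cov:
                best_cov, best_db, best_sid = h.qcov, dbname, h.sid
        if best_cov >= config.status_known_min_query_cov:
            verdict = "known"
        elif best_cov <= config.status_unknown_max_query_cov:
            verdict = "unknown"
        else:
            verdict = "ambiguous"
        out[name] = StatusCall(verdict, round(best_cov, 4), best_db, best_sid)
    return out
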