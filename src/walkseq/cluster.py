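"""Two-round greedy identity clustering with chimera suppression.

Round 1 is a greedy incremental global clustering (reads sorted by
length descending; a read joins the first cluster whose representative
it matches at >= 95% global identity with length ratio >= 0.99); only
clusters with >= 6 members are retained, which removes under-represented
reads and PCR/sequencing chimeras.  Round 2 merges retained clusters
whose shorter representative is contained in a longer one (local
alignment covering the shorter at >= 95% identity); all round-2 clusters
are retained.

Identity definitions (deterministic, traceback-invariant):
  global      1 - editdist(a, b) / max(|a|, |b|)
  containment 1 - editdist(shorter aligned inside longer) / |shorter|
Both orientations are considered (reads may come from either strand).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import edlib

from .io import PipelineConfig, Read, revcomp

log = logging.getLogger("walkseq")


@dataclass(slots=True)
class Cluster:
    id: str
    representative: str          # read id of the longest member
    members: list[str] = field(default_factory=list)
    round: int = 1

    @property
    def size(self) -> int:
        return len(self.members)


def global_identity(a: str, b: str, min_identity: float = 0.0) -> float:
    """max over orientations of 1 - editdist(a, b)/max(|a|,|b|)."""
    L = max(len(a), len(b))
    k = int((1 - min_identity) * L) + 1 if min_identity > 0 else -1
    best = 0.0
    for bb in (b, revcomp(b)):
        d = edlib.align(a, bb, mode="NW", task="distance", k=k)["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / L)
    return best


def containment_identity(shorter: str, longer: str,
                         min_identity: float = 0.0) -> float:
    """max over orientations of 1 - editdist_infix(shorter in longer)/|shorter|."""
    k = int((1 - min_identity) * len(shorter)) + 1 if min_identity > 0 else -1
    best = 0.0
    for s in (shorter, revcomp(shorter)):
        d = edlib.align(s, longer, mode="HW", task="distance", k=k)["editDistance"]
        if d >= 0:
            best = max(best, 1.0 - d / len(shorter))
    return best


def cluster_round1(reads: list[Read], config: PipelineConfig | None = None
                   ) -> tuple[list[Cluster], list[str], list[Cluster]]:
    """Greedy round-1 clustering.

    Returns (retained clusters, discarded read ids, all clusters).  The
    discard pool holds every member of a cluster smaller than the
    minimum size — this is where chimeras are expected to end up.
    """
    if config is None:
        config = PipelineConfig()
    min_id = config.clust_min_identity
    min_ratio = config.clust_round1_min_length_ratio
    ordered = sorted(reads, key=lambda r: (-len(r.seq), r.id))
    clusters: list[Cluster] = []
    rep_seqs: list[str] = []
    rep_lens: list[int] = []
    start = 0  # reps are founded in non-increasing length order
    for r in ordered:
        L = len(r.seq)
        while start < len(clusters) and rep_lens[start] * min_ratio > L:
            start += 1
        placed = False
        for ci in range(start, len(clusters)):
            if L < rep_lens[ci] * min_ratio:
                continue
            if global_identity(r.seq, rep_seqs[ci], min_id) >= min_id:
                clusters[ci].members.append(r.id)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(f"c1_{len(clusters):05d}", r.id, [r.id], 1))
            rep_seqs.append(r.seq)
            rep_lens.append(L)
    retained = [c for c in clusters if c.size >= config.clust_min_cluster_size]
    discarded = [m for c in clusters
                 if c.size < config.clust_min_cluster_size for m in c.members]
    log.info("round 1: %d clusters, %d retained (>=%d reads), %d reads discarded",
             len(clusters), len(retained), config.clust_min_cluster_size,
             len(discarded))
    return retained, discarded, clusters


def cluster_round2(retained_round1: list[Cluster], reads_by_id: dict[str, Read],
                   leftover_reads: list[str] | None = None,
                   config: PipelineConfig | None = None) -> list[Cluster]:
    """Merge retained round-1 clusters by representative containment.

    ``leftover_reads`` (the round-1 discard pool) is accepted for
    interface completeness but is not rescued: the published second
    clustering round operated on retained clusters only.
    """
    if config is None:
        config = PipelineConfig()
    min_id = config.clust_min_identity
    ordered = sorted(retained_round1,
                     key=lambda c: (-len(reads_by_id[c.representative].seq),
                                    c.representative))
    merged: list[Cluster] = []
    merged_rep_seq: list[str] = []
    for c in ordered:
        rep = reads_by_id[c.representative].seq
        placed = False
        for mi, big in enumerate(merged):
            if containment_identity(rep, merged_rep_seq[mi], min_id) >= min_id:
                big.members.extend(c.members)
                big.round = 2
                placed = True
                break
        if not placed:
            merged.append(Cluster(f"c2_{len(merged):05d}", c.representative,
                                  list(c.members), 1))
            merged_rep_seq.append(rep)
    log.info("round 2: %d -> %d clusters", len(retained_round1), len(merged))
    return merged


def cluster_stats(round1_all: list[Cluster], retained: list[Cluster],
                  discarded: list[str], round2: list[Cluster],
                  n_input_reads: int) -> list[dict]:
    """Per-round summary: cluster counts, sizes, discards, fold reduction."""
    rows = []
    for name, cs in (("round1", round1_all), ("round1_retained", retained),
                     ("round2", round2)):
        sizes = [c.size for c in cs]
        rows.append({
            "round": name,
            "n_clusters": len(cs),
            "mean_size": round(sum(sizes) / len(sizes), 2) if sizes else 0,
            "max_size": max(sizes) if sizes else 0,
            "n_reads": sum(sizes),
        })
    rows.append({"round": "discarded", "n_clusters": 0, "mean_size": 0,
                 "max_size": 0, "n_reads": len(discarded)})
    fold = n_input_reads / len(round2) if round2 else 0.0
    rows.append({"round": "fold_reduction", "n_clusters": len(round2),
                 "mean_size": round(fold, 1), "max_size": 0,
                 "n_reads": n_input_reads})
    return rows
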