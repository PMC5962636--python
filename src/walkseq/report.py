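"""Run-level statistics, end-to-end orchestration and the run manifest.

Stages communicate via files (FASTQ/FASTA/TSV/BED) so each stage is
independently re-runnable; a JSON manifest of stage parameters and
input/output checksums makes reruns verifiable.  The "raw" statistics
tier is the adapter-trimmed, length-filtered read set; the "processed"
tier is the corrected and trimmed set, as in the published run overview
(correction runs once on the full dataset; per-subset processed tiers
filter on the source read's start time).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .align import AlignmentHit, SeqDB, map_reads
from .annotate import (ANNOTATION_COLUMNS, INTERNAL_INSERT, JUNCTION_CANDIDATE,
                       AnnotationRecord, annotate_all)
from .characterize import (InsertionSite, StatusCall, assemble_flanks,
                           call_status, delineate_sites,
                           order_insert_fragments, site_consensus)
from .cluster import Cluster, cluster_round1, cluster_round2, cluster_stats
from .correct import CorrectedRead, correction_pipeline
from .io import (PipelineConfig, Read, attach_times, read_fasta_db, read_fastq,
                 read_times_tsv, write_bed, write_fasta, write_fastq,
                 write_times_tsv, write_tsv)
from .preprocess import subset_by_time, trim_platform_adapters, trim_walking_adapter
from .simulate import SimConfig, simulate_run

log = logging.getLogger("walkseq")

STATS_COLUMNS = ["tier", "subset_h", "total_reads", "mapped_pct",
                 "mean_error_pct", "min_len", "max_len", "mean_len"]


def run_stats(raw_reads: list[Read], processed_reads: list[Read],
              raw_hits: dict[str, AlignmentHit],
              proc_hits: dict[str, AlignmentHit],
              subsets_h: list[float]) -> list[dict]:
    """One row per (tier, time subset): read counts, mapped fraction,
    mean per-base error, and length summary."""
    rows = []
    for tier, reads, hits in (("raw", raw_reads, raw_hits),
                              ("processed", processed_reads, proc_hits)):
        for h in subsets_h:
            sub = subset_by_time(reads, h) if reads else []
            n = len(sub)
            if n == 0:
                log.warning("run_stats: empty %s tier at %sh", tier, h)
                rows.append({"tier": tier, "subset_h": h, "total_reads": 0,
                             "mapped_pct": 0, "mean_error_pct": 0,
                             "min_len": 0, "max_len": 0, "mean_len": 0})
                continue
            mapped = [hits[r.id] for r in sub if r.id in hits]
            lens = [len(r.seq) for r in sub]
            err = float(np.mean([m.error_rate for m in mapped])) if mapped else 0.0
            rows.append({
                "tier": tier, "subset_h": h, "total_reads": n,
                "mapped_pct": round(100 * len(mapped) / n, 2),
                "mean_error_pct": round(100 * err, 2),
                "min_len": min(lens), "max_len": max(lens),
                "mean_len": round(float(np.mean(lens)), 1),
            })
    return rows


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    raw_reads: list[Read] = field(default_factory=list)
    processed: list[CorrectedRead] = field(default_factory=list)
    round1_all: list[Cluster] = field(default_factory=list)
    round1_retained: list[Cluster] = field(default_factory=list)
    round1_discarded: list[str] = field(default_factory=list)
    clusters: list[Cluster] = field(default_factory=list)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    class_summary: dict[str, int] = field(default_factory=dict)
    sites: list[InsertionSite] = field(default_factory=list)
    windows: dict[str, str] = field(default_factory=dict)
    status: dict[str, StatusCall] = field(default_factory=dict)
    flanks: dict[str, str] = field(default_factory=dict)
    layout: list[dict] = field(default_factory=list)
    stats: list[dict] = field(default_factory=list)
    raw_hits: dict[str, AlignmentHit] = field(default_factory=dict)
    proc_hits: dict[str, AlignmentHit] = field(default_factory=dict)
    sim_paths: dict[str, Path] = field(default_factory=dict)

    @property
    def delineated_sites(self) -> list[InsertionSite]:
        return [s for s in self.sites if s.delineation == "delineated"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def pipeline_run(config: PipelineConfig, outdir: str | Path,
                 reads_path: str | Path | None = None,
                 times_path: str | Path | None = None,
                 db_paths: dict[str, str | Path] | None = None,
                 reference_path: str | Path | None = None,
                 simulate: bool = False,
                 sim_config: SimConfig | None = None) -> PipelineResult:
    """Execute trim -> correct -> cluster -> annotate -> characterize ->
    status -> report, writing all artefacts plus a manifest to outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    res = PipelineResult(config, outdir)
    stage = "setup"
    try:
        if simulate:
            stage = "simulate"
            sc = sim_config or SimConfig(rng_seed=config.rng_seed)
            res.sim_paths = simulate_run(sc, outdir / "sim")
            reads_path = res.sim_paths["reads"]
            times_path = res.sim_paths["times"]
            db_paths = {k: res.sim_paths[f"{k}_db"]
                        for k in ("host", "vector", "element", "authorized")}
            reference_path = res.sim_paths["reference"]
        if reads_path is None or db_paths is None:
            raise ValueError("need reads and databases (or --simulate)")
        for key, p in {**db_paths, "reads": reads_path}.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"missing input for {key}: {p}")

        stage = "load"
        reads = read_fastq(reads_path)
        if times_path is not None:
            reads = attach_times(reads, read_times_tsv(times_path))
        host_db = SeqDB(read_fasta_db(db_paths["host"]), "host")
        vector_db = SeqDB(read_fasta_db(db_paths["vector"]), "vector")
        element_db = SeqDB(read_fasta_db(db_paths["element"]), "element")
        auth_db = SeqDB(read_fasta_db(db_paths["authorized"]), "authorized")
        patent_db = None
        if "patent" in db_paths:
            patent_db = SeqDB(read_fasta_db(db_paths["patent"]), "patent")

        stage = "trim"
        reads, prep = trim_platform_adapters(reads, config=config)
        reads, prep2 = trim_walking_adapter(reads, config)
        res.raw_reads = reads
        write_fastq(reads, outdir / "trimmed.fastq")
        write_times_tsv(reads, outdir / "trimmed_times.tsv")

        stage = "correct"
        res.processed = correction_pipeline(reads, config)
        proc_reads = [cr.read for cr in res.processed]
        write_fastq(proc_reads, outdir / "processed.fastq")
        write_times_tsv(proc_reads, outdir / "processed_times.tsv")

        stage = "cluster"
        retained, discarded, all_c = cluster_round1(proc_reads, config)
        reads_by_id = {r.id: r for r in proc_reads}
        clusters = cluster_round2(retained, reads_by_id, discarded, config)
        res.round1_all, res.round1_retained = all_c, retained
        res.round1_discarded, res.clusters = discarded, clusters
        write_tsv([{"cluster_id": c.id, "representative": c.representative,
                    "member": m, "round": c.round}
                   for c in clusters for m in c.members],
                  outdir / "clusters.tsv",
                  ["cluster_id", "representative", "member", "round"])
        write_fasta([(c.id, reads_by_id[c.representative].seq,
                      {"rep": c.representative, "n": c.size})
                     for c in clusters], outdir / "reps.fasta")

        stage = "annotate"
        res.annotations, res.class_summary = annotate_all(
            clusters, reads_by_id, host_db, vector_db, element_db, config)
        write_tsv([a.to_row() for a in res.annotations],
                  outdir / "annotations.tsv", ANNOTATION_COLUMNS)
        write_tsv([{"group": k, "n_clusters": v}
                   for k, v in sorted(res.class_summary.items())],
                  outdir / "summary.tsv", ["group", "n_clusters"])

        stage = "characterize"
        jrecs = [a for a in res.annotations if a.fate == JUNCTION_CANDIDATE]
        res.sites = delineate_sites(jrecs, host_db, vector_db, config)
        recs_by_cluster = {a.cluster_id: a for a in res.annotations}
        clusters_by_id = {c.id: c for c in clusters}
        for site in res.sites:
            if site.delineation != "delineated":
                continue
            cons, _rep_window = site_consensus(site, recs_by_cluster,
                                               clusters_by_id, reads_by_id,
                                               config)
            site.consensus = cons
            res.windows[site.name] = cons.seq
            reps_here = {cid: reads_by_id[recs_by_cluster[cid].rep_id].seq
                         for cid in site.supporting_clusters}
            _, flank = assemble_flanks(reps_here, config)
            res.flanks[site.name] = flank
        write_bed([s.to_bed(config.junction_window_bp) for s in res.sites
                   if s.delineation == "delineated"], outdir / "sites.bed")
        write_tsv([{"site": s.name, "contig": s.contig, "side": s.side,
                    "breakpoint_1based": s.breakpoint + 1,
                    "delineation": s.delineation,
                    "n_clusters": len(s.supporting_clusters),
                    "n_reads": s.n_reads, "note": s.note}
                   for s in res.sites], outdir / "sites.tsv",
                  ["site", "contig", "side", "breakpoint_1based", "delineation",
                   "n_clusters", "n_reads", "note"])
        write_fasta([(n, s) for n, s in res.windows.items()],
                    outdir / "junctions.fasta")
        write_fasta([(n, s) for n, s in res.flanks.items() if s],
                    outdir / "flanks.fasta")
        internal = [a for a in res.annotations if a.fate == INTERNAL_INSERT]
        res.layout = order_insert_fragments(internal, reads_by_id, res.flanks,
                                            vector_db, config)
        write_tsv(res.layout, outdir / "insert_layout.tsv",
                  ["fragment", "length", "anchor", "position", "strand"])

        stage = "status"
        if res.windows:
            res.status = call_status(res.windows, auth_db, patent_db, config)
        write_tsv([{"junction": n, "verdict": s.verdict,
                    "coverage": s.coverage, "db": s.db_name,
                    "subject": s.subject}
                   for n, s in sorted(res.status.items())],
                  outdir / "status.tsv",
                  ["junction", "verdict", "coverage", "db", "subject"])

        stage = "report"
        if reference_path is not None:
            ref_db = SeqDB(read_fasta_db(reference_path), "reference")
            res.raw_hits = map_reads(res.raw_reads, ref_db,
                                     config.map_word_size)
            res.proc_hits = map_reads(proc_reads, ref_db, config.map_word_size)
            res.stats = run_stats(res.raw_reads, proc_reads, res.raw_hits,
                                  res.proc_hits, list(config.time_subsets_h))
            write_tsv(res.stats, outdir / "run_stats.tsv", STATS_COLUMNS)

        stage = "manifest"
        manifest = {
            "config": {f.name: getattr(config, f.name)
                       for f in fields(PipelineConfig)},
            "counters": {
                "reads_in": prep.reads_in,
                "reads_after_trim": len(res.raw_reads),
                "reads_processed": len(res.processed),
                "clusters_round1": len(all_c),
                "clusters_retained": len(retained),
                "reads_discarded_round1": len(discarded),
                "clusters_round2": len(clusters),
                "sites_delineated": len(res.delineated_sites),
                "sites_suspect": sum(
                    s.delineation == "chimeric_suspect" for s in res.sites),
            },
            "checksums": {p.name: _sha256(p) for p in sorted(outdir.glob("*"))
                          if p.is_file()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                         default=str))
    except Exception as exc:  # noqa: BLE001 - annotate failures with the stage
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    log.info("pipeline complete: %d delineated sites", len(res.delineated_sites))
    return res
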