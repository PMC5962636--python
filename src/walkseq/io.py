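"""Readers/writers for the standard formats the pipeline touches, plus configuration.

All genomic intervals are 0-based half-open internally; human-readable
reports convert to 1-based inclusive.  FASTQ qualities are Phred+33.
"""

from __future__ import annotations

import gzip
import logging
import sys
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("walkseq")

VALID_BASES = set("ACGTN")

#: the 57-bp DNA-walking tagging adapter ligated to the unknown end of
#: every amplicon (universal-tag primer sequence).
WALKING_ADAPTER = "GGAAGCAGTGGTATCAACGCAGAGTGGCCATTACGGCCGAACACGCGTCGTTTACCT"

#: bundled default sequencer (platform) adapters; synthetic stand-ins for
#: the ligation-kit adapter ends.
PLATFORM_ADAPTERS = (
    "AATGTACTTCGTTCAGTTACGTATTGCTAGGT",
    "AGCAATACGTAACTGAACGAAGTACATTCGCA",
)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="[walkseq %(levelname)s] %(message)s",
        force=True,
    )


@dataclass(slots=True)
class Read:
    """A sequencing read flowing through preprocessing/correction."""

    id: str
    seq: str
    qual: list[int] | None = None
    start_time_s: float | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"read {self.id!r}: empty sequence")
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"read {self.id!r}: invalid bases {sorted(bad)}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if self.start_time_s is not None and self.start_time_s < 0:
            raise ValueError(f"read {self.id!r}: negative start time")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(slots=True)
class PipelineConfig:
    """Flat pipeline configuration; one key per tunable threshold.

    Defaults are the study preset: every value traces to the published
    workflow (adapter-removal tolerances, the 700-bp correction floor,
    the 95%/99% clustering thresholds, word size 64, the 98% class-1
    cutoff, the 100-bp junction window, consensus coverage 2, and the
    90%/50% authorization-status operating points).
    """

    platform_adapter_min_trim_bp: int = 4
    platform_middle_threshold: float = 0.75
    platform_end_threshold: float = 0.75
    walking_adapter_seq: str = WALKING_ADAPTER
    walking_adapter_error_rate: float = 0.30
    walking_adapter_min_match_bp: int = 5
    min_read_len_post_trim_bp: int = 100
    corr_min_read_len_bp: int = 700
    corr_min_overlap_bp: int = 700
    corr_kmer: int = 12
    corr_min_shared_kmers: int = 3
    corr_max_evidence: int = 16
    corr_min_support: int = 2
    clust_min_identity: float = 0.95
    clust_round1_min_length_ratio: float = 0.99
    clust_round2_min_cov_of_shorter: float = 0.99
    clust_min_cluster_size: int = 6
    db_word_size: int = 64
    map_word_size: int = 15
    overhang_word_size: int = 16
    status_word_size: int = 16
    class1_min_query_cov: float = 0.98
    class2_element_min_overlap: float = 0.80
    near_full_band_lo: float = 0.90
    junction_window_bp: int = 100
    consensus_min_cov: int = 2
    status_known_min_query_cov: float = 0.90
    status_unknown_max_query_cov: float = 0.50
    site_group_tol_bp: int = 5
    site_locus_gap_bp: int = 1000
    site_modal_min_frac: float = 0.70
    site_max_fusion_partners: int = 3
    flank_min_overlap_bp: int = 40
    flank_min_identity: float = 0.94
    time_subsets_h: list[float] = field(default_factory=lambda: [1, 2, 4, 8, 16, 24])
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "platform_middle_threshold",
            "platform_end_threshold",
            "walking_adapter_error_rate",
            "clust_min_identity",
            "clust_round1_min_length_ratio",
            "clust_round2_min_cov_of_shorter",
            "class1_min_query_cov",
            "class2_element_min_overlap",
            "near_full_band_lo",
            "status_known_min_query_cov",
            "status_unknown_max_query_cov",
            "site_modal_min_frac",
            "flank_min_identity",
        ):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"config {name}={v}: must be in (0, 1]")
        for name in (
            "platform_adapter_min_trim_bp",
            "walking_adapter_min_match_bp",
            "min_read_len_post_trim_bp",
            "corr_min_read_len_bp",
            "corr_min_overlap_bp",
            "corr_kmer",
            "clust_min_cluster_size",
            "db_word_size",
            "map_word_size",
            "junction_window_bp",
            "consensus_min_cov",
            "flank_min_overlap_bp",
        ):
            v = getattr(self, name)
            if not (isinstance(v, int) and v > 0):
                raise ValueError(f"config {name}={v}: must be a positive integer")
        ts = list(self.time_subsets_h)
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise ValueError("time_subsets_h must be strictly increasing")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def with_overrides(self, **kw) -> "PipelineConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# FASTQ / FASTA

def _open(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: str | Path) -> list[Read]:
    """Parse a (possibly gzipped) FASTQ file into Read objects.

    Malformed records raise with the 1-based record index in the message.
    """
    reads: list[Read] = []
    seen: set[str] = set()
    with _open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                break
            idx += 1
            seq = fh.readline().rstrip("\n")
            sep = fh.readline()
            qual = fh.readline().rstrip("\n")
            if not header.startswith("@") or not sep.startswith("+") or not qual:
                raise ValueError(f"{path}: malformed FASTQ record {idx}")
            if len(seq) != len(qual):
                raise ValueError(
                    f"{path}: record {idx}: sequence/quality length mismatch"
                )
            rid = header[1:].split()[0]
            if rid in seen:
                raise ValueError(f"{path}: duplicate read id {rid!r} (record {idx})")
            seen.add(rid)
            reads.append(Read(rid, seq, [ord(c) - 33 for c in qual]))
    return reads


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with _open(path, "wt") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else [20] * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n")
            fh.write("".join(chr(min(q, 60) + 33) for q in qual) + "\n")


def read_fasta_db(path: str | Path) -> list[tuple[str, str, dict[str, str]]]:
    """Parse FASTA; tokens after the id are parsed as key=value tags."""
    out: list[tuple[str, str, dict[str, str]]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        tags = {}
        for token in rec.description.split()[1:]:
            if "=" in token:
                k, v = token.split("=", 1)
                tags[k] = v
        out.append((rec.id, str(rec.seq).upper(), tags))
    return out


def write_fasta(
    records: Iterable[tuple[str, str] | tuple[str, str, dict]],
    path: str | Path,
    width: int = 80,
) -> None:
    recs = []
    for rec in records:
        rid, seq = rec[0], rec[1]
        tags = rec[2] if len(rec) > 2 else {}
        desc = " ".join(f"{k}={v}" for k, v in tags.items())
        recs.append(SeqRecord(Seq(seq), id=rid, description=desc))
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# BED / TSV

@dataclass(slots=True)
class BedInterval:
    contig: str
    start: int
    end: int
    name: str = "."
    score: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"interval {self.name}: start {self.start} > end {self.end}"
            )


def write_bed(intervals: Iterable[BedInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.contig}\t{iv.start}\t{iv.end}\t{iv.name}\t{iv.score}\t{iv.strand}\n"
            )


def read_bed(path: str | Path) -> list[BedInterval]:
    out = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        f = line.split("\t")
        out.append(
            BedInterval(f[0], int(f[1]), int(f[2]), *(f[3:6] if len(f) >= 6 else []))
        )
    return out


def write_tsv(rows: Sequence[dict], path: str | Path, columns: Sequence[str] | None = None) -> None:
    """Write a list of dict rows as a header-ed TSV; empty input writes header only."""
    if columns is None:
        columns = list(rows[0].keys()) if rows else []
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in columns) + "\n")


def read_tsv(path: str | Path) -> list[dict[str, str]]:
    lines = Path(path).read_text().splitlines()
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:] if ln]


def read_times_tsv(path: str | Path) -> dict[str, float]:
    """Sidecar TSV of per-read sequencing start times (id, start_time_s)."""
    return {row["id"]: float(row["start_time_s"]) for row in read_tsv(path)}


def write_times_tsv(reads: Iterable[Read], path: str | Path) -> None:
    write_tsv(
        [
            {"id": r.id, "start_time_s": f"{r.start_time_s:.1f}"}
            for r in reads
            if r.start_time_s is not None
        ],
        path,
        columns=["id", "start_time_s"],
    )


def attach_times(reads: Iterable[Read], times: dict[str, float]) -> list[Read]:
    out = []
    for r in reads:
        if r.id in times:
            r.start_time_s = times[r.id]
        out.append(r)
    return out
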