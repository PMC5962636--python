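"""Synthetic transgenic host, DNA-walking amplicons and noisy nanopore reads.

The generator emulates the study library: a transgenic cassette
(LB - t35S - hpt - p35S - pUBI - cry1B - tNOS - RB) inserted at two host
loci, amplicons of 200 bp - 4 kbp anchored bidirectionally at the p35S,
tNOS and t35S elements and ending at random walking-tag positions, the
57-bp walking adapter on the tag end, ~13% per-base raw error with a
homopolymer multiplier, PCR/sequencing chimeras, and a non-linear read
accumulation profile over 24 h (knots taken from the published run, with
~68% of reads before 8 h).  Every read carries ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .io import (
    PLATFORM_ADAPTERS,
    WALKING_ADAPTER,
    BedInterval,
    Read,
    revcomp,
    write_bed,
    write_fasta,
    write_fastq,
    write_times_tsv,
    write_tsv,
)

log = logging.getLogger("walkseq")

_BASES = np.array(list("ACGT"))

#: fixed seed for the element/vector sequences themselves — the cassette
#: is a property of the simulated organism, not of a particular run.
_ELEMENT_SEED = 711

#: cassette element order and lengths (bp)
_CASSETTE_LAYOUT = [
    ("LB", 25), ("t35S", 200), ("hpt", 1000), ("p35S", 350),
    ("pUBI", 600), ("cry1B", 1800), ("tNOS", 250), ("RB", 25),
]
_ANCHORS = ("p35S", "tNOS", "t35S")


@dataclass(slots=True)
class ElementSpec:
    """A transgenic cassette element; anchors are targeted by walking primers."""

    name: str
    seq: str
    is_anchor: bool = False


@dataclass(slots=True)
class JunctionTruth:
    contig: str
    side: str              # LB or RB
    host_pos: int          # breakpoint in pre-insertion host coordinates
    post_pos: int          # breakpoint in post-insertion coordinates
    window_start: int      # 100-bp window on the post-insertion contig
    window_end: int
    window_seq: str
    clipped: bool = False

    @property
    def name(self) -> str:
        return f"{self.contig}-{self.side}"


@dataclass(slots=True)
class GenomeTruth:
    host: dict[str, str]
    cassette: str
    element_spans: dict[str, tuple[int, int]]   # cassette coordinates
    insertions: list[tuple[str, int, str]]      # (contig, host position, orientation)
    junctions: list[JunctionTruth]
    post: dict[str, str]


@dataclass(slots=True)
class SimConfig:
    """Study-condition knobs for the synthetic library."""

    host_contig_lengths: list[int] = field(default_factory=lambda: [30000, 30000])
    n_insertions: int = 2
    insertion_positions: list[int] | None = None
    sub_rate: float = 0.0585
    ins_rate: float = 0.0390
    del_rate: float = 0.0325
    homopolymer_multiplier: float = 2.0
    homopolymer_min_run: int = 4
    chimera_fraction: float = 0.02
    amplicon_len_range: list[int] = field(default_factory=lambda: [200, 4000])
    amplicons_per_anchor_direction: int = 6
    reads_per_amplicon: int = 90
    nonspecific_amplicons: int = 4
    chimera_families: int = 1
    chimera_family_types: int = 3
    chimera_family_reads_per_type: int = 24
    platform_adapter_prob: float = 0.7
    accumulation_hours: list[float] = field(default_factory=lambda: [1, 2, 4, 8, 16, 24])
    accumulation_cumfrac: list[float] = field(
        default_factory=lambda: [0.146, 0.299, 0.476, 0.676, 0.953, 1.0])
    authorized_junction_names: list[str] | None = None   # None -> both RB junctions
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_rate", "ins_rate", "del_rate", "chimera_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"sim config {name}={v}: must be in [0, 1)")
        lo, hi = self.amplicon_len_range
        if not (1 <= lo <= hi):
            raise ValueError("amplicon_len_range must satisfy 1 <= lo <= hi")
        if len(self.accumulation_hours) != len(self.accumulation_cumfrac):
            raise ValueError("accumulation knots and fractions differ in length")

    @property
    def total_error_rate(self) -> float:
        return self.sub_rate + self.ins_rate + self.del_rate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(slots=True)
class Amplicon:
    id: str
    seq: str                       # genomic part + walking adapter on tag end
    contig: str
    start: int                     # interval of the genomic part (post coords)
    end: int
    direction: str                 # F (rightward) / R (leftward) / N (nonspecific)
    anchor: str
    adapter_side: str              # 'start' or 'end'
    chimera_family: str = ""
    clip_pos: int = -1             # family only: host-side clip position


@dataclass(slots=True)
class SimulatedRead:
    read: Read
    amplicon_id: str
    contig: str
    start: int
    end: int
    strand: str
    is_chimera: bool = False
    chimera_family: str = ""
    chimera_parts: str = ""
    n_errors: int = 0


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, n))


def _markov_contig(rng: np.random.Generator, n: int) -> str:
    """Host contig from an order-3 Markov chain (avoids pathological
    low-complexity stretches that a uniform i.i.d. draw can produce)."""
    probs = rng.dirichlet(np.full(4, 5.0), size=64)
    cum = probs.cumsum(axis=1)
    out = np.empty(n, np.int64)
    out[:3] = rng.integers(0, 4, 3)
    u = rng.random(n)
    for i in range(3, n):
        state = out[i - 3] * 16 + out[i - 2] * 4 + out[i - 1]
        out[i] = np.searchsorted(cum[state], u[i], side="right")
    return "".join(_BASES[np.minimum(out, 3)])


def default_elements() -> list[ElementSpec]:
    """The bundled synthetic cassette elements (fixed sequences)."""
    rng = np.random.default_rng(_ELEMENT_SEED)
    out = []
    for name, length in _CASSETTE_LAYOUT:
        out.append(ElementSpec(name, _random_seq(rng, length), name in _ANCHORS))
    return out


def build_cassette(elements: Sequence[ElementSpec]
                   ) -> tuple[str, dict[str, tuple[int, int]]]:
    by_name = {e.name: e for e in elements}
    seqs, spans, pos = [], {}, 0
    for name, _ in _CASSETTE_LAYOUT:
        if name not in by_name:
            raise ValueError(f"cassette element {name!r} missing")
        s = by_name[name].seq
        spans[name] = (pos, pos + len(s))
        seqs.append(s)
        pos += len(s)
    return "".join(seqs), spans


def build_truth_genome(cfg: SimConfig, elements: Sequence[ElementSpec] | None = None
                       ) -> GenomeTruth:
    """Host contigs + cassette insertions + per-junction truth records.

    Each insertion replaces zero host bases; every insertion yields
    exactly one LB and one RB junction record with a 100-bp window
    centred on the breakpoint (clipped and flagged at contig edges).
    A deliberate low-complexity tract is planted just outside the last
    RB junction to exercise homopolymer-biased errors.
    """
    if elements is None:
        elements = default_elements()
    rng = np.random.default_rng(cfg.rng_seed + 1)
    cassette, spans = build_cassette(elements)
    host: dict[str, str] = {}
    for i, length in enumerate(cfg.host_contig_lengths):
        host[f"contig{i + 1}"] = _markov_contig(rng, length)
    contigs = list(host)
    if cfg.n_insertions > 0 and not contigs:
        raise ValueError("insertions require at least one host contig")
    positions = cfg.insertion_positions
    if positions is None:
        positions = [
            int(rng.integers(int(0.4 * len(host[contigs[i % len(contigs)]])),
                             int(0.6 * len(host[contigs[i % len(contigs)]]))))
            for i in range(cfg.n_insertions)
        ]
    insertions: list[tuple[str, int, str]] = []
    for i in range(cfg.n_insertions):
        contig = contigs[i % len(contigs)]
        p = positions[i]
        if not 0 <= p <= len(host[contig]):
            raise ValueError(f"insertion position {p} out of range on {contig}")
        insertions.append((contig, p, "+"))

    if insertions and cfg.homopolymer_multiplier > 1:
        # plant a low-complexity tract 150 bp outside the last RB junction
        contig, p, _ = insertions[-1]
        tract_at = min(p + 150, len(host[contig]) - 30)
        s = host[contig]
        host[contig] = s[:tract_at] + "A" * 18 + "TA" * 6 + s[tract_at + 30:]

    post = dict(host)
    junctions: list[JunctionTruth] = []
    # at most one insertion per contig in the default scenario; general case
    # handled by inserting right-to-left so earlier positions stay valid
    for contig in contigs:
        here = sorted([ins for ins in insertions if ins[0] == contig],
                      key=lambda t: -t[1])
        seq = host[contig]
        for _, p, _orient in here:
            seq = seq[:p] + cassette + seq[p:]
        post[contig] = seq
        shift = 0
        for _, p, _orient in sorted(here, key=lambda t: t[1]):
            lb = p + shift
            rb = p + shift + len(cassette)
            for side, bp in (("LB", lb), ("RB", rb)):
                w0, w1 = bp - 50, bp + 50
                clipped = w0 < 0 or w1 > len(seq)
                w0c, w1c = max(0, w0), min(len(seq), w1)
                junctions.append(JunctionTruth(
                    contig, side, p, bp, w0c, w1c, seq[w0c:w1c], clipped))
            shift += len(cassette)
    return GenomeTruth(host, cassette, spans, insertions, junctions, post)


# ---------------------------------------------------------------------------
# amplicons

def enumerate_amplicons(truth: GenomeTruth, cfg: SimConfig,
                        rng: np.random.Generator | None = None) -> list[Amplicon]:
    """Amplicons anchored at each anchor element in both directions, ending
    at random walking-tag positions; the 57-bp adapter sits on the tag end.

    With zero insertions (negative control) the walking primers have no
    target: only nonspecific host amplicons are produced.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 2)
    lo, hi = cfg.amplicon_len_range
    out: list[Amplicon] = []
    n = 0
    if truth.insertions:
        missing = [a for a in _ANCHORS if a not in truth.element_spans]
        if missing:
            raise ValueError(f"anchor elements absent from cassette: {missing}")
    clen = len(truth.cassette)
    # cassette offset of each insertion on the post contig
    offsets: dict[str, list[int]] = {}
    for contig in truth.post:
        here = sorted(p for c, p, _ in truth.insertions if c == contig)
        offsets[contig] = [p + i * clen for i, p in enumerate(here)]
    for contig, offs in offsets.items():
        seq = truth.post[contig]
        for off in offs:
            for anchor in _ANCHORS:
                a0, a1 = truth.element_spans[anchor]
                anchor_len = a1 - a0
                for direction in "FR":
                    for _ in range(cfg.amplicons_per_anchor_direction):
                        length = int(rng.integers(max(lo, anchor_len + 20), hi + 1))
                        if direction == "F":
                            s = off + a0
                            e = min(s + length, len(seq))
                            part = seq[s:e] + WALKING_ADAPTER
                            side = "end"
                        else:
                            e = off + a1
                            s = max(e - length, 0)
                            part = WALKING_ADAPTER + seq[s:e]
                            side = "start"
                        out.append(Amplicon(
                            f"amp{n:04d}_{contig}_{anchor}{direction}",
                            part, contig, s, e, direction, anchor, side))
                        n += 1
    # nonspecific host amplicons (aspecific PCR background)
    contigs = list(truth.post)
    for _ in range(cfg.nonspecific_amplicons):
        contig = contigs[int(rng.integers(len(contigs)))]
        seq = truth.post[contig]
        length = int(rng.integers(lo, hi + 1))
        forbidden = [(o - length - 100, o + clen + length + 100)
                     for o in offsets.get(contig, [])]
        for _attempt in range(50):
            s = int(rng.integers(0, max(1, len(seq) - length)))
            if all(not (f0 <= s <= f1) for f0, f1 in forbidden):
                break
        e = min(s + length, len(seq))
        out.append(Amplicon(f"amp{n:04d}_{contig}_nonspec",
                            seq[s:e] + WALKING_ADAPTER, contig, s, e,
                            "N", "none", "end"))
        n += 1
    return out


def chimera_family_amplicons(truth: GenomeTruth, cfg: SimConfig,
                             rng: np.random.Generator | None = None
                             ) -> list[Amplicon]:
    """Planted scattered-clip chimera family: one host locus fused to
    several distinct cassette fragments at clip points spread over tens
    of bp, mimicking a PCR-recombination hotspot.  Each type is amplified
    enough to survive the abundance filter, so suppression must come from
    the scatter rule downstream."""
    if cfg.chimera_families == 0 or not truth.insertions:
        return []
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 3)
    contig, p0, _ = truth.insertions[0]
    locus = max(2000, p0 - 8000)
    out = []
    clip_offsets = [0, 37, 81, 140, 210]
    for fam in range(cfg.chimera_families):
        for t in range(cfg.chimera_family_types):
            clip = locus + clip_offsets[t % len(clip_offsets)] + fam * 400
            host_len = int(rng.integers(500, 900))
            host_part = truth.post[contig][clip - host_len:clip]
            frag_start = 100 + 450 * t
            frag_len = int(rng.integers(500, 800))
            frag = truth.cassette[frag_start:frag_start + frag_len]
            out.append(Amplicon(
                f"chifam{fam}_{t}", host_part + frag + WALKING_ADAPTER,
                contig, clip - host_len, clip, "F", "none", "end",
                chimera_family=f"cf{fam}", clip_pos=clip))
    return out


# ---------------------------------------------------------------------------
# reads

def _homopolymer_mask(codes: np.ndarray, min_run: int) -> np.ndarray:
    n = len(codes)
    mask = np.zeros(n, bool)
    if n == 0:
        return mask
    change = np.flatnonzero(np.diff(codes)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    for s, e in zip(starts, ends):
        if e - s >= min_run:
            mask[s:e] = True
    return mask


def inject_errors(seq: str, cfg: SimConfig, rng: np.random.Generator
                  ) -> tuple[str, list[int], int]:
    """Apply i.i.d. substitution/insertion/deletion noise with the
    homopolymer multiplier; qualities are consistent with the draw
    (injected-error bases get low Phred scores)."""
    from .align import encode  # local import to avoid cycle at import time

    codes = encode(seq).astype(np.int64)
    n = len(codes)
    mult = np.ones(n)
    mult[_homopolymer_mask(codes, cfg.homopolymer_min_run)] = cfg.homopolymer_multiplier
    p_sub = np.minimum(cfg.sub_rate * mult, 0.3)
    p_ins = np.minimum(cfg.ins_rate * mult, 0.2)
    p_del = np.minimum(cfg.del_rate * mult, 0.2)
    u = rng.random(n)
    ev = np.zeros(n, np.int8)  # 0 none, 1 sub, 2 ins-after, 3 del
    ev[u < p_sub + p_ins + p_del] = 3
    ev[u < p_sub + p_ins] = 2
    ev[u < p_sub] = 1
    counts = np.where(ev == 3, 0, np.where(ev == 2, 2, 1))
    idx = np.repeat(np.arange(n), counts)
    out = codes[idx]
    errflag = np.zeros(len(out), bool)
    # substituted first copies
    pos_of_first = np.cumsum(counts) - counts     # output index of each input base
    subs = np.flatnonzero(ev == 1)
    out[pos_of_first[subs]] = (codes[subs] + rng.integers(1, 4, len(subs))) % 4
    errflag[pos_of_first[subs]] = True
    ins = np.flatnonzero(ev == 2)
    ins_out = pos_of_first[ins] + 1               # the inserted slot
    out[ins_out] = rng.integers(0, 4, len(ins))
    errflag[ins_out] = True
    qual = rng.integers(9, 17, len(out))
    qual[errflag] = rng.integers(3, 7, int(errflag.sum()))
    n_err = int((ev > 0).sum())
    return "".join(_BASES[np.minimum(out, 3)]), qual.tolist(), n_err


def _sample_times(n: int, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    hours = np.concatenate(([0.0], np.asarray(cfg.accumulation_hours, float)))
    frac = np.concatenate(([0.0], np.asarray(cfg.accumulation_cumfrac, float)))
    u = rng.random(n)
    seg = np.searchsorted(frac, u, side="right") - 1
    seg = np.clip(seg, 0, len(hours) - 2)
    f0, f1 = frac[seg], frac[seg + 1]
    h0, h1 = hours[seg], hours[seg + 1]
    t = h0 + (u - f0) / np.maximum(f1 - f0, 1e-12) * (h1 - h0)
    return t * 3600.0


def simulate_reads(amplicons: Sequence[Amplicon], cfg: SimConfig,
                   rng: np.random.Generator | None = None
                   ) -> list[SimulatedRead]:
    """One noisy read per draw from each amplicon, plus random chimeras
    joining two amplicon fragments tail-to-head (no adapter at the join)."""
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 4)
    if not amplicons:
        log.warning("simulate_reads: no amplicons, no reads generated")
        return []
    jobs: list[tuple[Amplicon, bool]] = []
    for amp in amplicons:
        nreads = (cfg.chimera_family_reads_per_type if amp.chimera_family
                  else cfg.reads_per_amplicon)
        jobs += [(amp, False)] * nreads
    n_regular = len(jobs)
    n_chim = int(np.floor(cfg.chimera_fraction * n_regular))
    regular_pool = [a for a in amplicons if not a.chimera_family]
    out: list[SimulatedRead] = []
    times = _sample_times(n_regular + n_chim, cfg, rng)
    order = rng.permutation(n_regular + n_chim)
    ridx = 0

    def finish(template: str, meta: dict) -> None:
        nonlocal ridx
        seq = template
        if rng.random() < cfg.platform_adapter_prob:
            seq = PLATFORM_ADAPTERS[0] + seq
        if rng.random() < cfg.platform_adapter_prob:
            seq = seq + PLATFORM_ADAPTERS[1]
        strand = "+"
        if rng.random() < 0.5:
            seq = revcomp(seq)
            strand = "-"
        noisy, qual, nerr = inject_errors(seq, cfg, rng)
        if not noisy:
            return
        t = float(times[order[ridx]])
        out.append(SimulatedRead(
            Read(f"r{ridx:06d}", noisy, qual, t), meta["amp"], meta["contig"],
            meta["start"], meta["end"], strand, meta["is_chimera"],
            meta["family"], meta["parts"], nerr))
        ridx += 1

    for amp, _ in jobs:
        finish(amp.seq, {
            "amp": amp.id, "contig": amp.contig, "start": amp.start,
            "end": amp.end, "is_chimera": bool(amp.chimera_family),
            "family": amp.chimera_family, "parts": ""})
    for _ in range(n_chim):
        if len(regular_pool) < 2:
            break
        ia, ib = rng.choice(len(regular_pool), 2, replace=False)
        a, b = regular_pool[ia], regular_pool[ib]
        cut_a = int(rng.integers(100, max(101, len(a.seq) - 100)))
        cut_b = int(rng.integers(100, max(101, len(b.seq) - 100)))
        template = a.seq[:cut_a] + b.seq[cut_b:]
        finish(template, {
            "amp": f"{a.id}|{b.id}", "contig": a.contig, "start": a.start,
            "end": a.end, "is_chimera": True, "family": "",
            "parts": f"{a.id}:0-{cut_a};{b.id}:{cut_b}-{len(b.seq)}"})
    return out


# ---------------------------------------------------------------------------
# mini databases and full run

def write_mini_databases(truth: GenomeTruth, elements: Sequence[ElementSpec],
                         cfg: SimConfig, outdir: str | Path,
                         rng: np.random.Generator | None = None) -> dict[str, Path]:
    """Local FASTA stand-ins for the public databases:

    host/plant DB   host contigs plus decoy plant contigs, one of which
                    embeds the pUBI element verbatim (exercises class 2A);
    vector DB       the cassette and a synthetic vector backbone;
    element DB      each cassette element;
    authorized DB   a configurable subset of true junction windows
                    (default: the two RB junctions, as in the published
                    control where only right-border junctions were known).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed + 5)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_name = {e.name: e for e in elements}

    host_recs = [(cid, seq, {"kind": "host"}) for cid, seq in truth.host.items()]
    d1 = _random_seq(rng, 4000)
    pubi = by_name["pUBI"].seq
    decoy1 = d1[:1500] + pubi + d1[1500:]
    host_recs.append(("decoy_zea", decoy1, {"kind": "plant", "element": "pUBI"}))
    host_recs.append(("decoy_plant2", _random_seq(rng, 3000), {"kind": "plant"}))
    host_db = outdir / "host_db.fasta"
    write_fasta(host_recs, host_db)

    vector_db = outdir / "vector_db.fasta"
    write_fasta([
        ("cassette", truth.cassette, {"kind": "construct"}),
        ("backbone", _random_seq(rng, 3000), {"kind": "vector"}),
    ], vector_db)

    element_db = outdir / "element_db.fasta"
    write_fasta([(e.name, e.seq, {"kind": "element"}) for e in elements], element_db)

    names = cfg.authorized_junction_names
    if names is None:
        names = [j.name for j in truth.junctions if j.side == "RB"]
    auth_db = outdir / "authorized_db.fasta"
    write_fasta([
        (f"auth_{j.name}", j.window_seq, {"kind": "junction"})
        for j in truth.junctions if j.name in names
    ], auth_db)
    return {"host": host_db, "vector": vector_db,
            "element": element_db, "authorized": auth_db}


def write_reference(truth: GenomeTruth, outdir: str | Path,
                    flank: int = 500) -> Path:
    """Mapping reference: each insert plus flanking host sequence."""
    outdir = Path(outdir)
    recs = []
    clen = len(truth.cassette)
    seen: dict[str, int] = {}
    for contig, p, _ in truth.insertions:
        n_before = seen.get(contig, 0)
        off = p + n_before * clen
        seen[contig] = n_before + 1
        seq = truth.post[contig]
        s = max(0, off - flank)
        e = min(len(seq), off + clen + flank)
        recs.append((f"insert_region_{contig}_{p}", seq[s:e],
                     {"kind": "reference", "contig": contig, "offset": s}))
    path = outdir / "reference.fasta"
    write_fasta(recs, path)
    return path


def simulate_run(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Full generator: truth genome, amplicons, reads, sidecar files and
    mini databases, all under ``outdir``.  Deterministic given rng_seed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    elements = default_elements()
    truth = build_truth_genome(cfg, elements)
    rng = np.random.default_rng(cfg.rng_seed + 2)
    amplicons = enumerate_amplicons(truth, cfg, rng)
    amplicons += chimera_family_amplicons(truth, cfg, rng)
    sim_reads = simulate_reads(amplicons, cfg, np.random.default_rng(cfg.rng_seed + 4))

    paths: dict[str, Path] = {}
    paths["reads"] = outdir / "reads.fastq"
    write_fastq([sr.read for sr in sim_reads], paths["reads"])
    paths["times"] = outdir / "reads_times.tsv"
    write_times_tsv([sr.read for sr in sim_reads], paths["times"])
    paths["truth_reads"] = outdir / "truth_reads.tsv"
    write_tsv([
        {"id": sr.read.id, "amplicon": sr.amplicon_id, "contig": sr.contig,
         "start": sr.start, "end": sr.end, "strand": sr.strand,
         "is_chimera": int(sr.is_chimera), "chimera_family": sr.chimera_family,
         "chimera_parts": sr.chimera_parts, "n_errors": sr.n_errors,
         "start_time_s": f"{sr.read.start_time_s:.1f}"}
        for sr in sim_reads
    ], paths["truth_reads"])
    paths["truth_junctions"] = outdir / "truth_junctions.bed"
    write_bed([
        BedInterval(j.contig, j.window_start, j.window_end,
                    f"{j.name}|host_pos={j.host_pos}|post_pos={j.post_pos}",
                    ".", "+")
        for j in truth.junctions
    ], paths["truth_junctions"])
    paths["truth_windows"] = outdir / "truth_junction_windows.fasta"
    write_fasta([(j.name, j.window_seq,
                  {"side": j.side, "host_pos": j.host_pos}) for j in truth.junctions],
                paths["truth_windows"])
    dbs = write_mini_databases(truth, elements, cfg, outdir,
                               np.random.default_rng(cfg.rng_seed + 5))
    paths.update({f"{k}_db": v for k, v in dbs.items()})
    paths["reference"] = write_reference(truth, outdir)
    paths["amplicons"] = outdir / "amplicons.fasta"
    write_fasta([(a.id, a.seq, {"contig": a.contig, "start": a.start,
                                "end": a.end, "direction": a.direction})
                 for a in amplicons], paths["amplicons"])
    log.info("simulated %d reads from %d amplicons", len(sim_reads), len(amplicons))
    return paths
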