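"""Reference-free classification of cluster representatives.

Each representative is searched against a plant/host genomic database
and a non-host database (vectors and constructs), both with a stringent
exact word size (default 64), and assigned to one of four classes:

  class 1   near-full-length plant hit (>= 98% of the query): host
            background, uninformative;
  class 2A  partial plant hit explained by a transgenic element
            (promoter/terminator similarity to donor genomes): insert-
            internal if it also hits the non-host DB, else no information;
  class 2B  partial plant hit NOT explained by elements: with a non-host
            hit it is a junction candidate (host flank + insert), without
            one it carries no information;
  class 3   no plant hit: insert-internal if the non-host DB hits, else
            no information.

Representatives whose plant hit is nearly full length (by default 90-98%
of the query) get their unaligned overhangs searched against the vector
DB with a reduced word size; if the overhangs show no vector sequence the
cluster is reassigned to class 1 (the automated analogue of the published
manual overhang review of ~92%-coverage chloroplast hits).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .align import AlignmentHit, SeqDB, best_hit, search
from .cluster import Cluster
from .io import PipelineConfig, Read

log = logging.getLogger("walkseq")

UNINFORMATIVE = "uninformative"
INTERNAL_INSERT = "internal_insert"
JUNCTION_CANDIDATE = "junction_candidate"
NO_INFORMATION = "no_information"


@dataclass(slots=True)
class AnnotationRecord:
    cluster_id: str
    rep_id: str
    class_label: str                    # "1", "2A", "2B", "3"
    fate: str
    plant_hit: AlignmentHit | None
    nonhost_hit: AlignmentHit | None
    element_overlap: float              # fraction of plant-hit interval
    overhang_checked: bool
    overhang_has_vector: bool | None
    n_reads: int

    def to_row(self) -> dict:
        return {
            "cluster_id": self.cluster_id,
            "rep_id": self.rep_id,
            "class": self.class_label,
            "fate": self.fate,
            "plant_hit": self.plant_hit.sid if self.plant_hit else "",
            "plant_qcov": f"{self.plant_hit.qcov:.3f}" if self.plant_hit else "",
            "nonhost_hit": self.nonhost_hit.sid if self.nonhost_hit else "",
            "element_overlap": f"{self.element_overlap:.2f}",
            "n_reads": self.n_reads,
        }


ANNOTATION_COLUMNS = ["cluster_id", "rep_id", "class", "fate", "plant_hit",
                      "plant_qcov", "nonhost_hit", "element_overlap", "n_reads"]


def decide_class(plant_cov: float | None, element_frac: float,
                 has_nonhost: bool, overhang_has_vector: bool | None,
                 config: PipelineConfig | None = None) -> tuple[str, str]:
    """The classification decision tree as a total, deterministic pure
    function of the hit configuration.

    ``plant_cov`` is the best plant-DB hit's query coverage (None = no
    hit); ``element_frac`` the fraction of the plant-hit query interval
    covered by element-DB hits; ``overhang_has_vector`` the overhang
    check result (None = band not entered / not checked, which leaves
    the class-2 assignment standing).
    """
    if config is None:
        config = PipelineConfig()
    if plant_cov is None:
        return ("3", INTERNAL_INSERT if has_nonhost else NO_INFORMATION)
    if plant_cov >= config.class1_min_query_cov:
        return ("1", UNINFORMATIVE)
    if (config.near_full_band_lo <= plant_cov < config.class1_min_query_cov
            and overhang_has_vector is False):
        return ("1", UNINFORMATIVE)
    if element_frac >= config.class2_element_min_overlap:
        return ("2A", INTERNAL_INSERT if has_nonhost else NO_INFORMATION)
    return ("2B", JUNCTION_CANDIDATE if has_nonhost else NO_INFORMATION)


def split_class2(element_frac: float, config: PipelineConfig | None = None
                 ) -> str:
    """2A when the plant-hit query interval is mostly (>= 80%) explained
    by transgenic-element hits, else 2B."""
    if config is None:
        config = PipelineConfig()
    return "2A" if element_frac >= config.class2_element_min_overlap else "2B"


def _element_overlap(rep_seq: str, plant: AlignmentHit, element_db: SeqDB,
                     config: PipelineConfig) -> float:
    """Fraction of the plant-hit query interval covered by element hits."""
    hits = search("rep", rep_seq, element_db, config.db_word_size)
    if not hits:
        return 0.0
    lo, hi = plant.qstart, plant.qend
    if hi <= lo:
        return 0.0
    ivs = sorted((max(lo, h.qstart), min(hi, h.qend)) for h in hits)
    covered, cur_lo, cur_hi = 0, None, None
    for s, e in ivs:
        if e <= s:
            continue
        if cur_lo is None:
            cur_lo, cur_hi = s, e
        elif s <= cur_hi:
            cur_hi = max(cur_hi, e)
        else:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = s, e
    if cur_lo is not None:
        covered += cur_hi - cur_lo
    return covered / (hi - lo)


def check_overhangs(rep_seq: str, plant: AlignmentHit, vector_db: SeqDB,
                    config: PipelineConfig | None = None,
                    min_overhang: int = 20) -> bool:
    """True when a non-aligned query overhang hits the vector/construct
    DB (reduced word size), i.e. the cluster stays on the junction track."""
    if config is None:
        config = PipelineConfig()
    for lo, hi in ((0, plant.qstart), (plant.qend, len(rep_seq))):
        if hi - lo < min_overhang:
            continue
        seg = rep_seq[lo:hi]
        if len(seg) < config.overhang_word_size:
            continue
        if search("overhang", seg, vector_db, config.overhang_word_size):
            return True
    return False


def classify_representative(cluster_id: str, rep: Read, plant_db: SeqDB,
                            nonhost_db: SeqDB, element_db: SeqDB,
                            config: PipelineConfig | None = None,
                            n_reads: int = 1) -> AnnotationRecord:
    """Classify one cluster representative (the full decision tree)."""
    if config is None:
        config = PipelineConfig()
    w = config.db_word_size
    plant = best_hit(search(rep.id, rep.seq, plant_db, w))
    nonhost = best_hit(search(rep.id, rep.seq, nonhost_db, w))
    plant_cov = plant.qcov if plant else None
    element_frac = 0.0
    if plant is not None and plant_cov < config.class1_min_query_cov:
        element_frac = _element_overlap(rep.seq, plant, element_db, config)
    overhang_checked = False
    overhang_has_vector: bool | None = None
    if (plant is not None
            and config.near_full_band_lo <= plant_cov < config.class1_min_query_cov):
        overhang_checked = True
        overhang_has_vector = check_overhangs(rep.seq, plant, nonhost_db, config)
    label, fate = decide_class(plant_cov, element_frac, bool(nonhost),
                               overhang_has_vector, config)
    return AnnotationRecord(cluster_id, rep.id, label, fate, plant, nonhost,
                            element_frac, overhang_checked, overhang_has_vector,
                            n_reads)


def annotate_all(clusters: list[Cluster], reads_by_id: dict[str, Read],
                 plant_db: SeqDB, nonhost_db: SeqDB, element_db: SeqDB,
                 config: PipelineConfig | None = None
                 ) -> tuple[list[AnnotationRecord], dict[str, int]]:
    """One record per cluster plus per-(class, fate) summary counts."""
    if config is None:
        config = PipelineConfig()
    records = []
    for c in clusters:
        rep = reads_by_id[c.representative]
        records.append(classify_representative(
            c.id, rep, plant_db, nonhost_db, element_db, config, c.size))
    summary: dict[str, int] = {}
    for r in records:
        key = f"class{r.class_label}:{r.fate}"
        summary[key] = summary.get(key, 0) + 1
    log.info("annotate: %s", summary)
    return records, summary
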