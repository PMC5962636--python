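"""Site delineation, junction excision, flank assembly, status calls."""

import numpy as np
import pytest

from walkseq.align import AlignmentHit, SeqDB
from walkseq.annotate import JUNCTION_CANDIDATE, AnnotationRecord
from walkseq.characterize import (assemble_flanks, call_status,
                                  delineate_sites, excise_junction,
                                  order_insert_fragments)
from walkseq.io import PipelineConfig, Read

CFG = PipelineConfig()


def rnd(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _hit(qid, sid, qs, qe, ss, se, strand="+", qlen=2000):
    ln = max(qe - qs, se - ss)
    return AlignmentHit(qid, sid, qs, qe, ss, se, strand, ln, ln, ln, qlen)


def _jrec(cid, host_bp, facing, qlen=2000, host_left=True, n_reads=20):
    """A junction-candidate record: host hit on one side of the query,
    vector (cassette) hit on the other."""
    if host_left:
        h = _hit(cid, "chrA", 0, 1000, host_bp - 1000, host_bp, qlen=qlen)
        v = _hit(cid, "cassette", 1010, 1900, facing, facing + 890, qlen=qlen)
    else:
        h = _hit(cid, "chrA", 1000, 2000, host_bp, host_bp + 1000, qlen=qlen)
        v = _hit(cid, "cassette", 0, 990, facing - 990, facing, qlen=qlen)
    return AnnotationRecord(cid, f"rep_{cid}", "2B", JUNCTION_CANDIDATE,
                            h, v, 0.0, False, None, n_reads)


@pytest.fixture(scope="module")
def dbs():
    rng = np.random.default_rng(0)
    host_db = SeqDB([("chrA", rnd(rng, 30000), {"kind": "host"})])
    nonhost_db = SeqDB([("cassette", rnd(rng, 4000), {"kind": "construct"})])
    return host_db, nonhost_db


class TestDelineate:
    def test_concordant_breakpoints_one_site(self, dbs):
        recs = [_jrec(f"c{i}", 10000 + d, facing=10)
                for i, d in enumerate((0, 2, -3))]
        sites = delineate_sites(recs, *dbs, CFG)
        assert len(sites) == 1
        s = sites[0]
        assert s.delineation == "delineated"
        assert abs(s.breakpoint - 10000) <= 3
        assert s.side == "LB"
        assert sorted(s.supporting_clusters) == ["c0", "c1", "c2"]

    def test_rb_side_inference(self, dbs):
        clen = 4000
        recs = [_jrec(f"c{i}", 12000, facing=clen - 5, host_left=False)
                for i in range(2)]
        sites = delineate_sites(recs, *dbs, CFG)
        assert len(sites) == 1
        assert sites[0].side == "RB"

    def test_scattered_clips_flagged_chimeric(self, dbs):
        # one locus fused to 3 distinct cassette fragments at spread-out
        # clip positions: must not become a delineated site
        recs = [_jrec("c0", 10000, facing=100),
                _jrec("c1", 10040, facing=600),
                _jrec("c2", 10085, facing=1200)]
        sites = delineate_sites(recs, *dbs, CFG)
        assert len(sites) == 1
        assert sites[0].delineation == "chimeric_suspect"
        assert "wet-lab" in sites[0].note

    def test_single_cluster_is_enough(self, dbs):
        sites = delineate_sites([_jrec("c0", 15000, facing=0)], *dbs, CFG)
        assert len(sites) == 1
        assert sites[0].delineation == "delineated"

    def test_permutation_invariant(self, dbs):
        recs = [_jrec(f"c{i}", 10000 + d, facing=10)
                for i, d in enumerate((0, 2, -3, 120))]
        a = delineate_sites(recs, *dbs, CFG)
        b = delineate_sites(recs[::-1], *dbs, CFG)
        assert [(s.contig, s.side, s.breakpoint, s.delineation,
                 sorted(s.supporting_clusters)) for s in a] == \
               [(s.contig, s.side, s.breakpoint, s.delineation,
                 sorted(s.supporting_clusters)) for s in b]

    def test_cluster_conservation(self, dbs):
        recs = [_jrec(f"c{i}", 10000 + d, facing=10)
                for i, d in enumerate((0, 1, 2, 300))]
        sites = delineate_sites(recs, *dbs, CFG)
        assigned = sorted(c for s in sites for c in s.supporting_clusters)
        assert assigned == [f"c{i}" for i in range(4)]


class TestExcise:
    def test_midpoint_rule(self):
        rng = np.random.default_rng(1)
        rep = Read("rep", rnd(rng, 1000))
        rec = AnnotationRecord(
            "c", "rep", "2B", JUNCTION_CANDIDATE,
            _hit("c", "chrA", 410, 900, 5000, 5490, qlen=1000),
            _hit("c", "cassette", 0, 400, 0, 400, qlen=1000),
            0.0, False, None, 10)
        seq, clipped = excise_junction(rec, rep, window=100)
        # vector hit ends at 400, host starts at 410 -> midpoint 405
        assert seq == rep.seq[355:455]
        assert not clipped

    def test_clipped_window_flagged(self):
        rng = np.random.default_rng(2)
        rep = Read("rep", rnd(rng, 500))
        rec = AnnotationRecord(
            "c", "rep", "2B", JUNCTION_CANDIDATE,
            _hit("c", "chrA", 35, 500, 5000, 5465, qlen=500),
            _hit("c", "cassette", 0, 25, 0, 25, qlen=500),
            0.0, False, None, 10)
        seq, clipped = excise_junction(rec, rep, window=100)
        assert clipped
        assert seq == rep.seq[0:80]

    def test_overlapping_hits_error(self):
        rng = np.random.default_rng(3)
        rep = Read("rep", rnd(rng, 1000))
        rec = AnnotationRecord(
            "c", "rep", "2B", JUNCTION_CANDIDATE,
            _hit("c", "chrA", 100, 900, 0, 800, qlen=1000),
            _hit("c", "cassette", 350, 995, 0, 645, qlen=1000),
            0.0, False, None, 10)
        with pytest.raises(ValueError, match="malformed"):
            excise_junction(rec, rep, window=100)


class TestAssembleFlanks:
    def test_overlapping_reps_merged(self):
        rng = np.random.default_rng(4)
        full = rnd(rng, 1500)
        a, b = full[:1000], full[500:]
        _, contig = assemble_flanks({"a": a, "b": b}, CFG)
        assert contig == full

    def test_disjoint_reps_longest_returned(self):
        rng = np.random.default_rng(5)
        a, b = rnd(rng, 900), rnd(rng, 600)
        _, contig = assemble_flanks({"a": a, "b": b}, CFG)
        assert contig == a

    def test_contained_rep_absorbed(self):
        rng = np.random.default_rng(6)
        big = rnd(rng, 1200)
        _, contig = assemble_flanks({"a": big, "b": big[200:900]}, CFG)
        assert contig == big


class TestOrderFragments:
    def test_contained_fragment_dropped_and_ordering(self):
        rng = np.random.default_rng(7)
        cassette = rnd(rng, 4000)
        db = SeqDB([("cassette", cassette, {"kind": "construct"})])
        reads = {
            "rA": Read("rA", cassette[100:1200]),
            "rB": Read("rB", cassette[300:900]),     # contained in rA
            "rC": Read("rC", cassette[2500:3600]),
        }
        recs = [AnnotationRecord(c, c.replace("c", "r"), "3",
                                 "internal_insert", None, None, 0.0, False,
                                 None, 10)
                for c in ("cA", "cB", "cC")]
        for r in recs:
            r.rep_id = "r" + r.cluster_id[1:]
        rows = order_insert_fragments(recs, reads, {}, db, CFG)
        names = [r["fragment"] for r in rows]
        assert "cB" not in names
        posA = next(r["position"] for r in rows if r["fragment"] == "cA")
        posC = next(r["position"] for r in rows if r["fragment"] == "cC")
        assert posA < posC


class TestCallStatus:
    @pytest.fixture(scope="class")
    def windows(self):
        rng = np.random.default_rng(8)
        return {"j1": rnd(rng, 100), "j2": rnd(rng, 100),
                "j3": rnd(rng, 100), "j4": rnd(rng, 100)}

    def test_verbatim_junction_known(self, windows):
        db = SeqDB([("auth1", windows["j1"], {})])
        calls = call_status({"j1": windows["j1"]}, db, None, CFG)
        assert calls["j1"].verdict == "known"
        assert calls["j1"].coverage >= 0.90

    def test_absent_junction_unknown(self, windows):
        db = SeqDB([("auth1", windows["j1"], {})])
        calls = call_status({"j2": windows["j2"]}, db, None, CFG)
        assert calls["j2"].verdict == "unknown"

    def test_empty_db_all_unknown(self, windows):
        calls = call_status(windows, SeqDB([]), None, CFG)
        assert all(c.verdict == "unknown" for c in calls.values())

    def test_partial_match_ambiguous(self, windows):
        rng = np.random.default_rng(9)
        partial = windows["j1"][:70] + rnd(rng, 30)
        db = SeqDB([("auth1", partial, {})])
        calls = call_status({"j1": windows["j1"]},
                            db, None, CFG.with_overrides(status_word_size=12))
        assert calls["j1"].verdict == "ambiguous"

    def test_empty_window_error(self):
        with pytest.raises(ValueError, match="empty"):
            call_status({"j": ""}, SeqDB([]), None, CFG)

    def test_patent_db_second_slot(self, windows):
        pat = SeqDB([("patX", windows["j3"], {})])
        calls = call_status({"j3": windows["j3"]}, SeqDB([]), pat, CFG)
        assert calls["j3"].verdict == "known"
        assert calls["j3"].db_name == "patent"
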