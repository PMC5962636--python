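"""Search/map engine vs a full local-DP oracle; consensus and profiles."""

import numpy as np
import pytest

from helpers import sw_oracle_score
from walkseq.align import (SeqDB, best_hit, consensus_call,
                           coverage_error_profile, extract_junction_reads,
                           map_reads, search)
from walkseq.io import Read, revcomp


def rnd(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def noisy_copy(rng, seq, sub=0.03, indel=0.005):
    out = []
    for c in seq:
        r = rng.random()
        if r < indel / 2:
            continue
        out.append(rng.choice(list("ACGT")) if r < indel / 2 + sub else c)
        if r > 1 - indel / 2:
            out.append(rng.choice(list("ACGT")))
    return "".join(out)


class TestSearch:
    def test_self_hit_full_coverage(self):
        rng = np.random.default_rng(0)
        s = rnd(rng, 1000)
        db = SeqDB([("s1", s, {})])
        h = best_hit(search("q", s, db, 64))
        assert h is not None
        assert h.qcov == 1.0
        assert h.identity == 1.0
        assert (h.sstart, h.send) == (0, 1000)

    def test_scattered_substitutions_full_interval(self):
        rng = np.random.default_rng(1)
        s = rnd(rng, 1000)
        q = list(s)
        for i in range(100, 1000, 200):
            q[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[i]]
        q = "".join(q)
        db = SeqDB([("s1", s, {})])
        h = best_hit(search("q", q, db, 64))
        assert h.qstart == 0 and h.qend == 1000
        assert h.identity == pytest.approx(0.995)

    def test_query_shorter_than_word_size_no_hits(self):
        rng = np.random.default_rng(2)
        db = SeqDB([("s1", rnd(rng, 500), {})])
        assert search("q", rnd(rng, 63), db, 64) == []

    def test_reverse_strand_hit(self):
        rng = np.random.default_rng(3)
        s = rnd(rng, 800)
        db = SeqDB([("s1", s, {})])
        h = best_hit(search("q", revcomp(s[200:600]), db, 64))
        assert h.strand == "-"
        assert (h.sstart, h.send) == (200, 600)
        assert h.qcov == 1.0

    @pytest.mark.parametrize("seed", range(6))
    def test_best_score_matches_full_dp_oracle(self, seed):
        """Seed-and-extend equals an independent optimal local aligner
        on planted homologies (score equality, >=95% interval overlap)."""
        rng = np.random.default_rng(10 + seed)
        s = rnd(rng, 3000)
        a, b = sorted(rng.integers(0, 3000, 2))
        if b - a < 300:
            a, b = 500, 1500
        core = noisy_copy(rng, s[a:b])
        q = rnd(rng, 100) + core + rnd(rng, 100)
        if seed % 2:
            q = revcomp(q)
        db = SeqDB([("s1", s, {})])
        h = best_hit(search("q", q, db, 64))
        oracle, ivals = sw_oracle_score(q, s)
        assert h is not None
        assert h.score == oracle
        oq0, oq1, os0, os1, _ = ivals
        qo = min(h.qend, oq1) - max(h.qstart, oq0)
        so = min(h.send, os1) - max(h.sstart, os0)
        assert qo >= 0.95 * (oq1 - oq0)
        assert so >= 0.95 * (os1 - os0)


class TestMap:
    def test_error_free_read_zero_error(self):
        rng = np.random.default_rng(20)
        ref = rnd(rng, 4000)
        db = SeqDB([("ref", ref, {})])
        reads = [Read("r0", ref[500:2500])]
        hits = map_reads(reads, db)
        assert hits["r0"].error_rate == 0.0
        assert (hits["r0"].sstart, hits["r0"].send) == (500, 2500)

    def test_unrelated_read_unmapped(self):
        rng = np.random.default_rng(21)
        db = SeqDB([("ref", rnd(rng, 4000), {})])
        hits = map_reads([Read("x", rnd(rng, 1500))], db)
        assert "x" not in hits

    def test_strand_symmetry(self):
        rng = np.random.default_rng(22)
        ref = rnd(rng, 4000)
        db = SeqDB([("ref", ref, {})])
        seg = noisy_copy(rng, ref[1000:2600])
        fwd = map_reads([Read("f", seg)], db)["f"]
        rev = map_reads([Read("r", revcomp(seg))], db)["r"]
        assert fwd.score == rev.score
        assert (fwd.sstart, fwd.send) == (rev.sstart, rev.send)
        assert {fwd.strand, rev.strand} == {"+", "-"}


class TestJunctionExtraction:
    def test_window_containment_rule(self):
        rng = np.random.default_rng(30)
        ref = rnd(rng, 2000)
        db = SeqDB([("ref", ref, {})])
        reads = [Read("spans", ref[800:1200]),     # covers 1000 +/- 50
                 Read("stops", ref[600:1010])]     # ends 10 bp past it
        hits = map_reads(reads, db)
        got = extract_junction_reads(hits, "ref", 1000, window=100)
        assert got == ["spans"]


class TestConsensus:
    def _setup(self, rng, n_reads, noise, ref_len=400):
        ref = rnd(rng, ref_len)
        db = SeqDB([("ref", ref, {})])
        reads = [Read(f"r{i}", noisy_copy(rng, ref, sub=noise, indel=noise / 3))
                 for i in range(n_reads)]
        hits = map_reads(reads, db)
        return ref, db, reads, hits

    def test_single_read_all_uncalled(self):
        rng = np.random.default_rng(40)
        ref, db, reads, hits = self._setup(rng, 1, 0.0)
        res = consensus_call(reads[:1], hits, db, "ref", 150, 250, min_cov=2)
        assert res.n_called == 0
        assert set(res.seq) == {"N"}

    def test_identical_reads_perfect_consensus(self):
        rng = np.random.default_rng(41)
        ref, db, reads, hits = self._setup(rng, 5, 0.0)
        res = consensus_call(reads, hits, db, "ref", 150, 250, min_cov=2,
                             truth=ref[150:250])
        assert res.seq == ref[150:250]
        assert res.percent_correct == 100.0

    def test_noisy_majority_vote_high_accuracy(self):
        rng = np.random.default_rng(42)
        ref, db, reads, hits = self._setup(rng, 10, 0.03)
        res = consensus_call(reads, hits, db, "ref", 100, 200, min_cov=2,
                             truth=ref[100:200])
        assert res.percent_correct is not None
        assert res.percent_correct >= 99.0

    def test_read_order_invariance(self):
        rng = np.random.default_rng(43)
        ref, db, reads, hits = self._setup(rng, 8, 0.03)
        a = consensus_call(reads, hits, db, "ref", 100, 200, min_cov=2)
        b = consensus_call(reads[::-1], hits, db, "ref", 100, 200, min_cov=2)
        assert a.seq == b.seq

    def test_no_reads_explicit_no_consensus(self):
        rng = np.random.default_rng(44)
        ref, db, _, _ = self._setup(rng, 1, 0.0)
        res = consensus_call([], {}, db, "ref", 0, 100, min_cov=2)
        assert res.n_called == 0


class TestCoverageProfile:
    def test_single_read_depth_one(self):
        rng = np.random.default_rng(50)
        ref = rnd(rng, 1000)
        db = SeqDB([("ref", ref, {})])
        reads = [Read("r", ref[200:700])]
        hits = map_reads(reads, db)
        prof = coverage_error_profile(reads, hits, db, "ref")
        assert prof.depth[200:700].min() == 1
        assert prof.depth[:200].max() == 0
        assert np.nanmax(prof.error_rate[200:700]) == 0.0

    def test_empty_hits_all_zero(self):
        rng = np.random.default_rng(51)
        db = SeqDB([("ref", rnd(rng, 500), {})])
        prof = coverage_error_profile([], {}, db, "ref")
        assert prof.depth.sum() == 0
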