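"""Generator truth bookkeeping, error calibration and determinism."""

import numpy as np
import pytest

import edlib
from walkseq.io import WALKING_ADAPTER, read_fastq
from walkseq.simulate import (SimConfig, build_truth_genome,
                              chimera_family_amplicons, default_elements,
                              enumerate_amplicons, inject_errors,
                              simulate_reads, simulate_run)


class TestTruthGenome:
    def test_two_insertions_four_junctions(self):
        truth = build_truth_genome(SimConfig(rng_seed=1))
        assert len(truth.insertions) == 2
        assert len(truth.junctions) == 4
        assert {j.side for j in truth.junctions} == {"LB", "RB"}

    def test_zero_insertions_genome_equals_host(self):
        truth = build_truth_genome(SimConfig(rng_seed=1, n_insertions=0))
        assert truth.junctions == []
        assert truth.post == truth.host

    def test_junction_windows_are_genome_substrings(self):
        truth = build_truth_genome(SimConfig(rng_seed=2))
        for j in truth.junctions:
            assert truth.post[j.contig][j.window_start:j.window_end] \
                == j.window_seq
            assert len(j.window_seq) == 100

    def test_insertion_at_origin_clips_window(self):
        truth = build_truth_genome(
            SimConfig(rng_seed=3, n_insertions=1, insertion_positions=[0],
                      host_contig_lengths=[5000]))
        lb = next(j for j in truth.junctions if j.side == "LB")
        assert lb.clipped
        assert lb.window_start == 0

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            build_truth_genome(SimConfig(
                rng_seed=4, n_insertions=1, insertion_positions=[99999],
                host_contig_lengths=[5000]))

    def test_insertion_replaces_zero_host_bases(self):
        cfg = SimConfig(rng_seed=5, n_insertions=1, insertion_positions=[3000],
                        host_contig_lengths=[8000])
        truth = build_truth_genome(cfg)
        host = truth.host["contig1"]
        post = truth.post["contig1"]
        assert post[:3000] == host[:3000]
        assert post[3000:3000 + len(truth.cassette)] == truth.cassette
        assert post[3000 + len(truth.cassette):] == host[3000:]


class TestAmplicons:
    def test_amplicons_contain_anchor_and_adapter(self):
        cfg = SimConfig(rng_seed=6, amplicons_per_anchor_direction=3)
        truth = build_truth_genome(cfg)
        amps = enumerate_amplicons(truth, cfg, np.random.default_rng(0))
        specific = [a for a in amps if a.anchor != "none"]
        # 3 anchors x 2 directions x 2 insertions x 3 amplicons
        assert len(specific) == 36
        elements = {e.name: e.seq for e in default_elements()}
        for a in specific:
            assert elements[a.anchor] in a.seq
            assert WALKING_ADAPTER in a.seq

    def test_junction_bearing_amplicons_match_bruteforce(self):
        cfg = SimConfig(rng_seed=7)
        truth = build_truth_genome(cfg)
        amps = enumerate_amplicons(truth, cfg, np.random.default_rng(1))
        for a in amps:
            spans = any(a.contig == j.contig and a.start < j.post_pos < a.end
                        for j in truth.junctions)
            genomic = a.seq.replace(WALKING_ADAPTER, "")
            # brute-force: the genomic part must equal the truth interval
            assert truth.post[a.contig][a.start:a.end] == genomic
            if spans:
                j = next(j for j in truth.junctions
                         if a.contig == j.contig and a.start < j.post_pos < a.end)
                assert a.start < j.post_pos < a.end

    def test_fixed_length_range(self):
        cfg = SimConfig(rng_seed=8, amplicon_len_range=[500, 500],
                        amplicons_per_anchor_direction=2)
        truth = build_truth_genome(cfg)
        amps = enumerate_amplicons(truth, cfg, np.random.default_rng(2))
        for a in [x for x in amps if x.anchor != "none"]:
            assert a.end - a.start == 500
            assert len(a.seq) == 500 + len(WALKING_ADAPTER)


class TestReads:
    def test_zero_error_reads_are_exact_substrings(self):
        cfg = SimConfig(rng_seed=9, sub_rate=0, ins_rate=0, del_rate=0,
                        chimera_fraction=0, platform_adapter_prob=0,
                        amplicons_per_anchor_direction=1, reads_per_amplicon=2,
                        chimera_families=0, nonspecific_amplicons=0)
        truth = build_truth_genome(cfg)
        amps = enumerate_amplicons(truth, cfg, np.random.default_rng(3))
        reads = simulate_reads(amps, cfg, np.random.default_rng(4))
        by_id = {a.id: a for a in amps}
        from walkseq.io import revcomp
        for sr in reads:
            template = by_id[sr.amplicon_id].seq
            assert sr.read.seq in (template, revcomp(template))

    def test_error_rate_calibration(self):
        """Measured per-base error of simulated reads is within one
        percentage point of the configured 13% total."""
        cfg = SimConfig(rng_seed=10)
        rng = np.random.default_rng(5)
        template = "".join(rng.choice(list("ACGT"), 2000))
        tot_ed, tot_len = 0, 0
        for _ in range(300):
            noisy, _, _ = inject_errors(template, cfg, rng)
            d = edlib.align(noisy, template, mode="NW")["editDistance"]
            tot_ed += d
            tot_len += len(template)
        assert abs(tot_ed / tot_len - 0.13) < 0.01

    def test_qualities_reflect_errors(self):
        cfg = SimConfig(rng_seed=11)
        rng = np.random.default_rng(6)
        template = "".join(rng.choice(list("ACGT"), 500))
        noisy, qual, n_err = inject_errors(template, cfg, rng)
        assert len(qual) == len(noisy)
        assert n_err > 0

    def test_accumulation_profile_majority_before_8h(self):
        cfg = SimConfig(rng_seed=12, amplicons_per_anchor_direction=2,
                        reads_per_amplicon=20)
        truth = build_truth_genome(cfg)
        amps = enumerate_amplicons(truth, cfg, np.random.default_rng(7))
        reads = simulate_reads(amps, cfg, np.random.default_rng(8))
        t = np.array([sr.read.start_time_s for sr in reads])
        assert (t <= 8 * 3600).mean() > 0.5
        assert t.max() <= 24 * 3600

    def test_chimera_family_is_scattered_at_one_locus(self):
        cfg = SimConfig(rng_seed=13)
        truth = build_truth_genome(cfg)
        fam = chimera_family_amplicons(truth, cfg, np.random.default_rng(9))
        assert len(fam) == cfg.chimera_family_types
        assert len({a.contig for a in fam}) == 1
        clips = sorted(a.clip_pos for a in fam)
        assert all(b - a > 5 for a, b in zip(clips, clips[1:]))


class TestDeterminismAndFiles:
    def test_fixed_seed_reproduces_byte_identical_outputs(self, tmp_path):
        cfg = SimConfig(rng_seed=42, amplicons_per_anchor_direction=1,
                        reads_per_amplicon=3, nonspecific_amplicons=1,
                        chimera_family_reads_per_type=2)
        p1 = simulate_run(cfg, tmp_path / "a")
        p2 = simulate_run(cfg, tmp_path / "b")
        for key in ("reads", "times", "truth_junctions", "host_db"):
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_mini_databases_content(self, tmp_path):
        cfg = SimConfig(rng_seed=14, amplicons_per_anchor_direction=1,
                        reads_per_amplicon=1)
        paths = simulate_run(cfg, tmp_path / "x")
        from walkseq.io import read_fasta_db
        host = read_fasta_db(paths["host_db"])
        kinds = {t.get("kind") for _, _, t in host}
        assert kinds == {"host", "plant"}
        elements = {e.name: e.seq for e in default_elements()}
        decoy = next(seq for rid, seq, _ in host if rid == "decoy_zea")
        assert elements["pUBI"] in decoy
        auth = read_fasta_db(paths["authorized_db"])
        assert len(auth) == 2
        assert all("RB" in rid for rid, _, _ in auth)
        reads = read_fastq(paths["reads"])
        assert len(reads) > 0
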