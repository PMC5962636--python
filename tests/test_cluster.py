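"""Two-round clustering vs brute-force DP oracles."""

import numpy as np
import pytest

from helpers import (oracle_cluster_round1, oracle_cluster_round2,
                     oracle_containment_identity, oracle_global_identity)
from walkseq.cluster import (Cluster, cluster_round1, cluster_round2,
                             cluster_stats, containment_identity,
                             global_identity)
from walkseq.io import PipelineConfig, Read, revcomp


def rnd(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def mutate(rng, seq, rate):
    out = []
    for c in seq:
        r = rng.random()
        if r < rate * 0.5:
            out.append(rng.choice(list("ACGT")))
        elif r < rate * 0.75:
            continue
        else:
            out.append(c)
            if r > 1 - rate * 0.25:
                out.append(rng.choice(list("ACGT")))
    return "".join(out)


CFG = PipelineConfig()


def random_instance(rng, n_families, reads_per_family, length_range=(80, 200),
                    noise=0.01):
    """A clustering instance: families of near-identical reads plus a
    few singleton outliers, some reverse-complemented."""
    reads = []
    i = 0
    for _ in range(n_families):
        base = rnd(rng, int(rng.integers(*length_range)))
        for _ in range(reads_per_family):
            s = mutate(rng, base, noise)
            if rng.random() < 0.4:
                s = revcomp(s)
            reads.append(Read(f"q{i:04d}", s))
            i += 1
    for _ in range(int(rng.integers(0, 4))):
        reads.append(Read(f"q{i:04d}", rnd(rng, int(rng.integers(*length_range)))))
        i += 1
    return reads


class TestIdentityDefinitions:
    def test_identity_matches_dp_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            a = rnd(rng, int(rng.integers(50, 150)))
            b = mutate(rng, a, 0.08) if rng.random() < 0.7 else rnd(rng, 120)
            assert global_identity(a, b) == pytest.approx(
                oracle_global_identity(a, b), abs=1e-12)

    def test_containment_matches_dp_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            big = rnd(rng, 300)
            s, e = sorted(rng.integers(0, 300, 2))
            if e - s < 20:
                continue
            small = mutate(rng, big[s:e], 0.05)
            assert containment_identity(small, big) == pytest.approx(
                oracle_containment_identity(small, big), abs=1e-12)


class TestRound1:
    def test_six_identical_reads_one_cluster(self):
        reads = [Read(f"r{i}", "ACGT" * 250) for i in range(6)]
        retained, discarded, _ = cluster_round1(reads, CFG)
        assert len(retained) == 1 and retained[0].size == 6
        assert discarded == []

    def test_five_reads_not_retained(self):
        reads = [Read(f"r{i}", "ACGT" * 250) for i in range(5)]
        retained, discarded, _ = cluster_round1(reads, CFG)
        assert retained == []
        assert len(discarded) == 5

    def test_low_identity_outlier_discarded(self):
        rng = np.random.default_rng(2)
        base = rnd(rng, 1000)
        reads = [Read(f"r{i}", base) for i in range(6)]
        reads.append(Read("r6", mutate(rng, base, 0.2)))
        retained, discarded, _ = cluster_round1(reads, CFG)
        assert len(retained) == 1 and retained[0].size == 6
        assert discarded == ["r6"]

    def test_representative_is_longest_member(self):
        rng = np.random.default_rng(3)
        base = rnd(rng, 1000)
        reads = [Read(f"r{i}", base[: 1000 - i]) for i in range(6)]
        retained, _, _ = cluster_round1(reads, CFG)
        assert retained and retained[0].representative == "r0"

    def test_conservation(self):
        rng = np.random.default_rng(4)
        reads = random_instance(rng, 4, 7)
        retained, discarded, all_c = cluster_round1(reads, CFG)
        seen = sorted(m for c in all_c for m in c.members)
        assert seen == sorted(r.id for r in reads)
        assert sorted([m for c in retained for m in c.members] + discarded) \
            == seen

    def test_deterministic(self):
        rng = np.random.default_rng(5)
        reads = random_instance(rng, 3, 8)
        a = cluster_round1(reads, CFG)
        b = cluster_round1(list(reads), CFG)
        assert [c.members for c in a[0]] == [c.members for c in b[0]]


class TestRound2:
    def test_containment_merges(self):
        rng = np.random.default_rng(6)
        base = rnd(rng, 1000)
        long_reads = [Read(f"a{i}", base) for i in range(6)]
        short_reads = [Read(f"b{i}", base[100:900]) for i in range(6)]
        reads = long_reads + short_reads
        retained, disc, _ = cluster_round1(reads, CFG)
        assert len(retained) == 2
        by_id = {r.id: r for r in reads}
        merged = cluster_round2(retained, by_id, disc, CFG)
        assert len(merged) == 1
        assert merged[0].size == 12
        assert merged[0].representative == "a0"
        assert merged[0].round == 2

    def test_short_overlap_not_merged(self):
        rng = np.random.default_rng(7)
        a = rnd(rng, 1000)
        b = a[700:] + rnd(rng, 500)    # 300-bp overlap, 38% of shorter
        r1 = [Read(f"a{i}", a) for i in range(6)]
        r2 = [Read(f"b{i}", b) for i in range(6)]
        retained, disc, _ = cluster_round1(r1 + r2, CFG)
        merged = cluster_round2(retained, {r.id: r for r in r1 + r2}, disc, CFG)
        assert len(merged) == 2


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(8))
    def test_round1_matches_bruteforce(self, seed):
        rng = np.random.default_rng(100 + seed)
        reads = random_instance(rng, int(rng.integers(2, 5)),
                                int(rng.integers(4, 9)))
        retained, discarded, _ = cluster_round1(reads, CFG)
        o_ret, o_disc = oracle_cluster_round1(reads, 0.95, 0.99, 6)
        assert sorted(sorted(c.members) for c in retained) == \
            sorted(sorted(m) for m in o_ret)
        assert sorted(discarded) == sorted(o_disc)

    @pytest.mark.parametrize("seed", range(4))
    def test_round2_matches_bruteforce(self, seed):
        rng = np.random.default_rng(200 + seed)
        base = rnd(rng, 600)
        reads = []
        i = 0
        # nested truncations of one template plus an unrelated family
        for start, end in [(0, 600), (50, 600), (0, 450), (200, 580)]:
            for _ in range(6):
                reads.append(Read(f"n{i:03d}", mutate(rng, base[start:end], 0.01)))
                i += 1
        other = rnd(rng, 500)
        for _ in range(6):
            reads.append(Read(f"n{i:03d}", mutate(rng, other, 0.01)))
            i += 1
        retained, disc, _ = cluster_round1(reads, CFG)
        by_id = {r.id: r for r in reads}
        merged = cluster_round2(retained, by_id, disc, CFG)
        o_parts = oracle_cluster_round2(
            [by_id[c.representative] for c in retained],
            [c.members for c in retained], 0.95)
        assert sorted(sorted(c.members) for c in merged) == sorted(o_parts)


def test_cluster_stats_shapes():
    c = Cluster("c", "r0", [f"r{i}" for i in range(6)])
    rows = cluster_stats([c], [c], [], [c], 6)
    by_round = {r["round"]: r for r in rows}
    assert by_round["round1"]["mean_size"] == 6.0
    assert by_round["round1"]["max_size"] == 6
    empty = cluster_stats([], [], [], [], 0)
    assert {r["round"] for r in empty} >= {"round1", "round2"}
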