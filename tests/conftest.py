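"""Shared fixtures: random sequences, a small simulated library, and one
session-scoped default pipeline run reused by the integration tests."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for helpers import

from walkseq.io import PipelineConfig
from walkseq.report import PipelineResult, pipeline_run
from walkseq.simulate import SimConfig


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))


@pytest.fixture(scope="session")
def default_config() -> PipelineConfig:
    return PipelineConfig(rng_seed=1)


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Scaled-down library: same structure as the default conditions
    (2 insertions, 13% error, 2% chimeras, planted chimera family) at
    lower depth, for fast integration tests."""
    return SimConfig(rng_seed=11, amplicons_per_anchor_direction=2,
                     reads_per_amplicon=12, nonspecific_amplicons=2,
                     chimera_family_reads_per_type=8)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory, default_config, small_sim_config
              ) -> PipelineResult:
    out = tmp_path_factory.mktemp("small_run")
    return pipeline_run(default_config.with_overrides(rng_seed=11), out,
                        simulate=True, sim_config=small_sim_config)


@pytest.fixture(scope="session")
def default_run(tmp_path_factory, default_config) -> PipelineResult:
    """The full study-condition run: 2 insertions, 4 junctions, 13% raw
    error, 2% chimeras, >500 raw reads covering each junction window."""
    out = tmp_path_factory.mktemp("default_run")
    return pipeline_run(default_config, out, simulate=True,
                        sim_config=SimConfig(rng_seed=1))


def read_truth_reads(run: PipelineResult) -> list[dict]:
    from walkseq.io import read_tsv
    return read_tsv(run.sim_paths["truth_reads"])


def read_truth_junctions(run: PipelineResult) -> list[dict]:
    """Truth junction records parsed from the BED name field."""
    from walkseq.io import read_bed
    out = []
    for iv in read_bed(run.sim_paths["truth_junctions"]):
        name, *kv = iv.name.split("|")
        rec = {"name": name, "contig": iv.contig,
               "window_start": iv.start, "window_end": iv.end}
        for item in kv:
            k, v = item.split("=")
            rec[k] = int(v)
        out.append(rec)
    return out


def read_truth_windows(run: PipelineResult) -> dict[str, str]:
    from walkseq.io import read_fasta_db
    return {rid: seq for rid, seq, _ in
            read_fasta_db(run.sim_paths["truth_windows"])}
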