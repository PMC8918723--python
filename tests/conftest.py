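"""Shared fixtures: tiny deterministic genomes and simulated datasets."""

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from metharc.genome import (ReferenceGenome, build_cpg_index,
                            build_pseudo_genome)
from metharc.sim import SimConfig, simulate_genome, simulate_reads


@pytest.fixture
def tiny_ref():
    # chrT: CpGs at 2 and 7; chrU: none
    return ReferenceGenome({"chrT": "AACGTTACGT", "chrU": "AATTAATT"})


@pytest.fixture(scope="session")
def sim_bisulfite():
    """Medium bisulfite dataset with spike-in, reused across tests."""
    cfg = SimConfig(seed=11, genome_length=20_000, n_fragments=1_500,
                    spike_in=True, error_rate=0.001)
    ref, truth = simulate_genome(cfg)
    r1, r2 = simulate_reads(ref, truth, cfg)
    return cfg, ref, truth, r1, r2


@pytest.fixture(scope="session")
def aligned_bisulfite(sim_bisulfite):
    """The same dataset trimmed, aligned (3-letter) and restored."""
    from metharc.align import align_reads
    from metharc.readprep import RawRead, TrimConfig, trim_pair

    cfg, ref, truth, r1, r2 = sim_bisulfite
    tcfg = TrimConfig()
    kept = [p for p in (trim_pair(a, b, tcfg) for a, b in zip(r1, r2))
            if p is not None]
    pg = build_pseudo_genome(ref, "3")
    restored, stats = align_reads(kept, pg, ref, "3")
    idx = build_cpg_index(ref)
    return cfg, ref, truth, idx, restored, stats
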