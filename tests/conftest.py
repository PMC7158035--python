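import copy

import pytest

from sealmir import preprocess
from sealmir.synthetic_data import (SimConfig, build_toy_genome,
                                    simulate_libraries)


@pytest.fixture(scope="session")
def toy():
    cfg = SimConfig(seed=101, n_hairpins=30, n_genes=32, genome_length=130_000,
                    mean_depth=4000)
    return build_toy_genome(cfg)


@pytest.fixture(scope="session")
def libsim(toy):
    return simulate_libraries(toy)


def pool_hits(hits_by_sample):
    """Aggregate per-library hits into one multiplicity-weighted hit set."""
    pooled = {}
    for hits in hits_by_sample.values():
        for h in hits:
            key = (h.seq, h.chrom, h.start, h.end, h.strand)
            if key in pooled:
                pooled[key].count += h.count
            else:
                pooled[key] = copy.copy(h)
    return list(pooled.values())


@pytest.fixture(scope="session")
def aligned(toy, libsim):
    """Per-library trim + exact alignment over the simulated libraries."""
    by_sample = {}
    unmapped_by_sample = {}
    trim_stats = {}
    for lib, reads in libsim.reads.items():
        collapsed, stats = preprocess.trim_adapter(reads, toy.config.adapter)
        hits, unmapped = preprocess.align_exact(collapsed, toy.genome)
        by_sample[lib] = hits
        unmapped_by_sample[lib] = unmapped
        trim_stats[lib] = stats
    return {"hits": by_sample, "unmapped": unmapped_by_sample,
            "trim_stats": trim_stats}


@pytest.fixture(scope="session")
def pooled_hits(aligned):
    return pool_hits(aligned["hits"])
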