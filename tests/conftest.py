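"""Shared fixtures: one moderately sized synthetic experiment, reused by the
tests that need called peaks, and a small config for cheap cases."""

from __future__ import annotations

import numpy as np
import pytest

from mitobook import (SimConfig, TagCollection, call_peaks, classify_peaks,
                      make_genome, plant_sites, simulate_tags)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(
        seed=11,
        chrom_lengths={"chr1": 400_000, "chr2": 200_000},
        n_genes=12,
        n_common=20,
        n_async_specific=10,
        n_mitotic_specific=5,
        n_shifted=5,
    )


@pytest.fixture(scope="session")
def sim_run(small_cfg):
    """Full simulate -> call -> classify chain on the small configuration."""
    genome, seqs = make_genome(small_cfg)
    sites, seqs = plant_sites(genome, seqs, small_cfg)
    tags = {
        cond: simulate_tags(genome, sites, cond, small_cfg)
        for cond in ("asynchronous", "mitotic", "input")
    }
    peak_sets = {
        cond: call_peaks(tags[cond], tags["input"], condition=cond)
        for cond in ("asynchronous", "mitotic")
    }
    comparison = classify_peaks(
        peak_sets["asynchronous"], peak_sets["mitotic"],
        tags["asynchronous"], tags["mitotic"],
    )
    return {
        "cfg": small_cfg,
        "genome": genome,
        "sequences": seqs,
        "sites": sites,
        "tags": tags,
        "peaks": peak_sets,
        "comparison": comparison,
    }


def make_tags(chrom_lengths: dict[str, int], positions: dict[str, list[int]]) -> TagCollection:
    return TagCollection(
        chrom_lengths=chrom_lengths,
        positions={c: np.array(p, dtype=np.int64) for c, p in positions.items()},
        strands={c: np.ones(len(p), dtype=np.int8) for c, p in positions.items()},
    )
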