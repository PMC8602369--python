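import numpy as np
import pandas as pd
import pytest

from epromoter import (
    GenomicInterval,
    SimConfig,
    evaluate_recovery,
    run_pipeline,
    simulate_all,
)


@pytest.fixture(scope="session")
def default_dataset():
    """Full synthetic dataset at the default study conditions, seed 0."""
    return simulate_all(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_run(default_dataset):
    ds = default_dataset
    return run_pipeline(
        ds.counts,
        ds.promoters[["promoter_id", "gene_id", "chrom", "tss", "strand"]],
        ds.tss_table,
        ds.de_table,
        ds.tf_peaks,
        ds.isre_sites,
        ds.tads,
        ds.chrom_sizes,
        seed=0,
    )


@pytest.fixture(scope="session")
def default_recovery(default_run, default_dataset):
    return evaluate_recovery(default_run, default_dataset)


def random_intervals(rng, n, chroms=("chr1", "chr2"), max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, max_pos))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, start + length))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
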