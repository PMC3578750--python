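import numpy as np
import pandas as pd
import pytest

from replitime import SimulationConfig, simulate_dataset


def make_annotation(positions, chrom="chr1", strand="+"):
    """Annotation table from a list of TSS positions (or (chrom, pos) pairs)."""
    rows = []
    for i, item in enumerate(positions):
        if isinstance(item, tuple):
            c, p = item
        else:
            c, p = chrom, item
        rows.append((f"g{i + 1:03d}", c, strand, int(p)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss"])


def make_track(intervals, chrom="chr1"):
    """Probe track from (start, end, value) triples."""
    return pd.DataFrame(
        [(chrom, s, e, v) for s, e, v in intervals],
        columns=["chrom", "start", "end", "value"],
    )


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic genome reused across tests (1.8 Mb, 200 genes)."""
    config = SimulationConfig(
        genome_length=1_800_000, n_chromosomes=1, n_genes=200, seed=11
    )
    return simulate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
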