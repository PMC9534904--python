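import numpy as np
import pytest

from ssingleap.io_formats import Genome, Interval, IntervalSet
from ssingleap.sim_data import SimParams, make_genome, make_spike_seqs


@pytest.fixture(scope="session")
def small_genome():
    """Two-chromosome 200 kb random genome with repeats and annotation."""
    genome, annotations, expression = make_genome(
        n_chrom=2, chrom_len=100_000, gc=0.42, repeat_frac=0.2, n_genes=20, seed=101
    )
    return genome, annotations, expression


@pytest.fixture(scope="session")
def spikes():
    return make_spike_seqs(n=3, length=500, seed=7)


@pytest.fixture(scope="session")
def spike_genome(spikes):
    return Genome(sequences=dict(spikes))


@pytest.fixture()
def toy_genome():
    """Tiny handmade genome for exact-arithmetic checks."""
    seq1 = "ACGTACGTACGTACGTACGT" * 5  # 100 bp
    seq2 = "GGCCATTAGGCCATTAGGCC" * 5
    mask = IntervalSet([
        Interval("c1", 10, 30, ".", "Satellite", "."),
        Interval("c1", 25, 40, ".", "LINE", "."),
    ])
    return Genome(sequences={"c1": seq1, "c2": seq2}, repeat_mask=mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def brute_force_masked_bases(genome: Genome) -> int:
    """Independent per-base oracle for merged repeat-mask accounting."""
    total = 0
    for chrom, length in genome.lengths.items():
        covered = np.zeros(length, dtype=bool)
        for r in genome.repeat_mask.records:
            if r.chrom == chrom:
                covered[r.start : r.end] = True
        total += int(covered.sum())
    return total
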