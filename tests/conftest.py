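import numpy as np
import pytest

from readforest.io_formats import ReadSet
from readforest.simulate import SimulationSpec, sample_reads, simulate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_read_set(seqs):
    return ReadSet.from_sequences(seqs)


def simulated_reads(genome_length, N, L, p=0.0, flip_prob=0.0, seed=0):
    G = simulate_genome(genome_length, seed)
    spec = SimulationSpec(genome_length=genome_length, N=N, L=L, p=p,
                          flip_prob=flip_prob, seed=seed + 1)
    return G, sample_reads(G, spec)


def inject_ns(reads, rate, seed):
    """Replace one random base with N in a `rate` fraction of reads."""
    r = np.random.default_rng(seed)
    out = []
    for s in reads:
        if r.random() < rate:
            i = int(r.integers(0, len(s)))
            s = s[:i] + "N" + s[i + 1:]
        out.append(s)
    return out
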