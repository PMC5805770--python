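"""Synthetic genomes and read sets matching the compressor's statistical model.

The generator emulates exactly the assumptions under which both the greedy
forest's optimality and the entropy approximation are stated: a uniform
i.i.d. genome, read start positions uniform over the genome, i.i.d.
substitution errors (uniform over the three alternative bases), and optional
uniform strand flips.  All randomness flows through a single seeded
numpy PCG64 generator, so fixtures are byte-reproducible across platforms.
It deliberately does not model position-dependent quality, indels, repeats,
or paired-end structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ParameterError
from .forest import revcomp
from .io_formats import ReadSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated read collection.

    genome_length : bases of the (linear) genome
    N             : number of reads
    L             : read length in bases
    p             : per-base substitution probability
    flip_prob     : probability a read is emitted as its reverse complement
    seed          : RNG seed
    """

    genome_length: int
    N: int
    L: int
    p: float = 0.0
    flip_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 1 <= self.L <= self.genome_length:
            raise ParameterError(
                f"need genome_length >= L >= 1, got {self.genome_length}, {self.L}")
        if self.N < 1:
            raise ParameterError("N must be >= 1")
        if not 0.0 <= self.p < 1.0:
            raise ParameterError("p must be in [0, 1)")
        if not 0.0 <= self.flip_prob <= 1.0:
            raise ParameterError("flip_prob must be in [0, 1]")

    @property
    def coverage(self) -> float:
        return self.N * self.L / self.genome_length


def simulate_genome(length: int, seed: int) -> str:
    """Uniform i.i.d. genome over {A, C, G, T}; deterministic given seed."""
    if length < 1:
        raise ParameterError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def sample_reads(G: str, spec: SimulationSpec) -> ReadSet:
    """Sample spec.N reads of length spec.L uniformly from G, apply i.i.d.
    substitution errors at rate spec.p, then reverse-complement each read
    independently with probability spec.flip_prob."""
    if spec.L > len(G):
        raise ParameterError(f"L={spec.L} exceeds |G|={len(G)}")
    rng = np.random.default_rng(spec.seed)
    garr = np.frombuffer(G.encode("ascii"), dtype=np.uint8)
    starts = rng.integers(0, len(G) - spec.L + 1, size=spec.N)
    reads = garr[starts[:, None] + np.arange(spec.L)[None, :]].copy()
    if spec.p > 0:
        mask = rng.random(reads.shape) < spec.p
        # substitute with one of the 3 *other* bases, uniformly
        base_idx = np.searchsorted(_BASES, reads[mask])
        shift = rng.integers(1, 4, size=int(mask.sum()))
        reads[mask] = _BASES[(base_idx + shift) % 4]
    if spec.flip_prob > 0:
        flips = rng.random(spec.N) < spec.flip_prob
    else:
        flips = np.zeros(spec.N, dtype=bool)
    out = []
    for i in range(spec.N):
        s = reads[i].tobytes().decode("ascii")
        out.append(revcomp(s) if flips[i] else s)
    return ReadSet(reads=out, L=spec.L)


def simulate_read_set(spec: SimulationSpec) -> tuple[str, ReadSet]:
    """Convenience: genome + reads from one spec (genome uses the same seed)."""
    G = simulate_genome(spec.genome_length, spec.seed)
    return G, sample_reads(G, spec)
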