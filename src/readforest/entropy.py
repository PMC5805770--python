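"""Information-theoretic entropy approximation for a read collection.

For N reads of length L sampled uniformly at random from a genome G and
corrupted by i.i.d. substitutions at rate p, the entropy of the read multiset
decomposes (to first order) into three additive terms:

    H(R)  ~=  N*L*log2(3)*h2(p)  +  |G| * H(Poisson(N/|G|))  +  LZ(G)

— the entropy of the error process, of the Poisson read-sampling process, and
of the genome itself (estimated by the DEFLATE/LZ77 description length).
The two remaining conditional terms of the exact chain-rule decomposition,
H(G|R) and H(R*|G,R), are negligible at realistic coverage and are treated
as zero here.  The result is a lower-bound approximation: no lossless
compressor can beat it on data matching the model's assumptions.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import ParameterError

#: DEFLATE setting pinned so LZ(G) is deterministic for a given zlib build.
_ZLIB_LEVEL = 9

#: Poisson entropy series is truncated once the remaining tail can contribute
#: fewer than this many bits (far below 3-decimal reporting precision).
_POISSON_TOL = 1e-12


@dataclass(frozen=True)
class EntropyEstimate:
    """The three additive terms of the read-set entropy approximation."""

    lz_genome_bits: float
    sampling_bits: float
    error_bits: float
    N: int
    L: int

    @property
    def total_bits(self) -> float:
        return self.lz_genome_bits + self.sampling_bits + self.error_bits

    @property
    def per_base(self) -> dict[str, float]:
        """Each term divided by N*L (bits per read base)."""
        nl = self.N * self.L
        return {
            "lz_genome": self.lz_genome_bits / nl,
            "sampling": self.sampling_bits / nl,
            "error": self.error_bits / nl,
            "total": self.total_bits / nl,
        }


def binary_entropy(p: float) -> float:
    """h2(p) = -p*log2(p) - (1-p)*log2(1-p); endpoints return 0 by continuity."""
    if not 0.0 <= p <= 1.0:
        raise ParameterError(f"probability {p} outside [0, 1]")
    if p in (0.0, 1.0):
        return 0.0
    return -p * math.log2(p) - (1.0 - p) * math.log2(1.0 - p)


def error_entropy_per_base(p: float) -> float:
    """Bits per base needed to describe i.i.d. substitution errors at rate p:
    log2(3) * h2(p).  (The total is N*L times this.)"""
    if not 0.0 <= p < 1.0:
        raise ParameterError(f"error rate {p} outside [0, 1)")
    return math.log2(3.0) * binary_entropy(p)


def poisson_entropy(lam: float) -> float:
    """Entropy (bits) of a Poisson random variable with mean ``lam``.

    The series sum_k -P(k) log2 P(k) is truncated once the remaining tail
    can contribute less than 1e-12 bits; poisson_entropy(0) = 0.
    """
    if lam < 0:
        raise ParameterError("Poisson mean must be >= 0")
    if lam == 0:
        return 0.0
    dist = stats.poisson(lam)
    total = 0.0
    k0 = 0
    chunk = max(64, int(lam + 10 * math.sqrt(lam)))
    while True:
        ks = np.arange(k0, k0 + chunk)
        pmf = dist.pmf(ks)
        nz = pmf > 0
        total += float(-(pmf[nz] * np.log2(pmf[nz])).sum())
        k0 += chunk
        tail = dist.sf(k0 - 1)
        if tail <= 0:
            break
        # each remaining term -p log2 p is at most p * log2(1/p_min); bound
        # the whole tail by tail * max(-log2) of its largest term
        bound = tail * max(1.0, -math.log2(min(tail, 1.0)) + math.log2(max(k0 - lam, 2.0)))
        if bound < _POISSON_TOL:
            break
    return total


def lz_genome_bits(G: str) -> float:
    """Description length of the genome under DEFLATE at the pinned maximum
    setting: 8 x compressed byte count."""
    if not G:
        raise ParameterError("genome must be non-empty")
    return 8.0 * len(zlib.compress(G.encode("ascii"), _ZLIB_LEVEL))


def estimate_read_set_entropy(G: str, N: int, L: int, p: float) -> EntropyEstimate:
    """Assemble the three-term entropy approximation for N length-L reads
    sampled from genome G with substitution rate p."""
    if N < 1:
        raise ParameterError("N must be >= 1")
    if not 1 <= L <= len(G):
        raise ParameterError(f"L={L} outside [1, |G|={len(G)}]")
    return EntropyEstimate(
        lz_genome_bits=lz_genome_bits(G),
        sampling_bits=len(G) * poisson_entropy(N / len(G)),
        error_bits=N * L * error_entropy_per_base(p),
        N=N,
        L=L,
    )
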