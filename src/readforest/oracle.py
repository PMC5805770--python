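"""Brute-force reference implementations for certifying optimality claims.

These are test-suite oracles, deliberately independent of the production
K-mer-window code path:

* :func:`brute_rep_table` — per-node minimum representation cost rep(v) by
  direct all-pairs scanning of every overlap length (no hashing, no sliding
  windows).  rep(v) = min over u != v of L - (longest exact suffix(u)/
  prefix(v) overlap) provided the overlap is >= K, else L.  The sum of
  rep(v) is the proven lower bound on any read forest's total weight, and
  the greedy builder attains it for error-free reads.
* :func:`rep_table_lengthscan` — the same quantity by exhaustive
  per-overlap-length sorted-array matching (vectorized; scales to tens of
  thousands of reads).  A third independent route, cross-checked against
  brute_rep_table in the suite.
* :func:`brute_scs_length` — exact shortest-common-superstring length by
  permutation enumeration (the forest's total weight is provably <= this).
* :func:`multiset_equal` — operationalizes "lossless".
"""

from __future__ import annotations

from collections import Counter
from itertools import permutations
from typing import Sequence

import numpy as np

from .exceptions import ParameterError
from .io_formats import ReadSet


def brute_rep_table(reads: Sequence[str], K: int) -> dict[str, int]:
    """rep(v) for every read by naive all-pairs, all-lengths scanning.

    Exact matching only (the optimality theorem assumes error-free reads).
    Reads must be distinct and of equal length.
    """
    if len(set(reads)) != len(reads):
        raise ParameterError("reads must be distinct")
    if not reads:
        return {}
    L = len(reads[0])
    if any(len(r) != L for r in reads):
        raise ParameterError("reads must have equal length")
    if not 1 <= K <= L:
        raise ParameterError(f"K={K} outside [1, L={L}]")
    table: dict[str, int] = {}
    for v in reads:
        best = 0
        for u in reads:
            if u == v:
                continue
            for l in range(L - 1, best, -1):
                if u[L - l:] == v[:l]:
                    best = max(best, l)
                    break
        table[v] = L - best if best >= K else L
    return table


def rep_table_lengthscan(reads: Sequence[str], K: int) -> np.ndarray:
    """rep(v) for every read by exhaustive per-length sorted matching.

    For each overlap length l from L-1 down to K, every read's l-prefix is
    matched against the sorted multiset of all l-suffixes; a read resolves
    at the first (longest) l for which some *other* read's suffix equals its
    prefix.  Returns rep values aligned with the input order.
    """
    if len(set(reads)) != len(reads):
        raise ParameterError("reads must be distinct")
    n = len(reads)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    L = len(reads[0])
    if any(len(r) != L for r in reads):
        raise ParameterError("reads must have equal length")
    if not 1 <= K <= L:
        raise ParameterError(f"K={K} outside [1, L={L}]")
    A = np.frombuffer("".join(reads).encode("ascii"), dtype=np.uint8).reshape(n, L)
    rep = np.full(n, L, dtype=np.int64)
    unresolved = np.arange(n)
    for l in range(L - 1, K - 1, -1):
        if unresolved.size == 0:
            break
        dt = f"S{l}"
        suff = np.frombuffer(np.ascontiguousarray(A[:, L - l:]).tobytes(), dtype=dt)
        pref = np.frombuffer(
            np.ascontiguousarray(A[unresolved, :l]).tobytes(), dtype=dt)
        ss = np.sort(suff)
        lo = np.searchsorted(ss, pref, side="left")
        hi = np.searchsorted(ss, pref, side="right")
        cnt = hi - lo
        self_eq = suff[unresolved] == pref
        hit = (cnt >= 2) | ((cnt >= 1) & ~self_eq)
        rep[unresolved[hit]] = L - l
        unresolved = unresolved[~hit]
    return rep


def _max_overlap(a: str, b: str) -> int:
    """Longest l with suffix(a, l) == prefix(b, l)."""
    for l in range(min(len(a), len(b)), 0, -1):
        if a[-l:] == b[:l]:
            return l
    return 0


def brute_scs_length(reads: Sequence[str]) -> int:
    """Exact shortest-common-superstring length by permutation enumeration.

    Reads contained in other reads are removed first (required for
    permutation-merge exactness).  Restricted to n <= 8 distinct reads.
    """
    if len(set(reads)) != len(reads):
        raise ParameterError("reads must be distinct")
    kept = [r for r in reads
            if not any(r in s for s in reads if s != r and len(s) >= len(r))]
    # two equal-length reads cannot contain each other unless equal (excluded)
    if len(kept) > 8:
        raise ParameterError(f"n={len(kept)} too large for factorial enumeration")
    if not kept:
        return 0
    if len(kept) == 1:
        return len(kept[0])
    n = len(kept)
    ov = [[0 if i == j else _max_overlap(kept[i], kept[j]) for j in range(n)]
          for i in range(n)]
    total_len = sum(len(r) for r in kept)
    best = total_len
    for perm in permutations(range(n)):
        merged = total_len - sum(ov[perm[i]][perm[i + 1]] for i in range(n - 1))
        best = min(best, merged)
    return best


def multiset_equal(a: ReadSet, b: ReadSet) -> bool:
    """True iff the two sequence multisets coincide, order ignored."""
    return Counter(a.reads) == Counter(b.reads)
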