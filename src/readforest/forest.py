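"""Greedy construction of a minimum-total-weight read forest.

A read forest is a directed graph over the distinct reads in which every node
has at most one outgoing edge, to its *parent*: a previously processed read
whose suffix covers the node's prefix.  The edge weight w(v, u) = L - l is
the number of bases of v NOT covered by the overlap of length l; roots cost a
full L.  The total weight — the number of consensus symbols the compressed
representation must store — is provably minimized by the greedy procedure
implemented here (for error-free reads): each incoming read first searches
for the best available parent, then adopts as children any existing nodes
that overlap it better than their current parents do.

Candidate overlaps are found with two K-mer hash tables (read prefixes and
read suffixes).  A hash hit is an *exact* K-base seed; the rest of the
overlap is verified allowing at most ``eps`` mismatches (seed-and-extend).
Because tables are keyed by the K-mer string itself, hash collisions cannot
produce false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .exceptions import ParameterError
from .io_formats import ReadSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def default_k(L: int) -> int:
    """Default minimum overlap / seed length: floor(L / 5), at least 1."""
    return max(1, L // 5)


@dataclass(slots=True)
class Node:
    """One distinct (oriented) read in the forest.

    ``copies`` records, per input occurrence collapsed into this node, the
    orientation flag (True if the emitted read is the reverse complement of
    ``seq``) and the N positions of that occurrence in emitted-read
    coordinates.  ``multiplicity`` is ``len(copies)``.
    """

    id: int
    seq: str
    parent: Optional[int] = None
    edge_weight: int = 0
    copies: list[tuple[bool, tuple[int, ...]]] = field(default_factory=list)

    @property
    def multiplicity(self) -> int:
        return len(self.copies)

    @property
    def reversed(self) -> bool:
        """True if any stored copy is emitted reverse-complemented."""
        return any(rev for rev, _ in self.copies)


def _hamming_leq(a: str, b: str, eps: int) -> bool:
    """True iff Hamming(a, b) <= eps (fast paths for the common cases)."""
    if a == b:
        return True
    if eps == 0:
        return False
    budget = eps
    for x, y in zip(a, b):
        if x != y:
            budget -= 1
            if budget < 0:
                return False
    return True


def _validate_overlap(parent_seq: str, child_seq: str, l: int, K: int, eps: int) -> bool:
    """Check a candidate suffix(parent)/prefix(child) overlap of length l.

    The last K bases of the overlap must match exactly (the seed); the
    remaining l-K positions may differ in at most eps places.
    """
    if child_seq[l - K:l] != parent_seq[len(parent_seq) - K:]:
        return False
    L = len(parent_seq)
    return _hamming_leq(child_seq[: l - K], parent_seq[L - l: L - K], eps)


def suffix_prefix_overlap(u_seq: str, v_seq: str, K: int, eps: int) -> Optional[int]:
    """Longest l in [K, L] such that the suffix of ``u_seq`` covers the
    prefix of ``v_seq``: the last K bases of the overlap match exactly and
    the remaining l-K positions differ in at most ``eps`` places.

    Scans l from L down to K and returns the first (largest) valid l, or
    None if no overlap of length >= K exists.
    """
    L = len(u_seq)
    if len(v_seq) != L:
        raise ParameterError("reads must have equal length")
    if not 1 <= K <= L:
        raise ParameterError(f"K={K} outside [1, L={L}]")
    if eps < 0:
        raise ParameterError("eps must be >= 0")
    for l in range(L, K - 1, -1):
        if _validate_overlap(u_seq, v_seq, l, K, eps):
            return l
    return None


class ReadForest:
    """Parent-function graph over distinct reads, with its K-mer indices."""

    def __init__(self, L: int, K: int, eps: int = 0, strand_correct: bool = False) -> None:
        if K < 1:
            raise ParameterError("K must be >= 1")
        if L and K > L:
            raise ParameterError(f"K={K} exceeds read length L={L}")
        if eps < 0:
            raise ParameterError("eps must be >= 0")
        self.L = L
        self.K = K
        self.eps = eps
        self.strand_correct = strand_correct
        self.nodes: list[Node] = []
        self._seq_to_id: dict[str, int] = {}
        # K-mer -> node ids in insertion (ascending id) order
        self._prefix_index: dict[str, list[int]] = {}
        self._suffix_index: dict[str, list[int]] = {}

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_distinct(self) -> int:
        return len(self.nodes)

    @property
    def n_total(self) -> int:
        return sum(n.multiplicity for n in self.nodes)

    def children_counts(self) -> list[int]:
        counts = [0] * len(self.nodes)
        for node in self.nodes:
            if node.parent is not None:
                counts[node.parent] += 1
        return counts

    # -- construction -----------------------------------------------------

    def _find_parent(self, seq: str) -> tuple[Optional[int], int]:
        """Greedy parent search: slide the K-window right-to-left over
        ``seq`` and return (parent id, overlap l) for the first (longest)
        validated hit; (None, 0) if none.

        Overlaps are capped at L-1 so that every node contributes at least
        one consensus symbol (a weight-0 edge is possible only with eps > 0
        and is deliberately not taken).
        """
        L, K, eps = self.L, self.K, self.eps
        suffix_index = self._suffix_index
        nodes = self.nodes
        for l in range(L - 1, K - 1, -1):
            hits = suffix_index.get(seq[l - K:l])
            if not hits:
                continue
            for uid in hits:
                u_seq = nodes[uid].seq
                if eps == 0:
                    if u_seq[L - l:] == seq[:l]:
                        return uid, l
                elif _validate_overlap(u_seq, seq, l, K, eps):
                    return uid, l
        return None, 0

    def _adopt_children(self, node: Node) -> None:
        """Children search: slide the K-window left-to-right over the new
        node, querying the prefix index; any existing node that overlaps the
        new node more tightly than its current parent is re-parented.  Each
        candidate can only improve (windows are visited best-first), so no
        node is reassigned twice per call."""
        L, K, eps = self.L, self.K, self.eps
        prefix_index = self._prefix_index
        nodes = self.nodes
        seq = node.seq
        nid = node.id
        for s in range(1, L - K + 1):  # new weight = s, overlap l = L - s
            hits = prefix_index.get(seq[s:s + K])
            if not hits:
                continue
            l = L - s
            for uid in hits:
                if uid == nid:
                    continue
                u = nodes[uid]
                if u.edge_weight <= s:  # roots carry weight L
                    continue
                u_seq = u.seq
                if eps == 0:
                    ok = u_seq[:l] == seq[s:]
                else:
                    ok = _validate_overlap(seq, u_seq, l, K, eps)
                if ok:
                    u.parent = nid
                    u.edge_weight = s

    def integrate_read(self, seq: str) -> Node:
        """Insert one distinct oriented read: parent search (both strands if
        strand correction is enabled), children search, index insertion.
        ``seq`` must not already be present."""
        nid = len(self.nodes)
        if self.strand_correct:
            rc = revcomp(seq)
            pid_f, l_f = self._find_parent(seq)
            pid_r, l_r = self._find_parent(rc) if rc != seq else (None, 0)
            if l_r > l_f:  # tie -> keep the forward strand
                seq, pid, l = rc, pid_r, l_r
            else:
                pid, l = pid_f, l_f
        else:
            pid, l = self._find_parent(seq)
        weight = self.L - l if pid is not None else self.L
        node = Node(id=nid, seq=seq, parent=pid, edge_weight=weight)
        self.nodes.append(node)
        self._seq_to_id[seq] = nid
        self._adopt_children(node)
        self._prefix_index.setdefault(seq[: self.K], []).append(nid)
        self._suffix_index.setdefault(seq[self.L - self.K:], []).append(nid)
        return node

    def add_read(self, raw_seq: str) -> Node:
        """Add one input read occurrence (the public entry point).

        N symbols are substituted by the placeholder base 'A' for matching;
        true N positions are recorded on the stored copy.  Exact duplicates
        of an already committed oriented read (or, with strand correction,
        of its reverse complement) collapse into that node.
        """
        n_offsets = tuple(i for i, c in enumerate(raw_seq) if c == "N")
        seq = raw_seq.replace("N", "A") if n_offsets else raw_seq
        existing = self._seq_to_id.get(seq)
        if existing is not None:
            self.nodes[existing].copies.append((False, n_offsets))
            return self.nodes[existing]
        if self.strand_correct:
            rc = revcomp(seq)
            existing = self._seq_to_id.get(rc)
            if existing is not None:
                # stored string is the RC of this occurrence; N offsets stay
                # in emitted-read coordinates.
                self.nodes[existing].copies.append((True, n_offsets))
                return self.nodes[existing]
        node = self.integrate_read(seq)
        rev = node.seq != seq  # strand correction may have flipped it
        # N offsets are kept in emitted-read coordinates: if the stored
        # string is the RC, decode emits revcomp(node.seq) == the original
        # (N-substituted) read, so the original offsets apply unchanged.
        node.copies.append((rev, n_offsets))
        return node


def build_forest(
    rs: ReadSet,
    K: Optional[int] = None,
    eps: int = 0,
    strand_correct: bool = False,
) -> ReadForest:
    """Build the minimum-total-weight read forest for a read multiset.

    Exact duplicate reads are collapsed into single nodes with multiplicity;
    distinct reads are integrated greedily in input order.  With ``eps = 0``
    the result provably attains the per-node lower bound sum(rep(v))
    regardless of input order.

    Parameters
    ----------
    rs:
        Validated fixed-length read multiset.
    K:
        Minimum overlap / seed length; defaults to floor(L / 5).
    eps:
        Maximum mismatches allowed in an overlap outside the exact K-seed.
    strand_correct:
        If True, each read commits to the orientation (forward or reverse
        complement) giving the longer parent overlap.
    """
    L = rs.L
    if K is None:
        K = default_k(L)
    forest = ReadForest(L=L, K=K, eps=eps, strand_correct=strand_correct)
    for seq in rs.reads:
        forest.add_read(seq)
    return forest


def total_weight(forest: ReadForest) -> int:
    """Sum of edge weights over all nodes (roots contribute L; multiplicity
    does not multiply weight)."""
    return sum(node.edge_weight for node in forest.nodes)


def integrate_read(forest: ReadForest, seq: str) -> Node:
    """Module-level alias for :meth:`ReadForest.integrate_read`."""
    return forest.integrate_read(seq)


def find_cycles(forest: ReadForest) -> list[list[int]]:
    """Return all cycles (as id lists) in the parent-function graph.

    Because each node has at most one outgoing edge, every connected
    component contains at most one cycle; cycles are returned with their
    smallest node id first, ordered parent-before-child along the cycle.
    """
    state = [0] * len(forest.nodes)  # 0 unseen, 1 on stack, 2 done
    cycles: list[list[int]] = []
    for start in range(len(forest.nodes)):
        if state[start]:
            continue
        path: list[int] = []
        v: Optional[int] = start
        while v is not None and state[v] == 0:
            state[v] = 1
            path.append(v)
            v = forest.nodes[v].parent
        if v is not None and state[v] == 1:
            cyc = path[path.index(v):]
            # orient parent-before-child starting from the smallest id:
            # path lists child -> parent, so reverse it.
            cyc = cyc[::-1]
            m = cyc.index(min(cyc))
            cycles.append(cyc[m:] + cyc[:m])
        for u in path:
            state[u] = 2
    return cycles
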