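"""Container codec: forest -> contigs -> byte-exact archive -> read multiset.

The read forest is decomposed into *contigs*: cycles are detected and emitted
first (a cycle is the root of its component), then each remaining node is
covered by a leaf-to-root walk that stops at the first already-claimed node.
Every contig is serialized as a small tuple — parent-contig pointer,
parent-read index, per-read differential codes (the edge weights, Huffman
coded), its consensus symbols, and per-read mismatch records — so that the
number of consensus symbols stored equals the forest's total weight exactly.

Roots with no children ("neither a parent nor a child could be identified")
bypass the contig machinery entirely and go to a raw 2-bit singleton stream.
Auxiliary streams carry multiplicities (Elias gamma), per-copy strand flags
(only when strand correction was enabled), and per-copy N positions, making
the archive lossless and self-contained.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass, field
from typing import Optional

from ._bitio import (
    BitReader,
    BitWriter,
    DeltaCoder,
    offset_width,
    pack_bases,
    unpack_bases,
)
from .exceptions import ContainerFormatError, ContainerIntegrityError
from .forest import ReadForest, find_cycles, revcomp
from .io_formats import ReadSet

MAGIC = b"ATRF"
VERSION = 1

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}

_HEADER = struct.Struct("<4sBBBBIIQQQQ")
# magic, version, flags, eps, pad, L, K, N_total, distinct, n_contigs, n_singletons


@dataclass
class Contig:
    """A leaf-to-root path (or cycle) of the forest: the unit of encoding.

    ``deltas`` lists per-read edge weights in root-to-leaf order; their sum
    is ``len(consensus)``.  ``errors[i]`` holds (offset, base) mismatch
    records of read i against its consensus-derived string.  For a cycle
    contig, ``parent_contig`` equals the contig's own id.
    """

    id: int
    node_ids: list[int]
    deltas: list[int]
    consensus: str = ""
    errors: list[list[tuple[int, str]]] = field(default_factory=list)
    parent_contig: Optional[int] = None
    parent_read_index: Optional[int] = None
    is_cycle: bool = False

    @property
    def n_reads(self) -> int:
        return len(self.node_ids)


def _cycle_raw(consensus: str, s_i: int, L: int) -> str:
    """Read of length L ending at position s_i of a circular consensus."""
    C = len(consensus)
    start = s_i - L
    return "".join(consensus[(start + t) % C] for t in range(L))


def _diff(actual: str, raw: str) -> list[tuple[int, str]]:
    if actual == raw:
        return []
    return [(i, a) for i, (a, b) in enumerate(zip(actual, raw)) if a != b]


def decompose(forest: ReadForest) -> list[Contig]:
    """Break the forest into disjoint contigs.

    Cycle contigs come first (so that attached trees can point into them),
    then leaf-to-root walks in ascending leaf id; every parent_contig id
    refers to an earlier contig (or to itself, for cycles).
    """
    L = forest.L
    nodes = forest.nodes
    contigs: list[Contig] = []
    where: dict[int, tuple[int, int]] = {}  # node id -> (contig id, read idx)

    def emit(node_ids: list[int], **kw) -> Contig:
        cid = len(contigs)
        contig = Contig(id=cid, node_ids=node_ids,
                        deltas=[nodes[n].edge_weight for n in node_ids], **kw)
        for idx, nid in enumerate(node_ids):
            where[nid] = (cid, idx)
        contigs.append(contig)
        return contig

    for cyc in find_cycles(forest):
        contig = emit(cyc, is_cycle=True)
        contig.parent_contig = contig.id
        # consensus: each read contributes its last d_i bases at [s_i-d_i, s_i)
        parts = []
        for nid in cyc:
            d = nodes[nid].edge_weight
            parts.append(nodes[nid].seq[L - d:])
        contig.consensus = "".join(parts)
        s = 0
        for nid in cyc:
            s += nodes[nid].edge_weight
            contig.errors.append(_diff(nodes[nid].seq, _cycle_raw(contig.consensus, s, L)))

    counts = forest.children_counts()
    for leaf in range(len(nodes)):
        if counts[leaf] != 0 or leaf in where:
            continue
        path = []
        v: Optional[int] = leaf
        while v is not None and v not in where:
            path.append(v)
            v = nodes[v].parent
        path.reverse()  # root-to-leaf
        contig = emit(path)
        if v is not None:
            contig.parent_contig, contig.parent_read_index = where[v]
        contig.consensus = "".join(
            nodes[nid].seq[L - nodes[nid].edge_weight:] for nid in path
        )
        # chain reconstruction: read i borrows its uncovered prefix from its
        # parent read's (already exact) string.
        prev = nodes[v].seq if v is not None else None
        off = 0
        for nid in path:
            d = nodes[nid].edge_weight
            new = contig.consensus[off: off + d]
            raw = new if prev is None else prev[d:] + new
            contig.errors.append(_diff(nodes[nid].seq, raw))
            prev = nodes[nid].seq
            off += d
    return contigs


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def _pri_width(n_reads: int) -> int:
    """ceil(log2 n) bits for a parent-read index into an n-read contig."""
    return (n_reads - 1).bit_length() if n_reads > 1 else 0


def encode_container(forest: ReadForest) -> bytes:
    """Serialize a read forest into the self-contained binary container."""
    L = forest.L
    nodes = forest.nodes
    counts = forest.children_counts()
    all_contigs = decompose(forest)

    singleton_ids = [
        c.node_ids[0] for c in all_contigs
        if not c.is_cycle and c.parent_contig is None and c.n_reads == 1
        and counts[c.node_ids[0]] == 0
    ]
    singleton_set = set(singleton_ids)
    contigs = [c for c in all_contigs
               if not (c.n_reads == 1 and c.node_ids[0] in singleton_set)]
    # renumber surviving contigs (nothing ever points at a singleton contig)
    remap = {c.id: i for i, c in enumerate(contigs)}
    for i, c in enumerate(contigs):
        c.parent_contig = remap[c.parent_contig] if c.parent_contig is not None else None
        c.id = i

    # global distinct-read output order: contig reads, then singletons
    ordered_nodes = [nid for c in contigs for nid in c.node_ids] + singleton_ids

    delta_coder = DeltaCoder(L) if contigs else None
    offw = offset_width(L) if L else 1

    meta = BitWriter()
    errw = BitWriter()
    consensus_parts: list[str] = []
    for c in contigs:
        meta.write_bits(1 if c.is_cycle else 0, 1)
        has_parent = c.parent_contig is not None and not c.is_cycle
        meta.write_bits(1 if has_parent else 0, 1)
        meta.write_gamma(c.n_reads)
        if has_parent:
            meta.write_gamma(c.parent_contig + 1)
            meta.write_bits(c.parent_read_index, _pri_width(contigs[c.parent_contig].n_reads))
        for d in c.deltas:
            delta_coder.encode(meta, d)
        consensus_parts.append(c.consensus)
        for recs in c.errors:
            errw.write_gamma(len(recs) + 1)
            for off, base in recs:
                errw.write_bits(off, offw)
                errw.write_bits(_BASE_CODE[base], 2)

    consensus_stream = zlib.compress(pack_bases("".join(consensus_parts)), 9)
    singleton_stream = zlib.compress(
        pack_bases("".join(nodes[nid].seq for nid in singleton_ids)), 9)

    multw = BitWriter()
    revw = BitWriter()
    nposw = BitWriter()
    n_records = []
    copy_idx = 0
    for nid in ordered_nodes:
        node = nodes[nid]
        multw.write_gamma(node.multiplicity)
        for rev, n_offs in node.copies:
            if forest.strand_correct:
                revw.write_bits(1 if rev else 0, 1)
            for off in n_offs:
                n_records.append((copy_idx, off))
            copy_idx += 1
    nposw.write_gamma(len(n_records) + 1)
    prev_idx = 0
    for idx, off in n_records:
        nposw.write_gamma(idx - prev_idx + 1)
        nposw.write_bits(off, offw)
        prev_idx = idx

    flags = 1 if forest.strand_correct else 0
    header = _HEADER.pack(
        MAGIC, VERSION, flags, forest.eps, 0, L, forest.K,
        forest.n_total, len(nodes), len(contigs), len(singleton_ids),
    )
    streams = [meta.getvalue(), consensus_stream, errw.getvalue(),
               singleton_stream, multw.getvalue(), nposw.getvalue()]
    if forest.strand_correct:
        streams.append(revw.getvalue())
    body = b"".join(struct.pack("<Q", len(s)) + s for s in streams)
    return header + body


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def _read_stream(data: bytes, pos: int) -> tuple[bytes, int]:
    if pos + 8 > len(data):
        raise ContainerIntegrityError("container truncated (stream header)")
    (n,) = struct.unpack_from("<Q", data, pos)
    pos += 8
    if pos + n > len(data):
        raise ContainerIntegrityError("container truncated (stream body)")
    return data[pos: pos + n], pos + n


def decode_container(data: bytes) -> ReadSet:
    """Reconstruct the original read multiset from a container.

    The output order is the codec's canonical order (contig reads
    root-to-leaf, then singletons), not the order of the compressed file.
    """
    if len(data) < _HEADER.size:
        raise ContainerFormatError("container shorter than header")
    (magic, version, flags, eps, _pad, L, K, n_total, distinct,
     n_contigs, n_singletons) = _HEADER.unpack_from(data, 0)
    if magic != MAGIC:
        raise ContainerFormatError(f"bad magic {magic!r}")
    if version != VERSION:
        raise ContainerFormatError(f"unsupported container version {version}")
    strand = bool(flags & 1)

    pos = _HEADER.size
    meta_b, pos = _read_stream(data, pos)
    consensus_b, pos = _read_stream(data, pos)
    err_b, pos = _read_stream(data, pos)
    singleton_b, pos = _read_stream(data, pos)
    mult_b, pos = _read_stream(data, pos)
    npos_b, pos = _read_stream(data, pos)
    rev_b = b""
    if strand:
        rev_b, pos = _read_stream(data, pos)

    delta_coder = DeltaCoder(L) if n_contigs else None
    offw = offset_width(L) if L else 1

    # contig metadata
    meta = BitReader(meta_b)
    contig_hdrs = []  # (is_cycle, parent_contig, parent_read_index, deltas)
    n_reads_by_contig: list[int] = []
    for _ in range(n_contigs):
        is_cycle = bool(meta.read_bits(1))
        has_parent = bool(meta.read_bits(1))
        n_reads = meta.read_gamma()
        parent = pri = None
        if has_parent:
            parent = meta.read_gamma() - 1
            if parent >= len(n_reads_by_contig):
                raise ContainerIntegrityError("parent contig refers forward")
            pri = meta.read_bits(_pri_width(n_reads_by_contig[parent]))
            if pri >= n_reads_by_contig[parent]:
                raise ContainerIntegrityError("parent read index out of range")
        deltas = [delta_coder.decode(meta) for _ in range(n_reads)]
        contig_hdrs.append((is_cycle, parent, pri, deltas))
        n_reads_by_contig.append(n_reads)

    total_consensus = sum(sum(h[3]) for h in contig_hdrs)
    try:
        consensus_all = unpack_bases(zlib.decompress(consensus_b), total_consensus)
    except (zlib.error, ValueError) as exc:
        # also covers a delta sum exceeding the stored consensus length
        raise ContainerIntegrityError(f"consensus stream corrupt: {exc}") from exc

    errs = BitReader(err_b)
    contig_reads: list[list[str]] = []
    cons_off = 0
    for is_cycle, parent, pri, deltas in contig_hdrs:
        C = sum(deltas)
        consensus = consensus_all[cons_off: cons_off + C]
        cons_off += C
        reads: list[str] = []
        if is_cycle:
            s = 0
            for d in deltas:
                s += d
                raw = _cycle_raw(consensus, s, L)
                reads.append(_apply_errors(raw, errs, offw))
        else:
            prev = contig_reads[parent][pri] if parent is not None else None
            off = 0
            for d in deltas:
                new = consensus[off: off + d]
                raw = new if prev is None else prev[d:] + new
                read = _apply_errors(raw, errs, offw)
                if len(read) != L:
                    raise ContainerIntegrityError("reconstructed read length mismatch")
                reads.append(read)
                prev = read
                off += d
        contig_reads.append(reads)

    try:
        singles = unpack_bases(zlib.decompress(singleton_b), n_singletons * L)
    except (zlib.error, ValueError) as exc:
        raise ContainerIntegrityError(f"singleton stream corrupt: {exc}") from exc
    singleton_reads = [singles[i * L:(i + 1) * L] for i in range(n_singletons)]

    distinct_reads = [r for reads in contig_reads for r in reads] + singleton_reads
    if len(distinct_reads) != distinct:
        raise ContainerIntegrityError(
            f"decoded {len(distinct_reads)} distinct reads, header says {distinct}")

    mult = BitReader(mult_b)
    multiplicities = [mult.read_gamma() for _ in range(distinct)]
    n_copies = sum(multiplicities)
    if n_copies != n_total:
        raise ContainerIntegrityError("multiplicity sum does not match read count")

    revbits = BitReader(rev_b)
    out: list[str] = []
    for seq, m in zip(distinct_reads, multiplicities):
        rc = revcomp(seq) if strand else None
        for _ in range(m):
            if strand and revbits.read_bits(1):
                out.append(rc)
            else:
                out.append(seq)

    npos = BitReader(npos_b)
    n_records = npos.read_gamma() - 1
    idx = 0
    pending: dict[int, list[int]] = {}
    for _ in range(n_records):
        idx += npos.read_gamma() - 1
        off = npos.read_bits(offw)
        if idx >= n_copies or off >= L:
            raise ContainerIntegrityError("N record out of range")
        pending.setdefault(idx, []).append(off)
    for idx, offs in pending.items():
        chars = list(out[idx])
        for off in offs:
            chars[off] = "N"
        out[idx] = "".join(chars)

    return ReadSet(reads=out, L=L)


def _apply_errors(raw: str, errs: BitReader, offw: int) -> str:
    n = errs.read_gamma() - 1
    if n == 0:
        return raw
    chars = list(raw)
    for _ in range(n):
        off = errs.read_bits(offw)
        base = _BASES[errs.read_bits(2)]
        if off >= len(chars):
            raise ContainerIntegrityError("error record offset out of range")
        chars[off] = base
    return "".join(chars)


# ---------------------------------------------------------------------------
# Stats
# ---------------------------------------------------------------------------

def container_stats(data: bytes) -> dict:
    """Header fields and per-stream sizes of a container, without decoding."""
    if len(data) < _HEADER.size or data[:4] != MAGIC:
        raise ContainerFormatError("not a readforest container")
    (magic, version, flags, eps, _pad, L, K, n_total, distinct,
     n_contigs, n_singletons) = _HEADER.unpack_from(data, 0)
    names = ["contig_meta", "consensus", "errors", "singletons",
             "multiplicities", "n_positions"]
    if flags & 1:
        names.append("rev_flags")
    pos = _HEADER.size
    sizes = {}
    for name in names:
        stream, pos = _read_stream(data, pos)
        sizes[name] = len(stream)
    total_bases = n_total * L
    return {
        "version": version,
        "L": L,
        "K": K,
        "eps": eps,
        "strand_correct": bool(flags & 1),
        "n_total": n_total,
        "n_distinct": distinct,
        "n_contigs": n_contigs,
        "n_singletons": n_singletons,
        "stream_bytes": sizes,
        "total_bytes": len(data),
        "total_bits": 8 * len(data),
        "bits_per_base": 8 * len(data) / total_bases if total_bases else float("nan"),
    }
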