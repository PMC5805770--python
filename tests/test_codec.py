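"""Contig decomposition, delta coding, and container round trips."""

import itertools

import pytest

from readforest._bitio import BitReader, BitWriter, DeltaCoder
from readforest.codec import (
    container_stats,
    decode_container,
    decompose,
    encode_container,
)
from readforest.exceptions import (
    ContainerFormatError,
    ContainerIntegrityError,
    ParameterError,
)
from readforest.forest import build_forest, total_weight
from readforest.io_formats import ReadSet
from readforest.oracle import multiset_equal

from conftest import inject_ns, simulated_reads

FIVE_READS = ["ACGT", "CGTA", "GTAC", "TACG", "ACGG"]


def roundtrip(rs, **kw):
    forest = build_forest(rs, **kw)
    data = encode_container(forest)
    return forest, data, decode_container(data)


# ---------------------------------------------------------------------------
# bit primitives and delta code
# ---------------------------------------------------------------------------

def test_bit_writer_reader_round_trip():
    w = BitWriter()
    w.write_bits(0b1011, 4)
    w.write_gamma(1)
    w.write_gamma(17)
    w.write_bits(0, 0)
    r = BitReader(w.getvalue())
    assert r.read_bits(4) == 0b1011
    assert r.read_gamma() == 1
    assert r.read_gamma() == 17


def test_bit_reader_truncation_raises():
    r = BitReader(b"\xff")
    r.read_bits(8)
    with pytest.raises(ContainerIntegrityError):
        r.read_bits(1)


def test_delta_round_trip():
    coder = DeltaCoder(8)
    w = BitWriter()
    for d in [1, 1, 5, 8, 3]:
        coder.encode(w, d)
    r = BitReader(w.getvalue())
    assert [coder.decode(r) for _ in range(5)] == [1, 1, 5, 8, 3]


@pytest.mark.parametrize("L", [1, 2, 5, 8, 21, 64])
def test_delta_codebook_prefix_free(L):
    book = DeltaCoder(L).book
    codes = {sym: format(code, f"0{ln}b") for sym, (code, ln) in book.items()}
    assert len(codes) == L
    for a, b in itertools.permutations(codes.values(), 2):
        assert not b.startswith(a)


@pytest.mark.parametrize("L", [2, 8, 64, 100])
def test_delta_code_lengths_monotone_in_symbol(L):
    book = DeltaCoder(L).book
    assert book[1][1] <= book[L][1]


def test_delta_out_of_range():
    coder = DeltaCoder(8)
    w = BitWriter()
    with pytest.raises(ParameterError):
        coder.encode(w, 0)
    with pytest.raises(ParameterError):
        coder.encode(w, 9)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def test_decompose_five_read_example():
    forest = build_forest(ReadSet.from_sequences(FIVE_READS), K=2, eps=0)
    contigs = decompose(forest)
    assert len(contigs) == 2
    cycle, tail = contigs
    assert cycle.is_cycle and cycle.n_reads == 4
    assert len(cycle.consensus) == 4
    assert cycle.parent_contig == cycle.id
    assert not tail.is_cycle and tail.n_reads == 1
    assert tail.parent_contig == cycle.id
    assert tail.deltas == [1]
    assert forest.nodes[cycle.node_ids[tail.parent_read_index]].seq == "TACG"


def test_decompose_single_root():
    forest = build_forest(ReadSet.from_sequences(["ACGT"]), K=2)
    (contig,) = decompose(forest)
    assert contig.parent_contig is None
    assert contig.deltas == [4]
    assert contig.consensus == "ACGT"


def test_decompose_chain_of_three():
    # each read overlaps the previous by L-1 and nothing wraps around
    forest = build_forest(ReadSet.from_sequences(["AACG", "ACGT", "CGTT"]),
                          K=1, eps=0)
    contigs = decompose(forest)
    assert len(contigs) == 1
    assert contigs[0].deltas == [4, 1, 1]
    assert contigs[0].consensus == "AACGTT"


def test_decompose_covers_every_node_once():
    _, rs = simulated_reads(2000, 250, 40, seed=9)
    forest = build_forest(rs, eps=0)
    contigs = decompose(forest)
    seen = [nid for c in contigs for nid in c.node_ids]
    assert sorted(seen) == list(range(len(forest.nodes)))
    for c in contigs:
        assert sum(c.deltas) == len(c.consensus)
        if c.parent_contig is not None and not c.is_cycle:
            assert c.parent_contig < c.id


# ---------------------------------------------------------------------------
# container encode/decode
# ---------------------------------------------------------------------------

def test_encode_single_read_symbol_budget():
    forest = build_forest(ReadSet.from_sequences(["ACGT"]), K=2)
    stats = container_stats(encode_container(forest))
    # a lone read has no parent and no children: it is a singleton
    assert stats["n_singletons"] == 1
    assert stats["n_contigs"] == 0


def test_consensus_symbols_equal_total_weight():
    for seqs in (FIVE_READS, ["ACGT"], ["AAAA", "CCCC"]):
        forest = build_forest(ReadSet.from_sequences(seqs), K=2, eps=0)
        contigs = decompose(forest)
        counts = forest.children_counts()
        singles = sum(
            1 for c in contigs
            if c.n_reads == 1 and c.parent_contig is None and not c.is_cycle
            and counts[c.node_ids[0]] == 0)
        symbols = sum(len(c.consensus) for c in contigs
                      if not (c.n_reads == 1 and c.parent_contig is None
                              and not c.is_cycle and counts[c.node_ids[0]] == 0))
        assert symbols + singles * forest.L == total_weight(forest)


def test_five_read_container_round_trip():
    rs = ReadSet.from_sequences(FIVE_READS)
    _, _, out = roundtrip(rs, K=2, eps=0)
    assert multiset_equal(rs, out)


def test_duplicates_expand_on_decode():
    rs = ReadSet.from_sequences(["ACGT"] * 3)
    _, _, out = roundtrip(rs, K=2)
    assert out.reads == ["ACGT"] * 3


def test_n_positions_restored():
    rs = ReadSet.from_sequences(["ACGN"])
    forest, data, out = roundtrip(rs, K=2)
    assert forest.nodes[0].seq == "ACGA"  # placeholder base used internally
    assert out.reads == ["ACGN"]


def test_reads_differing_only_in_n_positions():
    rs = ReadSet.from_sequences(["ACGA", "ACGN", "NCGA"])
    _, _, out = roundtrip(rs, K=2)
    assert multiset_equal(rs, out)


def test_container_determinism():
    _, rs = simulated_reads(5000, 600, 50, p=0.01, seed=21)
    f1 = build_forest(rs, eps=2)
    f2 = build_forest(rs, eps=2)
    assert encode_container(f1) == encode_container(f2)


@pytest.mark.parametrize("eps,strand,p,flip", [
    (0, False, 0.0, 0.0),
    (0, True, 0.0, 0.3),
    (2, False, 0.01, 0.0),
    (2, True, 0.01, 0.3),
])
def test_lossless_round_trip_grid(eps, strand, p, flip):
    _, rs = simulated_reads(4000, 500, 50, p=p, flip_prob=flip,
                            seed=hash((eps, strand)) % 2**31)
    reads = inject_ns(rs.reads, 0.05, seed=4)
    rs = ReadSet(reads=reads + reads[:25], L=rs.L)  # force duplicates
    _, _, out = roundtrip(rs, eps=eps, strand_correct=strand)
    assert multiset_equal(rs, out)


def test_bad_magic_rejected():
    with pytest.raises(ContainerFormatError):
        decode_container(b"NOPE" + b"\x00" * 60)


def test_unsupported_version_rejected():
    forest = build_forest(ReadSet.from_sequences(["ACGT"]), K=2)
    data = bytearray(encode_container(forest))
    data[4] = 99
    with pytest.raises(ContainerFormatError):
        decode_container(bytes(data))


def test_truncated_container_rejected():
    forest = build_forest(ReadSet.from_sequences(FIVE_READS), K=2)
    data = encode_container(forest)
    with pytest.raises((ContainerIntegrityError, ContainerFormatError)):
        decode_container(data[: len(data) - 6])


def test_stats_reports_sizes():
    _, rs = simulated_reads(2000, 300, 40, seed=5)
    forest = build_forest(rs)
    data = encode_container(forest)
    stats = container_stats(data)
    assert stats["n_total"] == 300
    assert stats["L"] == 40
    assert stats["total_bytes"] == len(data)
    assert 0 < stats["bits_per_base"] < 16
    assert set(stats["stream_bytes"]) == {
        "contig_meta", "consensus", "errors", "singletons",
        "multiplicities", "n_positions"}
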