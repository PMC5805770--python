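"""Bit-level primitives shared by the container codec.

Everything here is deterministic and self-inverse: a decoder reconstructs each
code from the same parameters (read length L) the encoder used, so no codebook
is ever transmitted.
"""

from __future__ import annotations

import heapq

import numpy as np

from .exceptions import ContainerIntegrityError, ParameterError

_BASES = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(_BASES)}


class BitWriter:
    """Append-only MSB-first bit buffer."""

    def __init__(self) -> None:
        self._bytes = bytearray()
        self._acc = 0
        self._nacc = 0  # bits currently in _acc, < 8

    def write_bits(self, value: int, width: int) -> None:
        if width < 0 or (width and value >> width):
            raise ValueError(f"value {value} does not fit in {width} bits")
        acc = (self._acc << width) | value
        nacc = self._nacc + width
        while nacc >= 8:
            nacc -= 8
            self._bytes.append((acc >> nacc) & 0xFF)
        self._acc = acc & ((1 << nacc) - 1)
        self._nacc = nacc

    def write_gamma(self, value: int) -> None:
        """Elias gamma code for a positive integer."""
        if value < 1:
            raise ValueError("Elias gamma requires value >= 1")
        nbits = value.bit_length()
        self.write_bits(0, nbits - 1)
        self.write_bits(value, nbits)

    def getvalue(self) -> bytes:
        """Flush (zero-padding the final byte) and return the buffer."""
        out = bytearray(self._bytes)
        if self._nacc:
            out.append((self._acc << (8 - self._nacc)) & 0xFF)
        return bytes(out)

    def __len__(self) -> int:  # bits written so far
        return 8 * len(self._bytes) + self._nacc


class BitReader:
    """MSB-first reader over bytes; raises on reads past the end."""

    def __init__(self, data: bytes) -> None:
        self._data = data
        self._pos = 0  # bit position

    def read_bits(self, width: int) -> int:
        if width == 0:
            return 0
        end = self._pos + width
        if end > 8 * len(self._data):
            raise ContainerIntegrityError("bit stream truncated")
        value = 0
        pos = self._pos
        data = self._data
        while pos < end:
            byte = data[pos >> 3]
            take = min(8 - (pos & 7), end - pos)
            shift = 8 - (pos & 7) - take
            value = (value << take) | ((byte >> shift) & ((1 << take) - 1))
            pos += take
        self._pos = end
        return value

    def read_gamma(self) -> int:
        nzero = 0
        while self.read_bits(1) == 0:
            nzero += 1
            if nzero > 64:
                raise ContainerIntegrityError("malformed gamma code")
        return (1 << nzero) | self.read_bits(nzero)


# ---------------------------------------------------------------------------
# Canonical Huffman code over delta symbols {1..L}
# ---------------------------------------------------------------------------

_GEOMETRIC_DECAY = 0.85  # weight profile P(d) ~ decay**(d-1)


def delta_code_lengths(L: int) -> list[int]:
    """Huffman code lengths for symbols 1..L under a truncated geometric
    weight profile.  Deterministic: ties are broken by symbol order."""
    if L < 1:
        raise ParameterError("L must be >= 1")
    if L == 1:
        return [1]
    heap = [(_GEOMETRIC_DECAY ** (d - 1), d, (d,)) for d in range(1, L + 1)]
    heapq.heapify(heap)
    lengths = [0] * (L + 1)
    while len(heap) > 1:
        w1, o1, s1 = heapq.heappop(heap)
        w2, o2, s2 = heapq.heappop(heap)
        for d in s1 + s2:
            lengths[d] += 1
        heapq.heappush(heap, (w1 + w2, min(o1, o2), s1 + s2))
    return lengths[1:]


def canonical_codebook(lengths: list[int]) -> dict[int, tuple[int, int]]:
    """Map symbol -> (codeword, width) by canonical assignment: codes ordered
    by (length, symbol)."""
    order = sorted(range(len(lengths)), key=lambda i: (lengths[i], i))
    book: dict[int, tuple[int, int]] = {}
    code = 0
    prev_len = 0
    for i in order:
        ln = lengths[i]
        code <<= ln - prev_len
        book[i + 1] = (code, ln)
        code += 1
        prev_len = ln
    return book


class DeltaCoder:
    """Fixed-codebook Huffman coder for per-read deltas in [1, L]."""

    def __init__(self, L: int) -> None:
        self.L = L
        lengths = delta_code_lengths(L)
        self.book = canonical_codebook(lengths)
        # decode table: (width, first_code, symbols sorted canonically)
        by_len: dict[int, list[int]] = {}
        for sym, (_, ln) in self.book.items():
            by_len.setdefault(ln, []).append(sym)
        self._decode: list[tuple[int, int, list[int]]] = []
        for ln in sorted(by_len):
            syms = sorted(by_len[ln], key=lambda s: self.book[s][0])
            self._decode.append((ln, self.book[syms[0]][0], syms))

    def encode(self, writer: BitWriter, delta: int) -> None:
        if not 1 <= delta <= self.L:
            raise ParameterError(f"delta {delta} outside [1, {self.L}]")
        code, width = self.book[delta]
        writer.write_bits(code, width)

    def decode(self, reader: BitReader) -> int:
        code = 0
        width = 0
        for ln, first, syms in self._decode:
            code = (code << (ln - width)) | reader.read_bits(ln - width)
            width = ln
            idx = code - first
            if 0 <= idx < len(syms):
                return syms[idx]
        raise ContainerIntegrityError("invalid delta codeword")


# ---------------------------------------------------------------------------
# 2-bit base packing
# ---------------------------------------------------------------------------

def pack_bases(seq: str) -> bytes:
    """Pack an A/C/G/T string into 2 bits per base (MSB-first)."""
    if not seq:
        return b""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    codes = np.zeros(arr.size, dtype=np.uint8)
    for base, code in _BASE_TO_CODE.items():
        codes[arr == ord(base)] = code
    bits = np.empty(2 * codes.size, dtype=np.uint8)
    bits[0::2] = codes >> 1
    bits[1::2] = codes & 1
    return np.packbits(bits).tobytes()


def unpack_bases(data: bytes, n: int) -> str:
    """Inverse of :func:`pack_bases` for the first *n* bases."""
    if n == 0:
        return ""
    bits = np.unpackbits(np.frombuffer(data, dtype=np.uint8), count=2 * n)
    codes = (bits[0::2] << 1) | bits[1::2]
    lut = np.frombuffer(_BASES.encode("ascii"), dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def offset_width(L: int) -> int:
    """Bit width of a within-read offset in [0, L)."""
    return max(1, (L - 1).bit_length())
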