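"""Byte/bit conversion, 280-bit segmentation, and group-leading-bit access.

Conventions frozen here because every downstream nucleotide depends on them:
bits are most-significant-bit-first within each byte; a message is split into
280-bit segments (56 groups of 5), the last segment zero-padded; the leading
bit of every 5-bit group, concatenated across ALL segments in order, forms the
global first-bit stream that the chaos layer balances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SEGMENT_BITS = 280
GROUPS_PER_SEGMENT = 56
GROUP_BITS = 5

__all__ = [
    "SEGMENT_BITS",
    "GROUPS_PER_SEGMENT",
    "BitSegment",
    "PaddingRecord",
    "bytes_to_bits",
    "bits_to_bytes",
    "segment_message",
    "reassemble_message",
    "extract_first_bits",
    "replace_first_bits",
]


@dataclass
class BitSegment:
    """One 280-bit payload unit, viewable as 56 ordered 5-bit groups."""

    bits: np.ndarray
    segment_index: int

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.shape != (SEGMENT_BITS,):
            raise ValueError(f"segment must hold exactly {SEGMENT_BITS} bits")

    @property
    def groups(self) -> np.ndarray:
        """View as (56, 5); concatenating rows reproduces ``bits``."""
        return self.bits.reshape(GROUPS_PER_SEGMENT, GROUP_BITS)

    def bitstring(self) -> str:
        return "".join("01"[b] for b in self.bits)


@dataclass(frozen=True)
class PaddingRecord:
    """Bookkeeping to undo the zero-padding of the final segment."""

    original_bit_length: int
    pad_bits: int

    def __post_init__(self):
        if not (0 <= self.pad_bits < SEGMENT_BITS):
            raise ValueError("pad_bits must be in [0, 280)")
        if (self.original_bit_length + self.pad_bits) % SEGMENT_BITS:
            raise ValueError("padded length must be a multiple of 280")


def bytes_to_bits(data: bytes) -> np.ndarray:
    return np.unpackbits(np.frombuffer(data, dtype=np.uint8))


def bits_to_bytes(bits: np.ndarray) -> bytes:
    if bits.size % 8:
        raise ValueError("bit length must be a multiple of 8")
    return np.packbits(bits.astype(np.uint8)).tobytes()


def segment_message(payload: bytes):
    """Split a byte string into 280-bit segments (last one zero-padded).

    Returns ``(segments, padding_record)``.
    """
    if not payload:
        raise ValueError("payload must be non-empty")
    bits = bytes_to_bits(payload)
    n_bits = bits.size
    pad = (-n_bits) % SEGMENT_BITS
    if pad:
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    segs = [
        BitSegment(bits[i * SEGMENT_BITS:(i + 1) * SEGMENT_BITS], i)
        for i in range(bits.size // SEGMENT_BITS)
    ]
    return segs, PaddingRecord(original_bit_length=n_bits, pad_bits=pad)


def reassemble_message(segments, padding: PaddingRecord) -> bytes:
    """Inverse of :func:`segment_message` (exact, via the padding record)."""
    bits = np.concatenate([s.bits for s in sorted(segments, key=lambda s: s.segment_index)])
    if bits.size != padding.original_bit_length + padding.pad_bits:
        raise ValueError("segment count inconsistent with padding record")
    return bits_to_bytes(bits[: padding.original_bit_length])


def extract_first_bits(segments) -> np.ndarray:
    """Concatenate the leading bit of every 5-bit group, in stream order."""
    return np.concatenate([s.groups[:, 0] for s in segments])


def replace_first_bits(segments, new_first_bits) -> list:
    """Return new segments with group-leading bits replaced by ``new_first_bits``."""
    new_first_bits = np.asarray(new_first_bits, dtype=np.uint8)
    if new_first_bits.size != GROUPS_PER_SEGMENT * len(segments):
        raise ValueError(
            f"need {GROUPS_PER_SEGMENT * len(segments)} first bits, "
            f"got {new_first_bits.size}"
        )
    out = []
    for j, seg in enumerate(segments):
        g = seg.groups.copy()
        g[:, 0] = new_first_bits[j * GROUPS_PER_SEGMENT:(j + 1) * GROUPS_PER_SEGMENT]
        out.append(BitSegment(g.reshape(-1), seg.segment_index))
    return out
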