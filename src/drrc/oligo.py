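"""Oligo assembly and FASTA I/O.

Each 280-bit segment becomes one 255-nt oligo::

    5' primer (24 nt) | index (15 nt) | payload (168 nt) | RS parity (24 nt) | 3' primer (24 nt)

The 207-nt core (index + payload + parity) is the information-bearing and
error-protected region; primers flank it for PCR amplification and carry no
data.  The index encodes the segment's position through the same dual-rule
codec as the payload, but with its five group-leading bits fixed to the
pattern ``01010`` instead of chaotic bits — so indices are decodable before
the first-bit derandomization (which itself needs the segments in order) and
the fixed pattern doubles as a lightweight integrity check.  Five 5-bit
groups with fixed leading bits leave 20 information bits: up to 1,048,576
addressable segments (≈ 36 MB per pool).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import ecc
from .codec import CodeTable, decode_bases, encode_bits, seq_to_idx
from .ecc import RSConfig

INDEX_NT = 15
PAYLOAD_NT = 168
CORE_NT = 207
PRIMER_NT = 24
FULL_NT = 255
INDEX_LEAD_PATTERN = (0, 1, 0, 1, 0)
INDEX_CAPACITY = 1 << 20

#: Default primers: 50% GC, no run > 2, far apart in Hamming distance.
PRIMER5 = "ACTGACTGCATGCATGACGTACGT"
PRIMER3 = "TGCATGCAGTCAGTCATGACTGAC"

__all__ = [
    "OligoRecord",
    "encode_index",
    "decode_index",
    "assemble_oligo",
    "disassemble_oligo",
    "write_fasta",
    "read_fasta",
]


@dataclass
class OligoRecord:
    """One assembled oligo; ``core`` is what the ecc layer protects."""

    index_value: int
    index_nt: str
    payload_nt: str
    parity_nt: str
    primer5: str = PRIMER5
    primer3: str = PRIMER3

    @property
    def core(self) -> str:
        return self.index_nt + self.payload_nt + self.parity_nt

    @property
    def full(self) -> str:
        return self.primer5 + self.core + self.primer3

    def __post_init__(self):
        if len(self.core) != CORE_NT:
            raise ValueError(f"core must be {CORE_NT} nt")


def encode_index(k: int, table: CodeTable) -> str:
    """Encode a segment position as 15 nt (five dual-rule slices)."""
    if not (0 <= k < INDEX_CAPACITY):
        raise ValueError(f"index {k} outside [0, {INDEX_CAPACITY})")
    payload = [(k >> (19 - i)) & 1 for i in range(20)]
    bits = np.empty(25, dtype=np.uint8)
    for g in range(5):
        bits[5 * g] = INDEX_LEAD_PATTERN[g]
        bits[5 * g + 1: 5 * g + 5] = payload[4 * g: 4 * g + 4]
    from .codec import idx_to_seq
    return idx_to_seq(encode_bits(bits, table))


def decode_index(index_nt: str, table: CodeTable):
    """Inverse of :func:`encode_index`; None when a slice is invalid or the
    fixed leading-bit pattern does not match (corruption guard)."""
    if len(index_nt) != INDEX_NT:
        raise ValueError(f"index field must be {INDEX_NT} nt")
    bits, valid = decode_bases(seq_to_idx(index_nt), table)
    if not valid.all():
        return None
    groups = bits.reshape(5, 5)
    if tuple(groups[:, 0]) != INDEX_LEAD_PATTERN:
        return None
    payload = groups[:, 1:].reshape(-1)
    k = 0
    for b in payload:
        k = (k << 1) | int(b)
    return k


def assemble_oligo(k: int, payload_nt: str, table: CodeTable,
                   rs_config: RSConfig = RSConfig(),
                   primers=(PRIMER5, PRIMER3)) -> OligoRecord:
    """Build one oligo: index, RS parity over index+payload, primers."""
    if len(payload_nt) != PAYLOAD_NT:
        raise ValueError(f"payload must be {PAYLOAD_NT} nt")
    index_nt = encode_index(k, table)
    parity_nt = ecc.rs_encode(index_nt + payload_nt, rs_config)
    return OligoRecord(index_value=k, index_nt=index_nt, payload_nt=payload_nt,
                       parity_nt=parity_nt, primer5=primers[0], primer3=primers[1])


def disassemble_oligo(core_nt: str, table: CodeTable):
    """Split a 207-nt core into (index_value_or_None, index, payload, parity)."""
    if len(core_nt) != CORE_NT:
        raise ValueError(f"core must be {CORE_NT} nt")
    index_nt = core_nt[:INDEX_NT]
    payload_nt = core_nt[INDEX_NT:INDEX_NT + PAYLOAD_NT]
    parity_nt = core_nt[INDEX_NT + PAYLOAD_NT:]
    return decode_index(index_nt, table), index_nt, payload_nt, parity_nt


def strip_primers(seq: str, primer5: str = PRIMER5, primer3: str = PRIMER3) -> str:
    """Remove flanking primers from a read.

    Exact primer match is tried first; otherwise the read is assumed to keep
    its primers intact at the ends (errors confined to the core) and fixed
    24-nt flanks are stripped.
    """
    i = seq.find(primer5)
    start = i + len(primer5) if i != -1 else len(primer5)
    j = seq.rfind(primer3)
    end = j if j >= start else len(seq) - len(primer3)
    return seq[start:end]


def write_fasta(oligos, path) -> None:
    """Write an oligo pool; headers carry only the record ordinal."""
    records = [
        SeqRecord(Seq(o.full if isinstance(o, OligoRecord) else o),
                  id=f"oligo_{i}", description="")
        for i, o in enumerate(oligos)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path):
    """Read raw oligo sequences; returns (sequences, flags).

    ``flags[i]`` is False for records containing non-ACGT characters, which
    must be excluded from recovery statistics.
    """
    seqs, flags = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq).upper()
        seqs.append(s)
        flags.append(all(c in "ACGT" for c in s))
    return seqs, flags
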