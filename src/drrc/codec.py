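"""Dual-rule rotary transcoding between 5-bit groups and 3-nt codewords.

Each 5-bit group ``(s1, s2, s3, s4, s5)`` maps to one 3-nt codeword.  The
leading bit ``s1`` selects one of two complementary sub-tables: under the
0-rule every codeword contains exactly one G/C base, under the 1-rule exactly
two.  Because the leading bits of a message are balanced to ~50% ones before
encoding (see :mod:`drrc.chaos`), the pooled GC content of the output sits at
50%.  Bits 2-3 fix the first base context-free (A=00, T=01, C=11, G=10); bits
4-5 pick the remaining two bases rotary-style, i.e. conditioned on the
preceding base within the same slice, which suppresses homopolymers.

At decode time the rule is recovered by counting G/C in each 3-nt slice
(one -> 0-rule, two -> 1-rule), so decoding is strictly slice-local: a
substitution can never corrupt more than its own 5-bit group.

The full rotary table is not uniquely determined by its constraints; this
module constructs one canonical table deterministically (see
:func:`build_code_table`) and freezes it under a version tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np

__all__ = [
    "BASES",
    "FIRST_BASE_MAP",
    "CodeTable",
    "InvalidSlice",
    "build_code_table",
    "encode_group",
    "encode_segment",
    "detect_rule",
    "decode_segment",
]

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: Context-free first-base mapping for bits 2-3.
FIRST_BASE_MAP = {"00": "A", "01": "T", "11": "C", "10": "G"}
FIRST_BASE_INV = {v: k for k, v in FIRST_BASE_MAP.items()}

#: Entries forced by the scheme's worked example; the table construction must
#: honour these exactly: (rule, base1, bits45) -> (base2, base3).
PINNED_ENTRIES = {
    (1, "C", "01"): ("A", "C"),   # 11101 -> CAC
    (0, "T", "00"): ("C", "A"),   # 00100 -> TCA
    (0, "A", "10"): ("T", "C"),   # 00010 -> ATC
    (1, "C", "10"): ("T", "G"),   # 11110 -> CTG
}

TABLE_VERSION = "drrc-table-1"

_BITS45 = ("00", "01", "10", "11")


def _gc(base: str) -> int:
    return 1 if base in "GC" else 0


class InvalidSlice(ValueError):
    """A 3-nt slice whose G/C count matches neither rule (0 or 3 G/C)."""


@dataclass(frozen=True)
class CodeTable:
    """Frozen dual-rule rotary code table.

    ``rule0``/``rule1`` map ``(base1, bits45) -> (base2, base3)``; the
    ``codeword_set`` holds all 32 valid codewords for Hamming lookups in the
    resynchronization layer.
    """

    rule0: dict
    rule1: dict
    first_base_map: dict
    codeword_set: frozenset
    version: str = TABLE_VERSION
    # vectorization caches, derived in __post_init__
    _enc_lut: np.ndarray = field(default=None, repr=False, compare=False)
    _dec_lut: np.ndarray = field(default=None, repr=False, compare=False)
    _dist_lut: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        enc = np.zeros((32, 3), dtype=np.uint8)
        for g in range(32):
            bits = format(g, "05b")
            cw = _encode_group_raw(bits, self)
            enc[g] = [BASE_INDEX[b] for b in cw]
        dec = np.full(64, 255, dtype=np.uint8)
        for g in range(32):
            idx = enc[g, 0] * 16 + enc[g, 1] * 4 + enc[g, 2]
            dec[idx] = g
        # min Hamming distance from each of the 64 possible slices to the set
        dist = np.zeros(64, dtype=np.uint8)
        cws = [tuple(enc[g]) for g in range(32)]
        for idx in range(64):
            s = (idx // 16, (idx // 4) % 4, idx % 4)
            dist[idx] = min(
                sum(a != b for a, b in zip(s, cw)) for cw in cws
            )
        object.__setattr__(self, "_enc_lut", enc)
        object.__setattr__(self, "_dec_lut", dec)
        object.__setattr__(self, "_dist_lut", dist)

    def rule_table(self, rule: int) -> dict:
        return self.rule0 if rule == 0 else self.rule1

    def validate(self) -> None:
        """Check every structural invariant; raise ``AssertionError`` on failure."""
        cws = set()
        for rule, want_gc in ((0, 1), (1, 2)):
            tab = self.rule_table(rule)
            for base1 in BASES:
                pairs = [tab[(base1, b45)] for b45 in _BITS45]
                if len(set(pairs)) != 4:
                    raise AssertionError(f"non-injective cell rule{rule}/{base1}")
                for (b2, b3), b45 in zip(pairs, _BITS45):
                    cw = base1 + b2 + b3
                    if sum(map(_gc, cw)) != want_gc:
                        raise AssertionError(f"GC count wrong for {cw} (rule {rule})")
                    if cw[0] == cw[1] == cw[2]:
                        raise AssertionError(f"homopolymer codeword {cw}")
                    cws.add(cw)
        if len(cws) != 32 or cws != set(self.codeword_set):
            raise AssertionError("codeword set is not the expected 32 words")
        for (rule, base1, b45), pair in PINNED_ENTRIES.items():
            if self.rule_table(rule)[(base1, b45)] != pair:
                raise AssertionError(f"pinned entry {(rule, base1, b45)} violated")
        # no run > 3 across any pair of adjacent codewords
        for a, b in product(sorted(cws), repeat=2):
            if max_run_str(a + b) > 3:
                raise AssertionError(f"run > 3 across boundary {a}|{b}")

    def to_text(self) -> str:
        """Plain-text audit dump: one line per entry."""
        lines = [f"# {self.version}", "# rule base1 bits45 codeword"]
        for rule in (0, 1):
            tab = self.rule_table(rule)
            for base1 in BASES:
                for b45 in _BITS45:
                    b2, b3 = tab[(base1, b45)]
                    lines.append(f"{rule} {base1} {b45} {base1}{b2}{b3}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CodeTable":
        rule0, rule1 = {}, {}
        version = TABLE_VERSION
        for line in text.splitlines():
            line = line.strip()
            if line.startswith("#"):
                if "table" in line:
                    version = line.lstrip("# ").strip()
                continue
            if not line:
                continue
            rule_s, base1, b45, cw = line.split()
            (rule0 if rule_s == "0" else rule1)[(base1, b45)] = (cw[1], cw[2])
        cws = frozenset(
            b1 + p[0] + p[1]
            for tab in (rule0, rule1)
            for (b1, _), p in tab.items()
        )
        return cls(rule0=rule0, rule1=rule1, first_base_map=dict(FIRST_BASE_MAP),
                   codeword_set=cws, version=version)


def max_run_str(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def _candidate_pairs(rule: int, base1: str) -> list:
    """All (base2, base3) pairs legal in this cell, lexicographic order.

    ``base2 != base1`` is imposed everywhere: no codeword then starts with a
    doubled base, which (with no in-codeword triple) caps homopolymer runs at
    3 even across slice boundaries.
    """
    need = (1 if rule == 0 else 2) - _gc(base1)
    return [
        (b2, b3)
        for b2 in BASES
        for b3 in BASES
        if _gc(b2) + _gc(b3) == need and b2 != base1
    ]


def build_code_table() -> CodeTable:
    """Construct the canonical frozen dual-rule table.

    Pinned worked-example entries are placed first; every remaining
    ``bits45`` slot (in order 00, 01, 10, 11) takes the lexicographically
    smallest unused legal pair.  Deterministic by construction; the result is
    validated before being returned.
    """
    tables = {0: {}, 1: {}}
    for rule in (0, 1):
        for base1 in BASES:
            used = set()
            cell = {}
            for b45 in _BITS45:
                pin = PINNED_ENTRIES.get((rule, base1, b45))
                if pin is not None:
                    cell[b45] = pin
                    used.add(pin)
            for b45 in _BITS45:
                if b45 in cell:
                    continue
                for pair in _candidate_pairs(rule, base1):
                    if pair not in used:
                        cell[b45] = pair
                        used.add(pair)
                        break
                else:  # pragma: no cover - cells always have >= 4 candidates
                    raise RuntimeError(f"unsatisfiable cell rule{rule}/{base1}")
            for b45, pair in cell.items():
                tables[rule][(base1, b45)] = pair
    cws = frozenset(
        b1 + p[0] + p[1]
        for rule in (0, 1)
        for (b1, _), p in tables[rule].items()
    )
    table = CodeTable(rule0=tables[0], rule1=tables[1],
                      first_base_map=dict(FIRST_BASE_MAP), codeword_set=cws)
    table.validate()
    return table


def _encode_group_raw(bits: str, table: CodeTable) -> str:
    rule = int(bits[0])
    base1 = FIRST_BASE_MAP[bits[1:3]]
    b2, b3 = table.rule_table(rule)[(base1, bits[3:5])]
    return base1 + b2 + b3


def encode_group(bits, table: CodeTable) -> str:
    """Encode one 5-bit group (string of '0'/'1' or length-5 bit sequence)."""
    if not isinstance(bits, str):
        bits = "".join(str(int(b)) for b in bits)
    if len(bits) != 5:
        raise ValueError(f"group must be 5 bits, got {len(bits)}")
    return _encode_group_raw(bits, table)


def detect_rule(slice3: str) -> int:
    """Return the decoding rule (0 or 1) from the slice's G/C count."""
    if len(slice3) != 3 or any(b not in BASES for b in slice3):
        raise ValueError(f"not a 3-nt ACGT slice: {slice3!r}")
    gc = sum(map(_gc, slice3))
    if gc == 1:
        return 0
    if gc == 2:
        return 1
    raise InvalidSlice(f"slice {slice3} has {gc} G/C bases; matches no rule")


# ---------------------------------------------------------------------------
# vectorized segment-level paths

def seq_to_idx(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(128, dtype=np.uint8)
    for b, i in BASE_INDEX.items():
        lut[ord(b)] = i
    return lut[arr]


_IDX_TO_CHAR = np.frombuffer(b"ACGT", dtype=np.uint8)


def idx_to_seq(idx: np.ndarray) -> str:
    return _IDX_TO_CHAR[idx].tobytes().decode("ascii")


def encode_bits(bits: np.ndarray, table: CodeTable) -> np.ndarray:
    """Encode a flat bit array (multiple of 5) to base indices, vectorized."""
    if bits.size % 5:
        raise ValueError("bit length must be a multiple of 5")
    groups = bits.reshape(-1, 5).astype(np.uint8)
    vals = groups @ np.array([16, 8, 4, 2, 1], dtype=np.uint8)
    return table._enc_lut[vals].reshape(-1)


def decode_bases(idx: np.ndarray, table: CodeTable):
    """Decode base indices (multiple of 3) to bits plus per-slice validity.

    Invalid slices (G/C count 0 or 3, or otherwise outside the codeword set)
    yield five zero bits and ``valid=False``; decoding never aborts — repair
    belongs to the error-correction layer.
    """
    if idx.size % 3:
        raise ValueError("sequence length must be a multiple of 3")
    slices = idx.reshape(-1, 3).astype(np.int64)
    keys = slices[:, 0] * 16 + slices[:, 1] * 4 + slices[:, 2]
    gvals = table._dec_lut[keys]
    valid = gvals != 255
    g = np.where(valid, gvals, 0).astype(np.uint8)
    bits = np.unpackbits(g[:, None], axis=1)[:, 3:]
    return bits.reshape(-1), valid


def encode_segment(segment, table: CodeTable) -> str:
    """Encode one 280-bit segment (or any 5-multiple bit string) to bases."""
    bits = getattr(segment, "bits", segment)
    if isinstance(bits, str):
        bits = np.frombuffer(bits.encode(), np.uint8) - ord("0")
    bits = np.asarray(bits, dtype=np.uint8)
    return idx_to_seq(encode_bits(bits, table))


def decode_segment(seq: str, table: CodeTable):
    """Decode a base string to (bit string, per-slice validity flags)."""
    if len(seq) % 3:
        raise ValueError("sequence length must be a multiple of 3; resync first")
    bits, valid = decode_bases(seq_to_idx(seq), table)
    return "".join("01"[b] for b in bits), valid.tolist()
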