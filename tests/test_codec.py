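"""Dual-rule rotary code table and 5-bit <-> 3-nt transcoding."""

import itertools

import numpy as np
import pytest

from drrc.codec import (
    CodeTable,
    InvalidSlice,
    build_code_table,
    decode_segment,
    detect_rule,
    encode_group,
    encode_segment,
    max_run_str,
)
from drrc.metrics import gc_content


def test_table_passes_all_invariants(table):
    table.validate()
    assert len(table.codeword_set) == 32


def test_table_construction_deterministic(table):
    again = build_code_table()
    assert again.rule0 == table.rule0 and again.rule1 == table.rule1


def test_table_text_roundtrip(table):
    restored = CodeTable.from_text(table.to_text())
    assert restored.rule0 == table.rule0
    assert restored.rule1 == table.rule1
    restored.validate()


@pytest.mark.parametrize(
    "group, codeword",
    [("11101", "CAC"), ("00100", "TCA"), ("00010", "ATC"), ("11110", "CTG")],
)
def test_pinned_worked_example_entries(table, group, codeword):
    assert encode_group(group, table) == codeword


def test_first_base_forced_by_bits23(table):
    want = {"00": "A", "01": "T", "11": "C", "10": "G"}
    for g in range(32):
        bits = format(g, "05b")
        assert encode_group(bits, table)[0] == want[bits[1:3]]


def test_rule_gc_classes(table):
    for g in range(32):
        bits = format(g, "05b")
        cw = encode_group(bits, table)
        gc = sum(c in "GC" for c in cw)
        assert gc == (1 if bits[0] == "0" else 2)


def test_exhaustive_group_roundtrip(table):
    seen = set()
    for g in range(32):
        bits = format(g, "05b")
        cw = encode_group(bits, table)
        seen.add(cw)
        decoded, valid = decode_segment(cw, table)
        assert valid == [True]
        assert decoded == bits
    assert len(seen) == 32


@pytest.mark.parametrize(
    "slice3, rule", [("CAC", 1), ("TCA", 0), ("ATC", 0), ("CTG", 1), ("AGC", 1)]
)
def test_detect_rule(slice3, rule):
    assert detect_rule(slice3) == rule


@pytest.mark.parametrize("slice3", ["AAA", "GCG", "TTT", "CGC"])
def test_detect_rule_invalid_slices(slice3):
    with pytest.raises(InvalidSlice):
        detect_rule(slice3)


def test_worked_example_segment(table):
    seq = encode_segment("11101001000001011110", table)
    assert seq == "CACTCAATCCTG"
    assert gc_content(seq) == 0.5
    assert max_run_str(seq) == 2


def test_segment_roundtrip_random(table, rng):
    for _ in range(300):
        bits = rng.integers(0, 2, 280).astype(np.uint8)
        seq = encode_segment(bits, table)
        assert len(seq) == 168
        decoded, valid = decode_segment(seq, table)
        assert all(valid)
        assert decoded == "".join("01"[b] for b in bits)


def test_payload_gc_closed_form(table, rng):
    """Per-segment GC equals (56 + k)/168 with k ones among leading bits."""
    for _ in range(50):
        bits = rng.integers(0, 2, 280).astype(np.uint8)
        k = int(bits.reshape(56, 5)[:, 0].sum())
        seq = encode_segment(bits, table)
        assert gc_content(seq) == pytest.approx((56 + k) / 168)


def test_substitution_locality_brute_force(table, rng):
    """A single substituted base never corrupts bits outside its own group."""
    bits = rng.integers(0, 2, 280).astype(np.uint8)
    seq = encode_segment(bits, table)
    original = "".join("01"[b] for b in bits)
    for pos in range(168):
        for alt in "ACGT":
            if alt == seq[pos]:
                continue
            mutated = seq[:pos] + alt + seq[pos + 1:]
            decoded, _ = decode_segment(mutated, table)
            differing = {
                g for g in range(56)
                if decoded[5 * g:5 * g + 5] != original[5 * g:5 * g + 5]
            }
            assert differing <= {pos // 3}


def test_homopolymer_bound_over_corpus(table, rng):
    """Runs never exceed 3, including across slice and oligo-internal
    boundaries, and the corpus exercises all 32 codewords."""
    seen = set()
    worst = 0
    for _ in range(200):
        bits = rng.integers(0, 2, 280).astype(np.uint8)
        seq = encode_segment(bits, table)
        seen.update(seq[i:i + 3] for i in range(0, 168, 3))
        worst = max(worst, max_run_str(seq))
    assert worst <= 3
    assert seen == set(table.codeword_set)


def test_invalid_slice_flagged_not_fatal(table):
    seq = "AAA" + encode_segment("11101", table)
    decoded, valid = decode_segment(seq, table)
    assert valid == [False, True]
    assert decoded == "00000" + "11101"


def test_decode_rejects_partial_slices(table):
    with pytest.raises(ValueError):
        decode_segment("ACGTA", table)


def test_adjacent_codeword_runs(table):
    for a, b in itertools.product(sorted(table.codeword_set), repeat=2):
        assert max_run_str(a + b) <= 3
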