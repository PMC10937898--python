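"""Two-level error correction: indel resynchronization and Reed-Solomon."""

import numpy as np
import pytest

from drrc.codec import decode_segment, encode_segment
from drrc.ecc import (
    CORE_NT,
    MESSAGE_NT,
    RSConfig,
    resync_indels,
    rs_decode,
    rs_encode,
    rs_encode_many,
    slice_hamming_profile,
    syndromes_many,
)


def random_nt(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


@pytest.fixture()
def core(rng):
    msg = random_nt(rng, MESSAGE_NT)
    return msg + rs_encode(msg)


# ---------------------------------------------------------------- RS layer

def test_rs_parity_shape_and_determinism(rng):
    msg = random_nt(rng, MESSAGE_NT)
    p1, p2 = rs_encode(msg), rs_encode(msg)
    assert p1 == p2
    assert len(p1) == 24
    assert set(p1) <= set("ACGT")


def test_rs_rejects_wrong_length():
    with pytest.raises(ValueError):
        rs_encode("ACGT")
    with pytest.raises(ValueError):
        rs_decode("ACGT")


def test_rs_clean_roundtrip(core):
    msg, ok = rs_decode(core)
    assert ok and msg == core[:MESSAGE_NT]


@pytest.mark.parametrize("n_errors", [1, 2, 3])
def test_rs_corrects_within_capacity(core, rng, n_errors):
    """Up to t=3 substituted bases (in distinct or shared symbols) are fixed."""
    for _ in range(30):
        s = list(core)
        for p in rng.choice(CORE_NT, size=n_errors, replace=False):
            s[p] = "ACGT"[("ACGT".index(s[p]) + int(rng.integers(1, 4))) % 4]
        msg, ok = rs_decode("".join(s))
        assert ok
        assert msg == core[:MESSAGE_NT]


def test_rs_flags_beyond_capacity(core, rng):
    """Five errors in five distinct symbols must be reported, not silently
    miscorrected into the wrong message."""
    for _ in range(30):
        s = list(core)
        for sym in rng.choice(CORE_NT // 4, size=5, replace=False):
            p = int(sym) * 4
            s[p] = "ACGT"[("ACGT".index(s[p]) + 1) % 4]
        msg, ok = rs_decode("".join(s))
        assert not ok or msg == core[:MESSAGE_NT]


def test_rs_encode_many_matches_scalar(rng):
    from drrc.codec import idx_to_seq, seq_to_idx
    msgs = [random_nt(rng, MESSAGE_NT) for _ in range(8)]
    batch = rs_encode_many(np.stack([seq_to_idx(m) for m in msgs]))
    for m, row in zip(msgs, batch):
        assert idx_to_seq(row) == rs_encode(m)


def test_syndromes_zero_iff_clean(core, rng):
    from drrc.codec import seq_to_idx
    s = list(core)
    s[100] = "ACGT"[("ACGT".index(s[100]) + 1) % 4]
    mat = np.stack([seq_to_idx(core), seq_to_idx("".join(s))])
    syn = syndromes_many(mat)
    assert not syn[0].any()
    assert syn[1].any()


def test_rs_config_capacity():
    assert RSConfig().t == 3
    assert RSConfig().parity_nt == 24


# ------------------------------------------------------- resynchronization

def test_profile_clean_sequence_all_zero(table, rng):
    seq = encode_segment(rng.integers(0, 2, 280).astype(np.uint8), table)
    assert all(d.min_hamming == 0 for d in slice_hamming_profile(seq, table))


def test_profile_flags_non_codeword_slices(table):
    diags = slice_hamming_profile("AAA" * 4, table)
    assert all(d.min_hamming >= 1 for d in diags)


def test_profile_reports_trailing_partial(table, rng):
    seq = encode_segment(rng.integers(0, 2, 280).astype(np.uint8), table)
    diags = slice_hamming_profile(seq + "AC", table)
    assert diags[-1].min_hamming == 1
    assert diags[-1].slice_index == 56


def test_resync_identity_on_clean_input(table, rng):
    seq = encode_segment(rng.integers(0, 2, 280).astype(np.uint8), table)
    assert resync_indels(seq, 168, table) == seq


def test_resync_single_deletion_exhaustive(table, rng):
    """After frame repair, corruption is a contiguous block starting no
    earlier than the deleted slice; everything downstream realigns."""
    bits = rng.integers(0, 2, 280).astype(np.uint8)
    seq = encode_segment(bits, table)
    original, _ = decode_segment(seq, table)
    for pos in range(168):
        repaired = resync_indels(seq[:pos] + seq[pos + 1:], 168, table)
        assert len(repaired) == 168
        decoded, _ = decode_segment(repaired, table)
        diffs = [g for g in range(56)
                 if decoded[5 * g:5 * g + 5] != original[5 * g:5 * g + 5]]
        if diffs:
            assert diffs == list(range(diffs[0], diffs[-1] + 1))
            assert diffs[0] >= pos // 3


def test_resync_single_insertion_exhaustive(table, rng):
    bits = rng.integers(0, 2, 280).astype(np.uint8)
    seq = encode_segment(bits, table)
    original, _ = decode_segment(seq, table)
    for pos in range(0, 169, 3):
        for base in "ACGT":
            repaired = resync_indels(seq[:pos] + base + seq[pos:], 168, table)
            assert len(repaired) == 168
            decoded, _ = decode_segment(repaired, table)
            diffs = [g for g in range(56)
                     if decoded[5 * g:5 * g + 5] != original[5 * g:5 * g + 5]]
            assert not diffs or diffs[0] >= pos // 3 - 1


def test_resync_beats_naive_end_padding(table, rng):
    """Paired over deletion positions, frame repair never recovers fewer
    groups than naively padding the truncated read at its end."""
    bits = rng.integers(0, 2, 280).astype(np.uint8)
    seq = encode_segment(bits, table)
    original, _ = decode_segment(seq, table)

    def n_correct(decoded):
        return sum(decoded[5 * g:5 * g + 5] == original[5 * g:5 * g + 5]
                   for g in range(56))

    for pos in range(0, 168, 5):
        broken = seq[:pos] + seq[pos + 1:]
        with_resync, _ = decode_segment(resync_indels(broken, 168, table), table)
        naive, _ = decode_segment(broken + "A", table)
        assert n_correct(with_resync) >= n_correct(naive)


def test_resync_handles_multiple_deletions(table, rng):
    bits = rng.integers(0, 2, 280).astype(np.uint8)
    seq = encode_segment(bits, table)
    broken = seq[:30] + seq[31:100] + seq[101:]
    assert len(resync_indels(broken, 168, table)) == 168


def test_resync_length_contract(table, rng):
    seq = encode_segment(rng.integers(0, 2, 280).astype(np.uint8), table)
    for delta in (-3, -1, 0, 1, 3):
        if delta < 0:
            broken = seq[:-delta * 7] + seq[-delta * 7 - delta:]
            broken = seq[:50] + seq[50 - delta:]
        elif delta > 0:
            broken = seq[:50] + "G" * delta + seq[50:]
        else:
            broken = seq
        assert len(resync_indels(broken, 168, table)) == 168
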