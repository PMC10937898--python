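"""Two-level error correction for 207-nt oligo cores.

Level 1 (resynchronization) restores the 3-nt reading frame after insertions
or deletions: the code table covers only 32 of the 64 possible 3-nt slices,
so a frame shift almost surely produces a downstream slice at nonzero Hamming
distance from the codeword set.  The first such slice is taken as the error
site; an insertion is repaired by deleting the slice's first base, a deletion
by inserting a filler base at its first position.  The repair sacrifices that
slice's content but stops the indel from corrupting everything after it.

Level 2 is a shortened systematic Reed–Solomon code over GF(2^8)
(primitive polynomial x^8+x^4+x^3+x^2+1): the 183-nt index+payload region is
packed 4 nt per 8-bit symbol (2 bits per base, A=00 C=01 G=10 T=11,
MSB-first) into 46 symbols, and 6 parity symbols — exactly 24 nt — give a
correction capacity of t = 3 symbol errors per oligo.  Because symbols are
4-nt aligned, a single base substitution costs one symbol, so up to three
scattered substitutions (or the residue of a resynchronized indel) are
repaired per oligo.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codec import BASE_INDEX, CodeTable, idx_to_seq, seq_to_idx

PARITY_NT = 24
MESSAGE_NT = 183
CORE_NT = 207
N_PARITY_SYMBOLS = 6          # 24 nt * 2 bit / 8 bit
N_MESSAGE_SYMBOLS = 46        # ceil(183 * 2 / 8)
FILLER_BASE = "A"

__all__ = [
    "RSConfig",
    "SliceDiagnostics",
    "slice_hamming_profile",
    "resync_indels",
    "rs_encode",
    "rs_decode",
    "rs_encode_many",
    "syndromes_many",
    "nt_to_symbols",
    "symbols_to_nt",
]

# ---------------------------------------------------------------------------
# GF(2^8) arithmetic, table-driven

_PRIM = 0x11D
GF_EXP = np.zeros(512, dtype=np.uint8)
GF_LOG = np.zeros(256, dtype=np.int32)
_x = 1
for _i in range(255):
    GF_EXP[_i] = _x
    GF_LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= _PRIM
GF_EXP[255:510] = GF_EXP[:255]


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(GF_EXP[GF_LOG[a] + GF_LOG[b]])


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError
    if a == 0:
        return 0
    return int(GF_EXP[(GF_LOG[a] - GF_LOG[b]) % 255])


def gf_poly_mul(p, q):
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            out[i + j] ^= gf_mul(a, b)
    return out


def gf_poly_eval(poly, x: int) -> int:
    y = poly[0]
    for c in poly[1:]:
        y = gf_mul(y, x) ^ c
    return y


def _generator_poly(nsym: int):
    g = [1]
    for i in range(nsym):
        g = gf_poly_mul(g, [1, int(GF_EXP[i])])
    return g


_GEN = _generator_poly(N_PARITY_SYMBOLS)


@dataclass(frozen=True)
class RSConfig:
    """Reed–Solomon layer parameters (frozen defaults fit the 24-nt budget)."""

    parity_nt: int = PARITY_NT
    message_nt: int = MESSAGE_NT
    nsym: int = N_PARITY_SYMBOLS
    bases_per_symbol: int = 4

    @property
    def t(self) -> int:
        """Symbol-error correction capacity."""
        return self.nsym // 2

    def to_dict(self) -> dict:
        return {"parity_nt": self.parity_nt, "message_nt": self.message_nt,
                "nsym": self.nsym, "bases_per_symbol": self.bases_per_symbol}


# ---------------------------------------------------------------------------
# nucleotide <-> symbol packing

def nt_to_symbols(idx: np.ndarray) -> np.ndarray:
    """Pack base indices (2 bits each, MSB-first) into uint8 symbols."""
    bits = np.unpackbits(idx.astype(np.uint8)[:, None], axis=1)[:, 6:].reshape(-1)
    pad = (-bits.size) % 8
    if pad:
        bits = np.concatenate([bits, np.zeros(pad, dtype=np.uint8)])
    return np.packbits(bits)


def symbols_to_nt(symbols: np.ndarray, n_nt: int) -> np.ndarray:
    bits = np.unpackbits(np.asarray(symbols, dtype=np.uint8))[: 2 * n_nt]
    return (bits[0::2] << 1 | bits[1::2]).astype(np.uint8)


# ---------------------------------------------------------------------------
# RS encode / decode

def _rs_encode_symbols(msg: np.ndarray, nsym: int = N_PARITY_SYMBOLS) -> np.ndarray:
    gen = _GEN if nsym == N_PARITY_SYMBOLS else _generator_poly(nsym)
    rem = [0] * nsym
    for m in msg:
        coef = int(m) ^ rem[0]
        rem = rem[1:] + [0]
        if coef:
            lc = GF_LOG[coef]
            for i in range(nsym):
                g = gen[i + 1]
                if g:
                    rem[i] ^= int(GF_EXP[lc + GF_LOG[g]])
    return np.array(rem, dtype=np.uint8)


def rs_encode(message_nt: str, config: RSConfig = RSConfig()) -> str:
    """Compute the 24-nt parity field for a 183-nt index+payload message."""
    if len(message_nt) != config.message_nt:
        raise ValueError(f"message must be {config.message_nt} nt")
    msg = nt_to_symbols(seq_to_idx(message_nt))
    parity = _rs_encode_symbols(msg, config.nsym)
    return idx_to_seq(symbols_to_nt(parity, config.parity_nt))


def rs_encode_many(msg_idx: np.ndarray, config: RSConfig = RSConfig()) -> np.ndarray:
    """Vectorized parity for many messages: (N, 183) base indices -> (N, 24)."""
    n = msg_idx.shape[0]
    # pack each row of 183 bases into 46 symbols
    b2 = np.unpackbits(msg_idx.astype(np.uint8).reshape(n, -1, 1), axis=2)[:, :, 6:]
    b2 = b2.reshape(n, -1)
    pad = (-b2.shape[1]) % 8
    if pad:
        b2 = np.concatenate([b2, np.zeros((n, pad), dtype=np.uint8)], axis=1)
    msgs = np.packbits(b2, axis=1).astype(np.int64)
    gen_log = np.array([GF_LOG[g] if g else -1 for g in _GEN[1:]], dtype=np.int64)
    rem = np.zeros((n, config.nsym), dtype=np.int64)
    for j in range(msgs.shape[1]):
        coef = msgs[:, j] ^ rem[:, 0]
        rem = np.concatenate([rem[:, 1:], np.zeros((n, 1), dtype=np.int64)], axis=1)
        nz = coef != 0
        if nz.any():
            lc = GF_LOG[coef[nz]]
            upd = np.zeros((nz.sum(), config.nsym), dtype=np.int64)
            for i in range(config.nsym):
                if gen_log[i] >= 0:
                    upd[:, i] = GF_EXP[lc + gen_log[i]]
            rem[nz] ^= upd
    parity_sym = rem.astype(np.uint8)
    bits = np.unpackbits(parity_sym, axis=1)[:, : 2 * config.parity_nt]
    return (bits[:, 0::2] << 1 | bits[:, 1::2]).astype(np.uint8)


def syndromes_many(core_idx: np.ndarray, config: RSConfig = RSConfig()) -> np.ndarray:
    """Vectorized RS syndromes for (N, 207) base-index cores.

    Returns an (N, nsym) array; an all-zero row means the codeword is clean.
    """
    n = core_idx.shape[0]
    b2 = np.unpackbits(core_idx.astype(np.uint8).reshape(n, -1, 1), axis=2)[:, :, 6:]
    b2 = b2.reshape(n, -1)
    msg_bits = b2[:, : 2 * config.message_nt]
    pad = (-msg_bits.shape[1]) % 8
    msg_bits = np.concatenate(
        [msg_bits, np.zeros((n, pad), dtype=np.uint8)], axis=1)
    par_bits = b2[:, 2 * config.message_nt:]
    cw = np.concatenate(
        [np.packbits(msg_bits, axis=1), np.packbits(par_bits, axis=1)], axis=1
    ).astype(np.int64)
    nsyn = config.nsym
    syn = np.zeros((n, nsyn), dtype=np.int64)
    log_cw = np.where(cw > 0, GF_LOG[cw], 0)
    for j in range(nsyn):
        # Horner evaluation at alpha^j across all rows
        acc = np.zeros(n, dtype=np.int64)
        for k in range(cw.shape[1]):
            nz = acc != 0
            acc[nz] = GF_EXP[(GF_LOG[acc[nz]] + j) % 255]
            acc ^= cw[:, k]
        syn[:, j] = acc
    return syn


def _gf_solve(A, b):
    """Gaussian elimination over GF(2^8); returns x with A x = b, or None."""
    k = len(b)
    M = [row[:] + [bv] for row, bv in zip(A, b)]
    for col in range(k):
        piv = next((r for r in range(col, k) if M[r][col]), None)
        if piv is None:
            return None
        M[col], M[piv] = M[piv], M[col]
        inv = gf_div(1, M[col][col])
        M[col] = [gf_mul(inv, v) for v in M[col]]
        for r in range(k):
            if r != col and M[r][col]:
                f = M[r][col]
                M[r] = [v ^ gf_mul(f, w) for v, w in zip(M[r], M[col])]
    return [M[r][k] for r in range(k)]


def _rs_correct_symbols(cw: list, nsym: int):
    """Berlekamp–Massey + Chien search + direct magnitude solve.

    Returns (corrected codeword, ok).  ``ok`` is False when the error count
    exceeds capacity or the locator is inconsistent; the input is returned
    untouched in that case.
    """
    syn = [gf_poly_eval(cw, int(GF_EXP[i])) for i in range(nsym)]
    if max(syn) == 0:
        return list(cw), True
    # Berlekamp–Massey for the error locator polynomial
    err_loc = [1]
    old_loc = [1]
    for i in range(nsym):
        delta = syn[i]
        for j in range(1, len(err_loc)):
            delta ^= gf_mul(err_loc[-(j + 1)], syn[i - j])
        old_loc = old_loc + [0]
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = [gf_mul(delta, x) for x in old_loc]
                old_loc = [gf_div(x, delta) for x in err_loc]
                err_loc = new_loc
            width = max(len(err_loc), len(old_loc))
            e = [0] * (width - len(err_loc)) + err_loc
            o = [0] * (width - len(old_loc)) + old_loc
            err_loc = [a ^ gf_mul(delta, b) for a, b in zip(e, o)]
    while err_loc and err_loc[0] == 0:
        err_loc = err_loc[1:]
    n_err = len(err_loc) - 1
    if n_err * 2 > nsym:
        return list(cw), False
    # Chien search restricted to the shortened codeword's positions
    n = len(cw)
    pows = []      # exponent of alpha for each error location X_e
    positions = []
    for p in range(n):
        pe = n - 1 - p
        x_inv = int(GF_EXP[(255 - pe) % 255])
        if gf_poly_eval(err_loc, x_inv) == 0:
            positions.append(p)
            pows.append(pe)
    if len(positions) != n_err:
        return list(cw), False
    # magnitudes from S_j = sum_e Y_e X_e^j, j = 0..n_err-1
    A = [[int(GF_EXP[(pe * j) % 255]) for pe in pows] for j in range(n_err)]
    mags = _gf_solve(A, syn[:n_err])
    if mags is None:
        return list(cw), False
    fixed = list(cw)
    for p, y in zip(positions, mags):
        fixed[p] ^= y
    if any(gf_poly_eval(fixed, int(GF_EXP[i])) for i in range(nsym)):
        return list(cw), False
    return fixed, True


def rs_decode(oligo_core_nt: str, config: RSConfig = RSConfig()):
    """Correct a 207-nt core; return ``(183-nt message, success flag)``.

    On failure the uncorrected message region is returned with
    ``success=False`` so best-effort decoding can proceed.
    """
    if len(oligo_core_nt) != config.message_nt + config.parity_nt:
        raise ValueError(
            f"core must be {config.message_nt + config.parity_nt} nt, "
            f"got {len(oligo_core_nt)}"
        )
    idx = seq_to_idx(oligo_core_nt)
    msg_sym = nt_to_symbols(idx[: config.message_nt])
    par_sym = nt_to_symbols(idx[config.message_nt:])
    cw = list(np.concatenate([msg_sym, par_sym]).astype(int))
    corrected, ok = _rs_correct_symbols(cw, config.nsym)
    msg_nt = idx_to_seq(
        symbols_to_nt(np.array(corrected[: N_MESSAGE_SYMBOLS], dtype=np.uint8),
                      config.message_nt))
    return msg_nt, ok


# ---------------------------------------------------------------------------
# level 1: Hamming-distance resynchronization

@dataclass(frozen=True)
class SliceDiagnostics:
    slice_index: int
    min_hamming: int


def _slice_distances(idx: np.ndarray, table: CodeTable) -> np.ndarray:
    n_full = idx.size // 3
    sl = idx[: 3 * n_full].reshape(-1, 3).astype(np.int64)
    keys = sl[:, 0] * 16 + sl[:, 1] * 4 + sl[:, 2]
    return table._dist_lut[keys]


def slice_hamming_profile(seq: str, table: CodeTable):
    """Minimum Hamming distance of every complete 3-nt slice to the codeword set.

    A trailing fragment shorter than 3 nt is reported as an extra diagnostic
    with ``min_hamming = 1`` (it can never be a codeword).
    """
    if len(seq) < 3:
        raise ValueError("sequence must be at least one slice long")
    idx = seq_to_idx(seq)
    dists = _slice_distances(idx, table)
    out = [SliceDiagnostics(i, int(d)) for i, d in enumerate(dists)]
    if len(seq) % 3:
        out.append(SliceDiagnostics(len(dists), 1))
    return out


def resync_indels(seq: str, expected_len: int, table: CodeTable,
                  filler: str = FILLER_BASE) -> str:
    """Restore the reading frame of a length-perturbed sequence.

    The sign of ``len(seq) - expected_len`` classifies the error (insertion
    vs deletion); slices are scanned left to right, and at the first slice at
    nonzero Hamming distance from the codeword set the single-base edit is
    applied (delete the slice's first base / insert ``filler`` at its first
    position).  The repaired slice is skipped and the scan continues, once
    per unit of length discrepancy.  Output length always equals
    ``expected_len``; residual slice corruption is left for the RS layer.
    """
    delta = len(seq) - expected_len
    if delta == 0:
        return seq
    s = list(seq)
    pos = 0
    while delta != 0:
        found = None
        i = pos
        while i + 3 <= len(s):
            d = table._dist_lut[
                BASE_INDEX[s[i]] * 16 + BASE_INDEX[s[i + 1]] * 4 + BASE_INDEX[s[i + 2]]
            ]
            if d > 0:
                found = i
                break
            i += 3
        if found is None:
            found = i  # trailing partial slice (or clean end): edit there
        if delta > 0:
            if found >= len(s):
                found = len(s) - 1
            del s[found]
            delta -= 1
        else:
            s.insert(found, filler)
            delta += 1
        pos = found + 3
    return "".join(s)
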