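"""End-to-end encode/decode pipelines.

Encoding: segment the byte stream into 280-bit units, balance the global
group-leading-bit stream with the chaotic keystream, transcode each segment
through the dual-rule table to a 168-nt payload, prepend a 15-nt index,
append 24 nt of RS parity and the primers, and emit a FASTA pool plus a JSON
sidecar holding everything decoding needs (chaotic parameters, padding, RS
and table versions).

Decoding inverts the pipeline and is tolerant by construction: reads may
arrive shuffled, length-perturbed or corrupted; each is primer-stripped,
resynchronized to 207 nt, RS-corrected, and slice-decoded, and missing
segments are zero-filled and reported rather than fatal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import chaos, ecc, oligo
from .bitstream import SEGMENT_BITS, segment_message
from .chaos import ChaoticParams, DEFAULT_BAND
from .codec import CodeTable, build_code_table, decode_bases, idx_to_seq, seq_to_idx
from .ecc import RSConfig
from .oligo import CORE_NT, INDEX_NT, OligoRecord, PAYLOAD_NT

SIDECAR_FORMAT = "drrc-sidecar-1"
DEFAULT_X0 = 0.37

__all__ = [
    "EncodeResult",
    "DecodeResult",
    "encode_bytes",
    "decode_pool",
    "encode_file",
    "decode_file",
    "make_sidecar",
]


@dataclass
class EncodeResult:
    oligos: list
    sidecar: dict
    segment_bits: np.ndarray  # (n_segments, 280), randomized domain
    params: ChaoticParams


@dataclass
class DecodeResult:
    data: bytes
    report: dict
    segment_bits: dict = field(repr=False)  # index -> (280,) randomized-domain bits


def make_sidecar(params: ChaoticParams, padding, rs_config: RSConfig,
                 table: CodeTable, n_oligos: int, file_size: int,
                 primers=(oligo.PRIMER5, oligo.PRIMER3)) -> dict:
    return {
        "format": SIDECAR_FORMAT,
        "table_version": table.version,
        "chaotic_params": params.to_dict(),
        "padding": {
            "original_bit_length": padding.original_bit_length,
            "pad_bits": padding.pad_bits,
        },
        "rs_config": rs_config.to_dict(),
        "n_oligos": n_oligos,
        "file_size_bytes": file_size,
        "primers": list(primers),
    }


def encode_bytes(data: bytes, x0: float = DEFAULT_X0, band=DEFAULT_BAND,
                 mu: float = chaos.MU_DEFAULT, table: CodeTable = None,
                 rs_config: RSConfig = RSConfig(),
                 max_iter: int = chaos.MAX_ITER_DEFAULT) -> EncodeResult:
    """Encode a byte string into an oligo pool (vectorized)."""
    if table is None:
        table = build_code_table()
    segments, padding = segment_message(data)
    n = len(segments)
    bits = np.stack([s.bits for s in segments]).reshape(n, 56, 5)
    first = bits[:, :, 0].reshape(-1)
    balanced, params = chaos.balance_first_bits(first, x0, band, max_iter, mu)
    bits[:, :, 0] = balanced.reshape(n, 56)
    flat = bits.reshape(n, SEGMENT_BITS)

    from .codec import encode_bits
    payload_idx = encode_bits(flat.reshape(-1), table).reshape(n, PAYLOAD_NT)
    index_idx = np.stack([seq_to_idx(oligo.encode_index(k, table)) for k in range(n)])
    msg_idx = np.concatenate([index_idx, payload_idx], axis=1)
    parity_idx = ecc.rs_encode_many(msg_idx, rs_config)

    oligos = []
    for k in range(n):
        oligos.append(OligoRecord(
            index_value=k,
            index_nt=idx_to_seq(index_idx[k]),
            payload_nt=idx_to_seq(payload_idx[k]),
            parity_nt=idx_to_seq(parity_idx[k]),
        ))
    sidecar = make_sidecar(params, padding, rs_config, table, n, len(data))
    return EncodeResult(oligos=oligos, sidecar=sidecar,
                        segment_bits=flat, params=params)


def decode_pool(seqs, sidecar: dict, table: CodeTable = None,
                correction: str = "resync+rs") -> DecodeResult:
    """Decode raw oligo reads back to the original byte string.

    ``correction`` is one of ``"none"`` (length-perturbed reads dropped, no
    RS), ``"resync"`` (frame repair only) or ``"resync+rs"`` (both levels).
    """
    if table is None:
        table = build_code_table()
    if sidecar.get("table_version") != table.version:
        raise ValueError("sidecar/table version mismatch")
    if correction not in ("none", "resync", "resync+rs"):
        raise ValueError(f"unknown correction level {correction!r}")
    use_resync = correction != "none"
    use_rs = correction == "resync+rs"
    rs_config = RSConfig(**sidecar["rs_config"])
    primer5, primer3 = sidecar.get("primers", [oligo.PRIMER5, oligo.PRIMER3])

    report = {
        "n_reads": len(seqs), "n_bad_chars": 0, "n_length_dropped": 0,
        "n_resynced": 0, "n_rs_failed": 0, "n_index_invalid": 0,
        "n_duplicates": 0, "correction": correction,
    }
    cores = []
    for s in seqs:
        if any(c not in "ACGT" for c in s):
            report["n_bad_chars"] += 1
            continue
        core = oligo.strip_primers(s, primer5, primer3)
        if len(core) != CORE_NT:
            if not use_resync:
                report["n_length_dropped"] += 1
                continue
            core = ecc.resync_indels(core, CORE_NT, table)
            report["n_resynced"] += 1
        cores.append(core)

    seg_bits = {}
    rs_ok_map = {}
    if cores:
        mat = np.stack([seq_to_idx(c) for c in cores])
        if use_rs:
            syn = ecc.syndromes_many(mat, rs_config)
            dirty = np.nonzero(syn.any(axis=1))[0]
            for r in dirty:
                msg_nt, ok = ecc.rs_decode(idx_to_seq(mat[r]), rs_config)
                if ok:
                    mat[r, :rs_config.message_nt] = seq_to_idx(msg_nt)
                else:
                    report["n_rs_failed"] += 1
                rs_ok_map[r] = ok
        bits, valid = decode_bases(mat.reshape(-1), table)
        bits = bits.reshape(len(cores), -1)
        valid = valid.reshape(len(cores), -1)
        n_groups_core = CORE_NT // 3
        for r in range(len(cores)):
            row = bits[r]
            groups = row.reshape(n_groups_core, 5)
            idx_valid = valid[r, :5].all()
            k = None
            if idx_valid:
                lead = tuple(groups[:5, 0])
                if lead == oligo.INDEX_LEAD_PATTERN:
                    k = 0
                    for b in groups[:5, 1:].reshape(-1):
                        k = (k << 1) | int(b)
            if k is None or k >= sidecar["n_oligos"]:
                report["n_index_invalid"] += 1
                continue
            payload_bits = groups[5:61].reshape(-1)
            if k in seg_bits:
                report["n_duplicates"] += 1
                # prefer a copy that passed RS over one that failed
                if rs_ok_map.get(r, True) and not seg_bits[k][1]:
                    seg_bits[k] = (payload_bits, rs_ok_map.get(r, True))
            else:
                seg_bits[k] = (payload_bits, rs_ok_map.get(r, True))

    n_total = sidecar["n_oligos"]
    full = np.zeros((n_total, SEGMENT_BITS), dtype=np.uint8)
    missing = []
    for k in range(n_total):
        if k in seg_bits:
            full[k] = seg_bits[k][0]
        else:
            missing.append(k)
    report["n_missing_segments"] = len(missing)

    params = ChaoticParams.from_dict(sidecar["chaotic_params"])
    grouped = full.reshape(n_total, 56, 5)
    first = grouped[:, :, 0].reshape(-1)
    grouped[:, :, 0] = chaos.derandomize_first_bits(first, params).reshape(n_total, 56)
    all_bits = grouped.reshape(-1)[: sidecar["padding"]["original_bit_length"]]
    data = np.packbits(all_bits).tobytes()[: sidecar["file_size_bytes"]]
    return DecodeResult(data=data, report=report,
                        segment_bits={k: v[0] for k, v in seg_bits.items()})


# ---------------------------------------------------------------------------
# file-level convenience wrappers

def encode_file(in_path, fasta_path, sidecar_path, **kwargs) -> EncodeResult:
    with open(in_path, "rb") as fh:
        data = fh.read()
    result = encode_bytes(data, **kwargs)
    oligo.write_fasta(result.oligos, fasta_path)
    with open(sidecar_path, "w") as fh:
        json.dump(result.sidecar, fh, indent=1)
    return result


def decode_file(fasta_path, sidecar_path, out_path=None,
                correction: str = "resync+rs") -> DecodeResult:
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    if sidecar.get("format") != SIDECAR_FORMAT:
        raise ValueError("unrecognized sidecar format")
    seqs, _flags = oligo.read_fasta(fasta_path)
    result = decode_pool(seqs, sidecar, correction=correction)
    if out_path is not None:
        with open(out_path, "wb") as fh:
            fh.write(result.data)
    return result
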