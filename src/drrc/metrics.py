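"""Constraint and density metrics for encoded oligo pools.

Densities are reported two ways: *coding potential* counts only the
information-carrying nucleotides (payload) plus the fixed ~200-nt overhead of
the separately stored chaotic-parameter record, while *net information
density* charges the index and RS parity too (280 payload bits over the
207-nt core).  Display values truncate — rather than round — to the printed
number of decimals; truncation is the convention under which the reference
figures 1.66 bit/nt (coding potential) and 1.352 bit/nt (net density) are
self-consistent with the exact ratios.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

#: Nucleotide cost of storing the chaotic parameters as their own oligo
#: (error-corrected and indexed), used as a constant overhead term.
PARAM_OVERHEAD_NT = 200

__all__ = [
    "PARAM_OVERHEAD_NT",
    "PoolMetrics",
    "gc_content",
    "max_run",
    "coding_potential",
    "net_density",
    "pool_profile",
    "truncate",
]


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` places (display convention)."""
    f = 10 ** decimals
    return math.trunc(value * f) / f


def gc_content(seq: str) -> float:
    """Fraction of G and C bases in a non-empty ACGT sequence."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    if any(c not in "ACGT" for c in seq):
        raise ValueError("sequence must contain only A, C, G, T")
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_run(seq: str) -> int:
    """Length of the longest homopolymer (block of identical bases)."""
    if not seq:
        raise ValueError("sequence must be non-empty")
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        if run > best:
            best = run
    return best


def coding_potential(l_bin_bits: int, n_oligos: int, payload_nt_per_oligo: int,
                     param_overhead_nt: int = PARAM_OVERHEAD_NT) -> float:
    """Information bits per information-carrying nucleotide.

    ``l_bin_bits / (n_oligos * payload_nt + overhead)`` — the overhead term
    is the fixed nucleotide cost of the parameter-storage oligo.
    """
    denom = n_oligos * payload_nt_per_oligo + param_overhead_nt
    if denom <= 0:
        raise ValueError("denominator must be positive")
    return l_bin_bits / denom


def net_density(payload_bits_per_oligo: int, core_nt_per_oligo: int) -> float:
    """Payload bits per core nucleotide (index and parity included)."""
    if core_nt_per_oligo <= 0:
        raise ValueError("core length must be positive")
    return payload_bits_per_oligo / core_nt_per_oligo


@dataclass
class PoolMetrics:
    gc_histogram: dict
    max_run_histogram: dict
    mean_gc: float
    overall_max_run: int
    n_oligos: int


def _max_runs_matrix(arr: np.ndarray) -> np.ndarray:
    """Per-row longest run for an (N, L) array of base indices."""
    n, L = arr.shape
    best = np.ones(n, dtype=np.int64)
    run = np.ones(n, dtype=np.int64)
    for j in range(1, L):
        same = arr[:, j] == arr[:, j - 1]
        run = np.where(same, run + 1, 1)
        best = np.maximum(best, run)
    return best


def pool_profile(payloads, gc_bins: int = 101) -> PoolMetrics:
    """Per-oligo GC and max-run distributions over a pool of payloads.

    ``payloads`` is an iterable of equal-length ACGT strings (by default the
    168-nt payload region; pass cores for full-core statistics).
    """
    payloads = list(payloads)
    if not payloads:
        raise ValueError("pool must be non-empty")
    from .codec import seq_to_idx
    arr = np.stack([seq_to_idx(p) for p in payloads])
    gc = ((arr == 1) | (arr == 2)).mean(axis=1)
    runs = _max_runs_matrix(arr)
    gc_hist = Counter(np.round(gc, 4).tolist())
    run_hist = Counter(runs.tolist())
    return PoolMetrics(
        gc_histogram=dict(sorted(gc_hist.items())),
        max_run_histogram=dict(sorted(run_hist.items())),
        mean_gc=float(gc.mean()),
        overall_max_run=int(runs.max()),
        n_oligos=len(payloads),
    )
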