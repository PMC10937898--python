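"""Logistic-map keystream generation and first-bit balancing.

The leading bit of each 5-bit group decides which coding rule (and hence
which GC class) its codeword falls in, so the pooled GC content of an encoded
file equals ``(56 + k) / 168`` per oligo, ``k`` being that segment's count of
1-valued leading bits.  To pin GC near 50% the concatenated leading-bit
stream is XORed with successive blocks of a binarized logistic-map orbit
(``x -> mu * x * (1 - x)``, chaotic at ``mu = 3.9``) until its ones-fraction
enters a target band around one half.

Each trial XORs the ORIGINAL stream with the next orbit block, so a single
stored map state — the state immediately preceding the successful block —
regenerates the exact keystream, and decoding is a single XOR.  The stored
triple (control parameter, keystream length, successful state) doubles as a
lightweight cipher key: without it the leading bits, and with them the rule
assignment of every group, cannot be reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MU_DEFAULT = 3.9
DEFAULT_BAND = (0.40, 0.60)
TIGHT_BAND = (0.49, 0.51)
MAX_ITER_DEFAULT = 10_000

__all__ = [
    "MU_DEFAULT",
    "DEFAULT_BAND",
    "TIGHT_BAND",
    "ChaoticParams",
    "BalanceError",
    "logistic_sequence",
    "binarize",
    "balance_first_bits",
    "derandomize_first_bits",
]


class BalanceError(RuntimeError):
    """Raised when no XOR iterate enters the balance band within max_iter."""


@dataclass(frozen=True)
class ChaoticParams:
    """Everything needed to invert the first-bit randomization.

    ``x0_success`` is the map state from which the successful keystream block
    is regenerated (the state just before its first element); with
    ``iterations == 0`` the input was already balanced and no XOR was applied.
    """

    mu: float
    x0_success: float
    keystream_length: int
    iterations: int
    balance_band: tuple

    def __post_init__(self):
        if not (0.0 < self.x0_success < 1.0):
            raise ValueError("x0_success must lie in (0, 1)")
        lo, hi = self.balance_band
        if not (lo < 0.5 < hi):
            raise ValueError("balance band must straddle 0.5")
        if self.iterations < 0 or self.keystream_length < 1:
            raise ValueError("invalid iteration count or keystream length")

    def to_dict(self) -> dict:
        return {
            "mu": repr(self.mu),
            "x0_success": repr(self.x0_success),
            "keystream_length": self.keystream_length,
            "iterations": self.iterations,
            "balance_band": [repr(self.balance_band[0]), repr(self.balance_band[1])],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ChaoticParams":
        return cls(
            mu=float(d["mu"]),
            x0_success=float(d["x0_success"]),
            keystream_length=int(d["keystream_length"]),
            iterations=int(d["iterations"]),
            balance_band=(float(d["balance_band"][0]), float(d["balance_band"][1])),
        )


def logistic_sequence(x0: float, mu: float, n: int) -> np.ndarray:
    """First ``n`` iterates of the logistic map from ``x0`` (x0 excluded).

    Degenerate seeds (0, 1, or anything outside the open unit interval) are
    rejected: their orbits collapse to the fixed point at zero.
    """
    if not (0.0 < x0 < 1.0):
        raise ValueError(f"x0 must lie strictly inside (0, 1), got {x0}")
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty(n, dtype=np.float64)
    x = x0
    for i in range(n):
        x = mu * x * (1.0 - x)
        out[i] = x
    return out


def binarize(xs) -> np.ndarray:
    """Threshold map values at one half: x >= 0.5 -> 1, else 0."""
    xs = np.asarray(xs, dtype=np.float64)
    if xs.size and (xs.min() < 0.0 or xs.max() > 1.0):
        raise ValueError("values must lie in [0, 1]")
    return (xs >= 0.5).astype(np.uint8)


def _as_bits(bits) -> np.ndarray:
    if isinstance(bits, str):
        bits = np.frombuffer(bits.encode(), np.uint8) - ord("0")
    return np.asarray(bits, dtype=np.uint8)


def ones_fraction(bits) -> float:
    bits = _as_bits(bits)
    return float(bits.mean())


def balance_first_bits(first_bits, x0: float, band=DEFAULT_BAND,
                       max_iter: int = MAX_ITER_DEFAULT, mu: float = MU_DEFAULT):
    """XOR the first-bit stream with successive keystream blocks until balanced.

    Balance is checked before any XOR: an input already inside ``[lo, hi]``
    is returned unchanged with ``iterations == 0``.  Returns
    ``(balanced_bits, ChaoticParams)``; raises :class:`BalanceError` when no
    iterate lands in the band within ``max_iter`` trials.
    """
    bits = _as_bits(first_bits)
    if bits.size < 1:
        raise ValueError("first_bits must be non-empty")
    lo, hi = band
    if lo <= bits.mean() <= hi:
        return bits.copy(), ChaoticParams(mu, x0, bits.size, 0, tuple(band))
    state = x0
    for k in range(1, max_iter + 1):
        block = logistic_sequence(state, mu, bits.size)
        candidate = bits ^ binarize(block)
        if lo <= candidate.mean() <= hi:
            return candidate, ChaoticParams(mu, state, bits.size, k, tuple(band))
        state = float(block[-1])
    raise BalanceError(
        f"no iterate entered band [{lo}, {hi}] within {max_iter} iterations"
    )


def derandomize_first_bits(balanced, params: ChaoticParams) -> np.ndarray:
    """Exact inverse of :func:`balance_first_bits`."""
    bits = _as_bits(balanced)
    if bits.size != params.keystream_length:
        raise ValueError(
            f"length {bits.size} does not match keystream_length "
            f"{params.keystream_length}"
        )
    if params.iterations == 0:
        return bits.copy()
    keystream = binarize(logistic_sequence(params.x0_success, params.mu, bits.size))
    return bits ^ keystream
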