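"""Lempel-Ziv complexity and the normalised entropy rate.

The epoch is binarised about its median and parsed with the Lempel-Ziv-76
scheme (exhaustive-production phrase counting).  The entropy rate
``Lz * log2(l) / l`` estimates the bits of innovation introduced per
sample; ~1 bit/sample for an i.i.d. fair coin, near 0 for a constant or
strongly predictable signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _fast

__all__ = ["EntropyRateComputation", "lz76_complexity", "entropy_rate"]


@dataclass
class EntropyRateComputation:
    lz: int          # LZ76 phrase count
    length: int      # samples in the epoch
    rate: float      # bits / sample


def lz76_complexity(bits) -> int:
    """Lempel-Ziv-76 complexity (number of phrases) of a binary sequence.

    Kaspar-Schuster formulation: scan left to right, extending the current
    phrase while it reproduces a substring of the prefix; each failure
    starts a new phrase.
    """
    arr = np.asarray(bits).astype(np.uint8)
    if arr.size == 0:
        raise ValueError("empty sequence")
    return int(_fast.lz76(arr))


def _lz76_reference(bits) -> int:
    """Pure-Python LZ76 scan (reference for the compiled version)."""
    s = "".join("1" if b else "0" for b in bits)
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    i, k, l = 0, 1, 1
    k_max = 1
    c = 1
    while True:
        if l + k > n:
            c += 1
            break
        if s[i + k - 1] == s[l + k - 1]:
            k += 1
        else:
            k_max = max(k, k_max)
            i += 1
            if i == l:
                c += 1
                l += k_max
                if l + 1 > n:
                    break
                i, k, k_max = 0, 1, 1
            else:
                k = 1
    return c


def entropy_rate(epoch: np.ndarray) -> EntropyRateComputation:
    """Normalised LZ76 entropy rate of an epoch binarised about its median."""
    x = np.asarray(epoch, dtype=float)
    l = len(x)
    if l < 2:
        raise ValueError("epoch must have at least 2 samples")
    bits = x > np.median(x)
    lz = lz76_complexity(bits)
    return EntropyRateComputation(lz, l, lz * np.log2(l) / l)
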