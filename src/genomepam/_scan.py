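"""Vectorized genome window scanning shared by the census and matcher."""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)  # everything unknown -> 4 (N)
for i, b in enumerate("ACGT"):
    _CODE[ord(b)] = i

BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Map an ACGTN string to uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def window_has_n(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask over start positions whose k-window contains an N."""
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return np.zeros(0, dtype=bool)
    is_n = codes == 4
    if not is_n.any():
        return np.zeros(n_win, dtype=bool)
    # prefix sums give N-count per window
    cs = np.concatenate(([0], np.cumsum(is_n)))
    return (cs[k:] - cs[:-k]) > 0


def mismatch_counts(codes: np.ndarray, allowed: list[np.ndarray]) -> np.ndarray:
    """Per-start-position count of query positions not matching the genome.

    ``allowed[j]`` is a length-5 boolean lookup saying which genome codes
    match query position j (N, code 4, never matches).  Returns an int16
    array over the ``len(codes) - k + 1`` window starts; windows containing
    N must be masked separately by the caller.
    """
    k = len(allowed)
    n_win = len(codes) - k + 1
    if n_win <= 0:
        return np.zeros(0, dtype=np.int16)
    mm = np.zeros(n_win, dtype=np.int16)
    for j, lut in enumerate(allowed):
        mm += ~lut[codes[j : j + n_win]]
    return mm


def exact_allowed(query: str) -> list[np.ndarray]:
    """Match tables for a plain ACGT query (one base allowed per position)."""
    out = []
    for ch in query:
        lut = np.zeros(5, dtype=bool)
        lut[_CODE[ord(ch)]] = True
        out.append(lut)
    return out
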