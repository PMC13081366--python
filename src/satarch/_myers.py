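"""Bit-parallel semi-global pattern scan (Myers' algorithm).

Computes, for every end position in a text, the minimal edit distance of the
pattern against any text window ending there (free text prefix/suffix).  With
pattern length <= 64 the column fits one machine word, giving an O(n) scan
per pattern that is complete for every locus at distance <= max_d — no
seeding heuristic is involved.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def encode_text(seq: str) -> np.ndarray:
    """Encode A/C/G/T as 0..3 and anything else as 4 (matches nothing)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _BASE_CODE[raw]


def pattern_eq(pattern: str) -> np.ndarray:
    """Per-symbol match bitmasks for a pattern (length <= 64 enforced)."""
    m = len(pattern)
    if not (0 < m <= 64):
        raise ValueError("pattern length must be in 1..64")
    peq = np.zeros(5, dtype=np.int64)
    for i, ch in enumerate(pattern):
        code = _BASE_CODE[ord(ch)]
        if code < 4:
            peq[code] |= np.int64(1) << np.int64(i)
    return peq


@njit(cache=True)
def scan_ends(text: np.ndarray, peq: np.ndarray, m: int, max_d: int):
    """End positions (exclusive) and distances where the semi-global edit
    distance of the pattern is <= max_d."""
    n = text.shape[0]
    mask = (np.int64(1) << np.int64(m)) - np.int64(1)
    high = np.int64(1) << np.int64(m - 1)
    pv = mask
    mv = np.int64(0)
    score = m
    ends = []
    dists = []
    for j in range(n):
        eq = peq[text[j]]
        xv = eq | mv
        xh = (((eq & pv) + pv) ^ pv) | eq
        ph = mv | (~(xh | pv) & mask)
        mh = pv & xh
        if ph & high:
            score += 1
        elif mh & high:
            score -= 1
        ph = (ph << np.int64(1)) & mask
        mh = (mh << np.int64(1)) & mask
        pv = (mh | (~(xv | ph) & mask))
        mv = ph & xv
        if score <= max_d:
            ends.append(j + 1)
            dists.append(score)
    return ends, dists
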