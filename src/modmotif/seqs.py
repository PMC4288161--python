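"""Low-level DNA sequence encoding shared by the counting and planting code.

Bases are encoded A=0, C=1, G=2, T=3; anything else (notably the masking
character 'N') becomes 255 and poisons every window that covers it.
k-mers are packed into integers base-4, most significant digit first, so the
lexicographic order of pattern strings equals the numeric order of codes.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _LUT[ord(_b)] = _i
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def encode(seq: str) -> np.ndarray:
    """Encode a sequence string into uint8 codes (255 for non-ACGT)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for i in range(k):
        out.append(BASES[(code >> (2 * (k - 1 - i))) & 3])
    return "".join(out)


def encode_kmer(pattern: str) -> int:
    code = 0
    for ch in pattern:
        v = _LUT[ord(ch)]
        if v == 255:
            raise ValueError(f"non-ACGT base in pattern {pattern!r}")
        code = (code << 2) | int(v)
    return code


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def rc_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Vectorized reverse complement of packed k-mer codes."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.zeros_like(codes)
    for i in range(k):
        digit = (codes >> (2 * (k - 1 - i))) & 3
        out |= (3 - digit) << (2 * i)
    return out


def canonical_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Merge each code with its reverse complement under the smaller key."""
    rc = rc_codes(codes, k)
    return np.minimum(np.asarray(codes, dtype=np.int64), rc)


def canonical_pattern(pattern: str) -> str:
    rc = revcomp(pattern)
    return pattern if pattern <= rc else rc


def window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Packed codes of all N-free length-k windows, in positional order.

    Windows containing any invalid base are dropped.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    invalid = (codes == 255).astype(np.int32)
    cum = np.concatenate(([0], np.cumsum(invalid)))
    bad = (cum[k:] - cum[:-k]) > 0
    safe = np.where(codes == 255, 0, codes).astype(np.int64)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    vals = np.lib.stride_tricks.sliding_window_view(safe, k) @ powers
    return vals[~bad]
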