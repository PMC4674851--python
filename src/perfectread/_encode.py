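"""2-bit k-mer codes and vectorized window extraction.

Bases map A=0, C=1, G=2, T=3 so that integer order on codes equals
lexicographic order on equal-length k-mer strings; the canonical code of a
window is therefore min(code, revcomp_code). N maps to -1 (never countable),
any other byte to -2 (used internally as a read-boundary sentinel).
"""

from __future__ import annotations

import numpy as np

_LUT = np.full(256, -2, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i
    _LUT[_b + 32] = _i  # lowercase
_LUT[ord("N")] = -1
_LUT[ord("n")] = -1

_LETTERS = np.frombuffer(b"ACGT", dtype=np.uint8)

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def seq_to_ints(seq: str | bytes) -> np.ndarray:
    """Map a sequence to int8 base codes (A0 C1 G2 T3, N=-1, other=-2)."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def encode_kmer(kmer: str) -> int:
    """2-bit code of a k-mer; raises on non-ACGT characters."""
    b = seq_to_ints(kmer)
    if (b < 0).any():
        raise ValueError(f"invalid k-mer (non-ACGT character): {kmer!r}")
    code = 0
    for v in b:
        code = (code << 2) | int(v)
    return code


def decode_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k - 1, -1, -1):
        out.append("ACGT"[(code >> (2 * j)) & 3])
    return "".join(out)


def revcomp_code(code: int, k: int) -> int:
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


def canonical_code(code: int, k: int) -> tuple[int, bool]:
    """(canonical code, flipped) where flipped means revcomp was smaller."""
    rc = revcomp_code(code, k)
    if rc < code:
        return rc, True
    return code, False


def codes_to_strings(codes: np.ndarray, k: int) -> np.ndarray:
    """Decode an int64 code array to a unicode array of k-mer strings."""
    codes = np.asarray(codes, dtype=np.int64)
    shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
    digits = ((codes[:, None] >> shifts[None, :]) & 3).astype(np.uint8)
    return np.ascontiguousarray(_LETTERS[digits]).view(f"S{k}")[:, 0].astype("U")


def window_min(a: np.ndarray, k: int) -> np.ndarray:
    """m[i] = min(a[i:i+k]) for every start position i."""
    n = a.shape[0] - k + 1
    if n <= 0:
        return np.empty(0, dtype=a.dtype)
    m = a[:n].copy()
    for j in range(1, k):
        np.minimum(m, a[j : j + n], out=m)
    return m


def window_codes(b: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Forward and reverse-complement codes for every length-k window.

    ``b`` is an int8 base-code array (negatives mark N / sentinels). Returns
    (codes_fwd, codes_rc, base_ok) where base_ok[i] is True iff window i
    contains only A/C/G/T. Codes of invalid windows are meaningless.
    """
    n = b.shape[0] - k + 1
    if n <= 0:
        z = np.empty(0, dtype=np.int64)
        return z, z.copy(), np.empty(0, dtype=bool)
    b64 = np.where(b >= 0, b, 0).astype(np.int64)
    cf = np.zeros(n, dtype=np.int64)
    cr = np.zeros(n, dtype=np.int64)
    for j in range(k):
        np.left_shift(cf, 2, out=cf)
        np.bitwise_or(cf, b64[j : j + n], out=cf)
        cr |= (3 - b64[j : j + n]) << (2 * j)
    base_ok = window_min(b, k) >= 0
    return cf, cr, base_ok
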