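"""Neighbor queries over the spectrum's k-mer set (Hamming distance <= d).

Replaces a materialized Hamming graph: neighbors are enumerated lazily per
query by XOR-ing every possible <=d-position substitution into the query's
2-bit code and testing membership in the spectrum's sorted code array.
Distances are computed between canonical representations only (no
strand-aware minimum); queries are canonicalized before lookup.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from ._encode import canonical_code, codes_to_strings, encode_kmer
from .kmer_spectrum import KmerSpectrum

__all__ = ["HammingIndex", "build_index", "neighbors"]


def _xor_deltas(k: int, d: int) -> np.ndarray:
    """All XOR masks changing exactly 1..d base positions of a 2-bit code.

    For a 2-bit digit b and x in {1,2,3}, b ^ x enumerates the three other
    bases, so code ^ (x << 2j) substitutes position j.
    """
    deltas: list[int] = []
    singles = [[x << (2 * j) for x in (1, 2, 3)] for j in range(k)]
    for dist in range(1, d + 1):
        for positions in combinations(range(k), dist):
            choices = [singles[j] for j in positions]
            stack = [0]
            for ch in choices:
                stack = [s | c for s in stack for c in ch]
            deltas.extend(stack)
    return np.asarray(deltas, dtype=np.int64)


class HammingIndex:
    """Exact <=d-substitution neighbor lookup over a KmerSpectrum's keys."""

    def __init__(self, spectrum: KmerSpectrum, d: int = 1):
        if d < 1:
            raise ValueError("d must be >= 1")
        if d >= spectrum.k:
            raise ValueError("d >= k makes every k-mer a neighbor of every other")
        self.spectrum = spectrum
        self.d = d
        self.k = spectrum.k
        self._deltas = _xor_deltas(self.k, d)
        self._cache: dict[int, tuple[np.ndarray, np.ndarray]] = {}

    def neighbor_codes(self, code: int) -> tuple[np.ndarray, np.ndarray]:
        """(codes, frequencies) of all stored k-mers within distance d.

        ``code`` must already be canonical; the query itself is never
        returned (all enumerated variants differ in >=1 position).
        """
        hit = self._cache.get(code)
        if hit is not None:
            return hit
        variants = code ^ self._deltas
        uni = self.spectrum.codes
        pos = np.searchsorted(uni, variants)
        np.minimum(pos, max(uni.shape[0] - 1, 0), out=pos)
        found = uni.shape[0] > 0
        mask = (uni[pos] == variants) if found else np.zeros(0, bool)
        res = (variants[mask], self.spectrum.freqs[pos[mask]])
        if len(self._cache) < 2_000_000:
            self._cache[code] = res
        return res

    def neighbors(self, kmer: str) -> set[tuple[str, int]]:
        """Set of (neighbor k-mer, frequency); query canonicalized first."""
        if len(kmer) != self.k:
            raise ValueError(f"query must have length k={self.k}")
        code, _ = canonical_code(encode_kmer(kmer), self.k)
        codes, freqs = self.neighbor_codes(code)
        names = codes_to_strings(codes, self.k)
        return set(zip(names.tolist(), freqs.tolist()))


    def export_edges(self, path) -> int:
        """Debug dump: TSV `kmer_a  kmer_b  hamming_distance`, each
        unordered pair once. Enumerates the whole universe; small inputs
        only."""
        names = codes_to_strings(self.spectrum.codes, self.k)
        by_code = dict(zip(self.spectrum.codes.tolist(), names.tolist()))
        n = 0
        with open(path, "w") as out:
            for code, name in by_code.items():
                ncodes, _ = self.neighbor_codes(code)
                for nc in ncodes:
                    if code < int(nc):
                        hd = sum(
                            1
                            for j in range(self.k)
                            if ((code ^ int(nc)) >> (2 * j)) & 3
                        )
                        out.write(f"{name}\t{by_code[int(nc)]}\t{hd}\n")
                        n += 1
        return n


def build_index(spectrum: KmerSpectrum, d: int = 1) -> HammingIndex:
    """Build the neighbor-query structure for distance <= d."""
    return HammingIndex(spectrum, d)


def neighbors(index: HammingIndex, kmer: str) -> set[tuple[str, int]]:
    return index.neighbors(kmer)
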