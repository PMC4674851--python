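"""Quality-aware canonical k-mer counting (phase 1 of the classifier).

An instance of a k-mer is counted only if every one of its k bases has
quality >= ``q_excellent`` (the Excellent Quality threshold, inclusive) and
none of the bases is N. A k-mer and its reverse complement are merged under
the lexicographically smaller of the two (canonical form).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from ._encode import (
    canonical_code,
    codes_to_strings,
    encode_kmer,
    revcomp_code,
    seq_to_ints,
    window_codes,
    window_min,
)
from .fastq_io import ReadRecord

__all__ = [
    "KmerSpectrum",
    "KmerHistogram",
    "canonical",
    "build_spectrum",
    "histogram",
]


def canonical(kmer: str) -> str:
    """Lexicographically smaller of a k-mer and its reverse complement."""
    code = encode_kmer(kmer)  # raises on non-ACGT
    rc = revcomp_code(code, len(kmer))
    if rc < code:
        return codes_to_strings(np.array([rc]), len(kmer))[0]
    return kmer.upper()


@dataclass
class KmerSpectrum:
    """Canonical k-mer -> quality-filtered frequency f(T).

    Internally k-mers are 2-bit codes held in a sorted int64 array; the
    ``counts`` mapping view (canonical string -> frequency) is materialized
    lazily for API/debugging use.
    """

    k: int
    q_excellent: int
    codes: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    freqs: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    n_instances_counted: int = 0
    n_instances_skipped: int = 0

    def __post_init__(self) -> None:
        if self.k < 2 or self.k % 2:
            raise ValueError("k must be an even integer >= 2")
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.freqs = np.asarray(self.freqs, dtype=np.int64)

    @property
    def n_distinct(self) -> int:
        return int(self.codes.shape[0])

    def f_codes(self, codes: np.ndarray) -> np.ndarray:
        """Frequencies for an array of canonical codes (0 when absent)."""
        codes = np.asarray(codes, dtype=np.int64)
        pos = np.searchsorted(self.codes, codes)
        pos_c = np.minimum(pos, max(self.n_distinct - 1, 0))
        out = np.zeros(codes.shape, dtype=np.int64)
        if self.n_distinct:
            hit = self.codes[pos_c] == codes
            out[hit] = self.freqs[pos_c[hit]]
        return out

    def f_code(self, code: int) -> int:
        return int(self.f_codes(np.array([code], dtype=np.int64))[0])

    def f(self, kmer: str) -> int:
        """f(T) for a k-mer given as a string (canonicalized first)."""
        if len(kmer) != self.k:
            raise ValueError(f"expected a {self.k}-mer, got length {len(kmer)}")
        try:
            code, _ = canonical_code(encode_kmer(kmer), self.k)
        except ValueError:
            return 0  # k-mers containing N are never in the spectrum
        return self.f_code(code)

    @cached_property
    def counts(self) -> dict[str, int]:
        """Mapping view: canonical k-mer string -> frequency."""
        keys = codes_to_strings(self.codes, self.k)
        return dict(zip(keys.tolist(), self.freqs.tolist()))

    # --- persistence ------------------------------------------------------
    def to_tsv(self, path) -> None:
        """TSV `kmer<tab>count` plus a JSON sidecar with the metadata."""
        path = Path(path)
        keys = codes_to_strings(self.codes, self.k)
        with open(path, "w") as out:
            for kmer, f in zip(keys, self.freqs):
                out.write(f"{kmer}\t{int(f)}\n")
        meta = {
            "k": self.k,
            "q_excellent": self.q_excellent,
            "n_instances_counted": self.n_instances_counted,
            "n_instances_skipped": self.n_instances_skipped,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))

    @classmethod
    def from_tsv(cls, path) -> "KmerSpectrum":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        codes, freqs = [], []
        with open(path) as handle:
            for line in handle:
                kmer, f = line.split("\t")
                codes.append(encode_kmer(kmer))
                freqs.append(int(f))
        order = np.argsort(codes)
        return cls(
            k=meta["k"],
            q_excellent=meta["q_excellent"],
            codes=np.asarray(codes, np.int64)[order],
            freqs=np.asarray(freqs, np.int64)[order],
            n_instances_counted=meta["n_instances_counted"],
            n_instances_skipped=meta["n_instances_skipped"],
        )


@dataclass
class KmerHistogram:
    """bins[x] = number of distinct k-mers with frequency exactly x."""

    bins: dict[int, int] = field(default_factory=dict)

    def dense(self) -> np.ndarray:
        """Counts on the dense frequency axis 0..max_frequency."""
        if not self.bins:
            return np.zeros(1, dtype=np.int64)
        out = np.zeros(max(self.bins) + 1, dtype=np.int64)
        for x, c in self.bins.items():
            out[x] = c
        return out

    def to_tsv(self, path) -> None:
        with open(path, "w") as out:
            for x in sorted(self.bins):
                out.write(f"{x}\t{self.bins[x]}\n")


def concat_reads(
    reads: Sequence[ReadRecord],
) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate reads into one base-code and one quality array.

    Reads are joined with a single sentinel position (base -2, quality -1)
    so that no window spans two reads.
    """
    seq = b"\x00".join(r.sequence.encode("ascii") for r in reads)
    b = seq_to_ints(seq)
    q = np.full(b.shape[0], -1, dtype=np.int16)
    off = 0
    for r in reads:
        q[off : off + len(r)] = r.qualities
        off += len(r) + 1
    return b, q


def build_spectrum(
    reads: Iterable[ReadRecord], k: int = 24, q_excellent: int = 0
) -> KmerSpectrum:
    """Count canonical k-mers over every read position, quality-filtered.

    Every length-k window of every read contributes +1 to its canonical
    k-mer iff all bases are A/C/G/T and all qualities are >= q_excellent;
    windows failing either test are tallied as skipped.
    """
    if k < 2 or k % 2:
        raise ValueError("k must be an even integer >= 2")
    reads = list(reads) if not isinstance(reads, Sequence) else reads
    spec = KmerSpectrum(k=k, q_excellent=q_excellent)
    if not reads:
        warnings.warn("no countable k-mer instance in input (empty spectrum)")
        return spec
    b, q = concat_reads(reads)
    cf, cr, base_ok = window_codes(b, k)
    minq = window_min(q, k)
    in_read = window_min(np.where(b == -2, np.int8(-2), np.int8(0)), k) >= 0
    countable = base_ok & (minq >= q_excellent) & in_read
    canon = np.minimum(cf, cr)[countable]
    codes, freqs = np.unique(canon, return_counts=True)
    spec.codes = codes
    spec.freqs = freqs.astype(np.int64)
    spec.n_instances_counted = int(countable.sum())
    spec.n_instances_skipped = int(in_read.sum()) - spec.n_instances_counted
    if spec.n_instances_counted == 0:
        warnings.warn("no countable k-mer instance in input (empty spectrum)")
    return spec


def histogram(spectrum: KmerSpectrum) -> KmerHistogram:
    """Frequency histogram: how many distinct k-mers occur exactly x times."""
    xs, cs = np.unique(spectrum.freqs, return_counts=True)
    return KmerHistogram(dict(zip(xs.tolist(), cs.tolist())))
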