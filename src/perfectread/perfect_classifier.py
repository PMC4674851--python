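"""Perfect/Erroneous read classification (phase 2).

A read is decomposed into k-mers overlapping by k/2 (the final k-mer is the
length-k suffix when the stride would overshoot) and declared Perfect iff
every visited k-mer is valid under Rule i, i.e. satisfies any one of:

  P1: f(T) >= C_E
  P2: f(T) >= C_G and every base of this instance has quality >= Q_G
  P3: f(T) >= C_G and no neighbor T' has f(T') >= C_G
  P4: f(T) >= C_G and no neighbor T' has f(T') >= f(T) * F_H
  P5: f(T) >= C_G and for every neighbor T', every position where T differs
      from T' has instance quality >= Q_G

f(T) is the quality-filtered canonical frequency from the KmerSpectrum; a
k-mer containing N or absent from the spectrum has f = 0 and can only fail.
Properties are tested in order and short-circuit on the first satisfied one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from ._encode import canonical_code, encode_kmer, seq_to_ints
from .fastq_io import ReadRecord
from .hamming_index import HammingIndex
from .kmer_spectrum import KmerSpectrum

__all__ = [
    "RuleConfig",
    "Classification",
    "FilterSummary",
    "ShortReadError",
    "kmer_positions",
    "kmer_is_valid",
    "classify_read",
    "classify_many",
    "filter_dataset",
]


class ShortReadError(ValueError):
    """Read shorter than k cannot be decomposed into k-mers."""


@dataclass
class RuleConfig:
    """Classifier parameters.

    Quality thresholds ``q_g``/``q_e`` are given in ``quality_unit``:
    ``"ascii"`` means raw ASCII codes of the quality characters (the unit
    the published defaults 45/71/73 are written in), ``"phred"`` means the
    decoded values stored on ReadRecords. ``quality_offset`` is the
    encoding offset of the data and converts between the two.
    """

    rule_level: int = 2
    c_e: int = 8
    c_g: int = 1
    q_g: int = 45
    q_e: int = 73
    f_h: float = 2.0
    d: int = 1
    quality_unit: Literal["ascii", "phred"] = "ascii"
    quality_offset: int = 33

    def __post_init__(self) -> None:
        if not 1 <= self.rule_level <= 5:
            raise ValueError("rule_level must be in 1..5")
        if self.c_e <= self.c_g:
            raise ValueError("C_E must be greater than C_G")
        if self.q_e <= self.q_g:
            raise ValueError("Q_E must be greater than Q_G")
        if self.f_h <= 1:
            raise ValueError("F_H must be > 1")
        if self.d < 1:
            raise ValueError("d must be >= 1")

    def _decode(self, q: int) -> int:
        return q - self.quality_offset if self.quality_unit == "ascii" else q

    @property
    def q_g_decoded(self) -> int:
        return self._decode(self.q_g)

    @property
    def q_e_decoded(self) -> int:
        return self._decode(self.q_e)

    @classmethod
    def from_decoded(cls, q_g: int, q_e: int, **kw) -> "RuleConfig":
        """Build a config whose quality thresholds are already decoded."""
        return cls(q_g=q_g, q_e=q_e, quality_unit="phred", **kw)


@dataclass
class Classification:
    """Outcome for one read, with the audit trail of visited k-mers."""

    read_id: str
    label: Literal["Perfect", "Erroneous"]
    checked_positions: list[int] = field(default_factory=list)
    first_invalid_position: int | None = None
    first_invalid_kmer: str | None = None
    is_short: bool = False

    @property
    def is_perfect(self) -> bool:
        return self.label == "Perfect"


@dataclass
class FilterSummary:
    n_input: int = 0
    n_perfect: int = 0
    n_erroneous: int = 0
    n_short: int = 0
    parameters: dict = field(default_factory=dict)
    property_hits: dict = field(default_factory=dict)


def kmer_positions(read_length: int, k: int) -> list[int]:
    """Start offsets of the k-mers visited by the error-detection scan.

    The scan starts at 0 and advances by k/2 while a full further stride
    fits ((p + k/2) + k < |r|); otherwise it jumps to the final window
    |r| - k. A window ending exactly at the read end terminates the scan.
    """
    if k < 2 or k % 2:
        raise ValueError("k must be an even integer >= 2")
    if read_length < k:
        raise ShortReadError(f"read length {read_length} < k={k}")
    positions = []
    p = 0
    while True:
        positions.append(p)
        if p + k == read_length:
            return positions
        if (p + k // 2) + k < read_length:
            p += k // 2
        else:
            p = read_length - k


def _neighbor_info(index: HammingIndex, code: int):
    return index.neighbor_codes(code)


def kmer_is_valid(
    kmer: str,
    qualities: Sequence[int] | np.ndarray,
    spectrum: KmerSpectrum,
    index: HammingIndex | None,
    cfg: RuleConfig,
) -> tuple[bool, str | None]:
    """Test properties P1..P(rule_level) in order; return first satisfied.

    ``qualities`` are this instance's per-base qualities in read
    orientation; P5's differing-position lookups are mapped through the
    canonical-strand flip when the stored key is the reverse complement.
    """
    k = spectrum.k
    if len(kmer) != k:
        raise ValueError(f"expected a {k}-mer")
    b = seq_to_ints(kmer)
    if (b < 0).any():
        return False, None  # contains N: cannot be genomic evidence
    code = 0
    for v in b:
        code = (code << 2) | int(v)
    canon, flipped = canonical_code(code, k)
    f = spectrum.f_code(canon)
    q = np.asarray(qualities, dtype=np.int16)
    q_g = cfg.q_g_decoded

    if f >= cfg.c_e:
        return True, "P1"
    if cfg.rule_level < 2 or f < cfg.c_g:
        return False, None
    if int(q.min()) >= q_g:
        return True, "P2"
    if cfg.rule_level < 3:
        return False, None
    if index is None:
        raise ValueError("rules 3-5 require a HammingIndex")
    ncodes, nfreqs = _neighbor_info(index, canon)
    if cfg.rule_level >= 3 and not (nfreqs >= cfg.c_g).any():
        return True, "P3"
    if cfg.rule_level >= 4 and not (nfreqs >= f * cfg.f_h).any():
        return True, "P4"
    if cfg.rule_level >= 5:
        if _p5_holds(canon, flipped, ncodes, q, q_g, k):
            return True, "P5"
    return False, None


def _p5_holds(
    canon: int,
    flipped: bool,
    ncodes: np.ndarray,
    q: np.ndarray,
    q_g: int,
    k: int,
) -> bool:
    """P5: every position where T differs from any neighbor has q >= Q_G.

    Digit j (from the least-significant end of the canonical code) is
    canonical-string index k-1-j; if the canonical key is the reverse
    complement of the read window, string index i maps back to instance
    position k-1-i, i.e. digit j maps to instance position j.
    """
    for ncode in ncodes:
        x = int(canon) ^ int(ncode)
        j = 0
        while x:
            if x & 3:
                pos = j if flipped else k - 1 - j
                if int(q[pos]) < q_g:
                    return False
            x >>= 2
            j += 1
    return True


def classify_read(
    read: ReadRecord,
    spectrum: KmerSpectrum,
    index: HammingIndex | None,
    cfg: RuleConfig,
    short_read: Literal["erroneous", "error"] = "erroneous",
) -> Classification:
    """Scan the read's k-mer schedule; Erroneous at the first invalid k-mer."""
    k = spectrum.k
    if len(read) < k:
        if short_read == "error":
            raise ShortReadError(f"read {read.read_id!r} shorter than k={k}")
        return Classification(read.read_id, "Erroneous", [], None, None, is_short=True)
    checked: list[int] = []
    for p in kmer_positions(len(read), k):
        checked.append(p)
        kmer = read.sequence[p : p + k]
        valid, _ = kmer_is_valid(kmer, read.qualities[p : p + k], spectrum, index, cfg)
        if not valid:
            return Classification(read.read_id, "Erroneous", checked, p, kmer)
    return Classification(read.read_id, "Perfect", checked)


# ---------------------------------------------------------------------------
# Batched classification: vectorizes P1/P2 over all reads of equal length and
# falls back to the scalar property chain only for the rare windows that
# reach P3..P5. Produces results identical to classify_read.
# ---------------------------------------------------------------------------


def _group_windows(reads: Sequence[ReadRecord], k: int, positions: list[int]):
    """Canonical codes, flip flags, min-quality and base-validity per window."""
    m = len(reads)
    length = len(reads[0])
    w = len(positions)
    blob = b"".join(r.sequence.encode("ascii") for r in reads)
    b = seq_to_ints(blob).reshape(m, length)
    qm = np.empty((m, length), dtype=np.int16)
    for i, r in enumerate(reads):
        qm[i] = r.qualities
    b64 = np.where(b >= 0, b, 0).astype(np.int64)
    cf = np.zeros((m, w), dtype=np.int64)
    cr = np.zeros((m, w), dtype=np.int64)
    minq = np.empty((m, w), dtype=np.int16)
    base_ok = np.empty((m, w), dtype=bool)
    for wi, p in enumerate(positions):
        colf = np.zeros(m, dtype=np.int64)
        colr = np.zeros(m, dtype=np.int64)
        for j in range(k):
            np.left_shift(colf, 2, out=colf)
            np.bitwise_or(colf, b64[:, p + j], out=colf)
            colr |= (3 - b64[:, p + j]) << (2 * j)
        cf[:, wi] = colf
        cr[:, wi] = colr
        minq[:, wi] = qm[:, p : p + k].min(axis=1)
        base_ok[:, wi] = b[:, p : p + k].min(axis=1) >= 0
    canon = np.minimum(cf, cr)
    return canon, cf, minq, base_ok, b, qm


def classify_many(
    reads: Iterable[ReadRecord],
    spectrum: KmerSpectrum,
    index: HammingIndex | None,
    cfg: RuleConfig,
    short_read: Literal["erroneous", "error"] = "erroneous",
    property_hits: dict | None = None,
) -> list[Classification]:
    """Classify a batch of reads; identical outcomes to classify_read."""
    reads = list(reads)
    k = spectrum.k
    results: list[Classification | None] = [None] * len(reads)
    by_length: dict[int, list[int]] = {}
    for i, r in enumerate(reads):
        if len(r) < k:
            if short_read == "error":
                raise ShortReadError(f"read {r.read_id!r} shorter than k={k}")
            results[i] = Classification(
                r.read_id, "Erroneous", [], None, None, is_short=True
            )
        else:
            by_length.setdefault(len(r), []).append(i)

    hits = property_hits if property_hits is not None else {}
    for prop in ("P1", "P2", "P3", "P4", "P5"):
        hits.setdefault(prop, 0)
    p34_cache: dict[int, tuple[bool, bool, int]] = {}

    for length, idxs in by_length.items():
        group = [reads[i] for i in idxs]
        positions = kmer_positions(length, k)
        canon, _cf, minq, base_ok, _b, qm = _group_windows(group, k, positions)
        f = spectrum.f_codes(canon)
        f[~base_ok] = 0
        q_g = cfg.q_g_decoded
        p1 = f >= cfg.c_e
        valid = p1.copy()
        prop = np.where(p1, 1, 0).astype(np.int8)
        if cfg.rule_level >= 2:
            p2 = ~valid & (f >= cfg.c_g) & (minq >= q_g) & base_ok
            valid |= p2
            prop[p2] = 2
        if cfg.rule_level >= 3:
            if index is None:
                raise ValueError("rules 3-5 require a HammingIndex")
            pend = ~valid & (f >= cfg.c_g) & base_ok
            for gi in zip(*np.nonzero(pend)):
                ri, wi = int(gi[0]), int(gi[1])
                code = int(canon[ri, wi])
                cached = p34_cache.get(code)
                if cached is None:
                    ncodes, nfreqs = index.neighbor_codes(code)
                    p3 = not (nfreqs >= cfg.c_g).any()
                    p4 = not (nfreqs >= f[ri, wi] * cfg.f_h).any()
                    p34_cache[code] = (p3, p4, int(f[ri, wi]))
                else:
                    p3, p4, _ = cached
                    ncodes = None
                if p3:
                    valid[ri, wi] = True
                    prop[ri, wi] = 3
                    continue
                if cfg.rule_level >= 4 and p4:
                    valid[ri, wi] = True
                    prop[ri, wi] = 4
                    continue
                if cfg.rule_level >= 5:
                    if ncodes is None:
                        ncodes, _ = index.neighbor_codes(code)
                    p = positions[wi]
                    flipped = canon[ri, wi] != _cf[ri, wi]
                    if _p5_holds(
                        code, bool(flipped), ncodes, qm[ri, p : p + k], q_g, k
                    ):
                        valid[ri, wi] = True
                        prop[ri, wi] = 5

        invalid_any = ~valid.all(axis=1)
        first_bad = np.argmax(~valid, axis=1)
        for gi, i in enumerate(idxs):
            r = reads[i]
            if invalid_any[gi]:
                wi = int(first_bad[gi])
                p = positions[wi]
                results[i] = Classification(
                    r.read_id,
                    "Erroneous",
                    positions[: wi + 1],
                    p,
                    r.sequence[p : p + k],
                )
                visited = prop[gi, : wi + 1]
            else:
                results[i] = Classification(r.read_id, "Perfect", list(positions))
                visited = prop[gi]
            for v in visited:
                if v:
                    hits[f"P{v}"] += 1
    return results  # type: ignore[return-value]


def filter_dataset(
    reads: Iterable[ReadRecord],
    spectrum: KmerSpectrum,
    index: HammingIndex | None,
    cfg: RuleConfig,
    short_read: Literal["erroneous", "error"] = "erroneous",
) -> tuple[list[ReadRecord], list[ReadRecord], FilterSummary]:
    """Partition reads into (predicted-perfect, predicted-erroneous).

    Short reads are routed to the erroneous stream but tallied separately,
    so n_perfect + n_erroneous + n_short == n_input.
    """
    reads = list(reads)
    hits: dict = {}
    classifications = classify_many(
        reads, spectrum, index, cfg, short_read, property_hits=hits
    )
    perfect: list[ReadRecord] = []
    erroneous: list[ReadRecord] = []
    summary = FilterSummary(
        n_input=len(reads),
        parameters={
            "k": spectrum.k,
            "rule_level": cfg.rule_level,
            "C_E": cfg.c_e,
            "C_G": cfg.c_g,
            "Q_G": cfg.q_g,
            "Q_E": cfg.q_e,
            "F_H": cfg.f_h,
            "d": cfg.d,
            "quality_unit": cfg.quality_unit,
        },
        property_hits=hits,
    )
    for r, c in zip(reads, classifications):
        if c.is_perfect:
            perfect.append(r)
            summary.n_perfect += 1
        else:
            erroneous.append(r)
            if c.is_short:
                summary.n_short += 1
            else:
                summary.n_erroneous += 1
    return perfect, erroneous, summary
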