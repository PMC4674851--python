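"""k-mer histogram diagnostics: applicability prediction and parameter hints.

A k-spectrum classifier works when the frequency histogram of all k-mers
shows the expected shape: a large low-frequency mass of error (bad) k-mers,
a dip, then a roughly normal mode of genomic (good) k-mers centred near the
average coverage. This module categorizes k-mers as good/bad/mixed when
ground truth is available, detects the dip and the mode, renders an
applicability verdict, and suggests the counting/classification thresholds.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._encode import canonical_code, codes_to_strings, encode_kmer, window_codes, window_min, seq_to_ints
from .fastq_io import GroundTruthLabel, ReadRecord
from .kmer_spectrum import KmerHistogram, KmerSpectrum, concat_reads

__all__ = [
    "KmerCategories",
    "CategorizedHistogram",
    "ApplicabilityReport",
    "categorize_kmers",
    "categorized_histogram",
    "first_local_minimum",
    "crossover_threshold",
    "assess_applicability",
    "suggest_quality_thresholds",
    "auto_configure",
]

GOOD, BAD, MIXED = 0, 1, 2
_NAMES = {GOOD: "good", BAD: "bad", MIXED: "mixed"}


class KmerCategories(Mapping):
    """Mapping canonical k-mer -> 'good' | 'bad' | 'mixed'.

    good: every occurrence lies in an error-free window of its read;
    bad: every occurrence overlaps an error; mixed: both kinds occur.
    Backed by sorted code arrays; string keys are decoded on demand.
    """

    def __init__(self, k: int, codes: np.ndarray, cats: np.ndarray):
        self.k = k
        self.codes = codes
        self.cats = cats

    def category_of_codes(self, codes: np.ndarray) -> np.ndarray:
        pos = np.searchsorted(self.codes, codes)
        pos_c = np.minimum(pos, max(len(self.codes) - 1, 0))
        if len(self.codes) == 0 or not (self.codes[pos_c] == codes).all():
            raise KeyError("k-mer not seen in the categorized read set")
        return self.cats[pos_c]

    def __getitem__(self, kmer: str) -> str:
        code, _ = canonical_code(encode_kmer(kmer), self.k)
        pos = int(np.searchsorted(self.codes, code))
        if pos >= len(self.codes) or self.codes[pos] != code:
            raise KeyError(kmer)
        return _NAMES[int(self.cats[pos])]

    def __iter__(self):
        return iter(codes_to_strings(self.codes, self.k).tolist())

    def __len__(self) -> int:
        return len(self.codes)


@dataclass
class CategorizedHistogram:
    """Per-frequency distinct-k-mer counts, split by category."""

    bins_all: dict[int, int] = field(default_factory=dict)
    bins_good: dict[int, int] = field(default_factory=dict)
    bins_bad: dict[int, int] = field(default_factory=dict)
    bins_mixed: dict[int, int] = field(default_factory=dict)

    def to_tsv(self, path) -> None:
        xs = sorted(self.bins_all)
        with open(path, "w") as out:
            out.write("frequency\tall\tgood\tbad\tmixed\n")
            for x in xs:
                out.write(
                    f"{x}\t{self.bins_all.get(x, 0)}\t{self.bins_good.get(x, 0)}"
                    f"\t{self.bins_bad.get(x, 0)}\t{self.bins_mixed.get(x, 0)}\n"
                )


@dataclass
class ApplicabilityReport:
    pattern_ok: bool
    first_minimum: int | None = None
    crossover_threshold: int | None = None
    peak_frequency: int | None = None
    suggested: dict = field(default_factory=dict)


def categorize_kmers(
    reads: Sequence[ReadRecord],
    truth: Mapping[str, GroundTruthLabel],
    k: int,
) -> KmerCategories:
    """Pool every window occurrence (all positions) over canonical identity.

    An occurrence at read offset p is erroneous iff [p, p+k) contains any
    of that read's error positions. Requires truth with known error
    positions for every read; windows containing N are ignored.
    """
    reads = list(reads)
    b_parts: list[np.ndarray] = []
    e_parts: list[np.ndarray] = []
    sep_b = np.array([-2], dtype=np.int8)
    sep_e = np.array([0], dtype=np.int8)
    for r in reads:
        try:
            lab = truth[r.read_id]
        except KeyError as exc:
            raise KeyError(f"read {r.read_id!r} missing from truth") from exc
        if lab.error_positions is None:
            raise ValueError(
                f"read {r.read_id!r}: truth has no error positions; "
                "categorization needs position-level truth"
            )
        err = np.zeros(len(r), dtype=np.int8)
        if lab.error_positions:
            err[np.asarray(lab.error_positions)] = 1
        b_parts.extend((seq_to_ints(r.sequence), sep_b))
        e_parts.extend((err, sep_e))
    if not b_parts:
        return KmerCategories(k, np.empty(0, np.int64), np.empty(0, np.int8))
    b = np.concatenate(b_parts[:-1])
    e = np.concatenate(e_parts[:-1])
    cf, cr, base_ok = window_codes(b, k)
    has_err = window_min(-e, k) < 0
    canon = np.minimum(cf, cr)[base_ok]
    has_err = has_err[base_ok]
    codes, inverse = np.unique(canon, return_inverse=True)
    n_err = np.bincount(inverse, weights=has_err).astype(np.int64)
    n_tot = np.bincount(inverse).astype(np.int64)
    cats = np.full(codes.shape, MIXED, dtype=np.int8)
    cats[n_err == 0] = GOOD
    cats[n_err == n_tot] = BAD
    return KmerCategories(k, codes, cats)


def categorized_histogram(
    spectrum: KmerSpectrum, categories: KmerCategories
) -> CategorizedHistogram:
    """Split the spectrum's frequency histogram by k-mer category.

    Every spectrum key must appear in the categorization (it was observed
    in the same reads), so the three category histograms sum to the all
    histogram bin by bin.
    """
    cats = categories.category_of_codes(spectrum.codes)
    out = CategorizedHistogram()
    for name, bins in (
        ("all", out.bins_all),
        (GOOD, out.bins_good),
        (BAD, out.bins_bad),
        (MIXED, out.bins_mixed),
    ):
        sel = slice(None) if name == "all" else cats == name
        xs, cs = np.unique(spectrum.freqs[sel], return_counts=True)
        bins.update(zip(xs.tolist(), cs.tolist()))
    return out


def _smooth(c: np.ndarray, window: int = 3) -> np.ndarray:
    """Moving average with shrinking windows at the edges."""
    kernel = np.ones(window)
    num = np.convolve(c, kernel, mode="same")
    den = np.convolve(np.ones_like(c, dtype=float), kernel, mode="same")
    return num / den


def first_local_minimum(
    hist: KmerHistogram, smooth_window: int = 3
) -> int | None:
    """First dip of the frequency histogram (candidate C_E).

    The candidate is the first frequency x >= 2 where the 3-point smoothed
    count sequence stops falling and starts rising; it is then walked left
    over the raw counts while the value to the left is <= the current one,
    so a flat-bottomed dip resolves to its leftmost frequency. None when
    the sequence is monotone.
    """
    c = hist.dense().astype(float)
    if c.shape[0] < 4:
        return None
    s = _smooth(c[1:], smooth_window)  # index i -> frequency i+1
    cand = None
    for i in range(1, s.shape[0] - 1):
        if s[i] <= s[i - 1] and s[i] < s[i + 1]:
            cand = i + 1
            break
    if cand is None:
        return None
    raw = c
    x = cand
    while x > 2 and raw[x - 1] <= raw[x]:
        x -= 1
    return x


def crossover_threshold(cat_hist: CategorizedHistogram) -> int | None:
    """Smallest frequency where the good count reaches the bad count."""
    xs = sorted(cat_hist.bins_all)
    for x in xs:
        g = cat_hist.bins_good.get(x, 0)
        b = cat_hist.bins_bad.get(x, 0)
        if g + b > 0 and g >= b:
            return x
    return None


def assess_applicability(
    hist: KmerHistogram,
    k: int,
    genome_size_hint: float | None = None,
    mean_coverage_hint: float | None = None,
    cat_hist: CategorizedHistogram | None = None,
    quality_sample: Sequence[int] | np.ndarray | None = None,
) -> ApplicabilityReport:
    """Verdict on whether the k-spectrum shape supports the classifier.

    pattern_ok requires (a) a first local minimum, (b) counts beyond it
    rising to a peak and falling again, (c) the peak within a factor 2 of
    mean_coverage_hint when given, and (d) |G|/4^k <= 0.01 when a genome
    size is given. Suggested C_E is the dip; C_G is the 95% rule (largest
    c with >=95% of distinct k-mers at frequency >= c), clamped below C_E;
    Q_G/Q_E come from the quality sample when provided.
    """
    c = hist.dense()
    fmin = first_local_minimum(hist)
    peak = None
    pattern_ok = fmin is not None
    if fmin is not None and c.shape[0] > fmin + 1:
        s = _smooth(c[1:].astype(float))
        seg = s[fmin:]  # frequencies fmin+1 ...
        rel = int(np.argmax(seg))
        peak = fmin + 1 + rel
        rises = s[peak - 1] > s[fmin - 1]
        falls = peak < c.shape[0] - 1 and s[-1] < s[peak - 1]
        pattern_ok = bool(rises and falls)
    else:
        pattern_ok = False
    if pattern_ok and mean_coverage_hint is not None and peak is not None:
        ratio = peak / mean_coverage_hint
        pattern_ok = 0.5 <= ratio <= 2.0
    if pattern_ok and genome_size_hint is not None:
        pattern_ok = genome_size_hint / 4**k <= 0.01

    suggested: dict = {"C_E": fmin, "C_G": None, "Q_G": None, "Q_E": None}
    total = int(c.sum())
    if total:
        tail = c[::-1].cumsum()[::-1]  # tail[x] = # k-mers with f >= x
        frac = tail / total
        ok = np.nonzero(frac[1:] >= 0.95)[0]
        if ok.size:
            c_g = int(ok[-1]) + 1
            if fmin is not None:
                c_g = min(c_g, fmin - 1)  # classifier requires C_E > C_G
            suggested["C_G"] = max(c_g, 1)
    if quality_sample is not None:
        q_g, q_e = suggest_quality_thresholds(quality_sample)
        suggested["Q_G"], suggested["Q_E"] = q_g, q_e

    xover = crossover_threshold(cat_hist) if cat_hist is not None else fmin
    return ApplicabilityReport(
        pattern_ok=pattern_ok,
        first_minimum=fmin,
        crossover_threshold=xover,
        peak_frequency=peak,
        suggested=suggested,
    )


def auto_configure(
    reads: Sequence[ReadRecord],
    k: int = 24,
    d: int = 1,
    rule_level: int = 2,
    quality_sample_size: int = 200_000,
    seed: int = 0,
):
    """Data-driven parameter choice: (RuleConfig, KmerSpectrum).

    Q_G/Q_E come from the 80%/20% base-quality percentiles of a sample;
    the spectrum is then counted at Q_E and C_E is the first dip of its
    histogram (falling back to the published default 8 when the histogram
    is monotone), with C_G from the 95% rule clamped below C_E. The
    returned spectrum is the one the classifier should use.
    """
    from .kmer_spectrum import build_spectrum, histogram
    from .perfect_classifier import RuleConfig

    rng = np.random.default_rng(seed)
    all_q = np.concatenate([r.qualities for r in reads])
    if all_q.shape[0] > quality_sample_size:
        all_q = rng.choice(all_q, size=quality_sample_size, replace=False)
    q_g, q_e = suggest_quality_thresholds(all_q)
    if q_e <= q_g:
        # Q_E > Q_G required; bump Q_E unless that would exceed the maximum
        # observed quality (making no instance countable) - then lower Q_G.
        if q_e + 1 <= int(all_q.max()):
            q_e = q_g + 1
        else:
            q_g = q_e - 1
    spectrum = build_spectrum(reads, k=k, q_excellent=q_e)
    report = assess_applicability(histogram(spectrum), k)
    c_e = report.suggested["C_E"] or 8
    c_g = report.suggested["C_G"] or 1
    c_g = max(1, min(c_g, c_e - 1))
    cfg = RuleConfig.from_decoded(
        q_g=q_g, q_e=q_e, c_e=c_e, c_g=c_g, rule_level=rule_level, d=d
    )
    return cfg, spectrum


def suggest_quality_thresholds(
    sample: Sequence[int] | np.ndarray,
) -> tuple[int, int]:
    """(Q_G, Q_E): largest thresholds met by >=80% / >=20% of base qualities.

    Returned in the decoded unit of the sample; the two values coincide on
    degenerate quality distributions, and the classifier's Q_E > Q_G
    requirement is enforced downstream (see auto_configure).
    """
    q = np.sort(np.asarray(sample, dtype=np.int64))[::-1]
    n = q.shape[0]
    if n == 0:
        raise ValueError("empty quality sample")
    m_g = int(np.ceil(0.8 * n))
    m_e = int(np.ceil(0.2 * n))
    return int(q[m_g - 1]), int(q[m_e - 1])
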