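# Methods

## The model

`perfectread` predicts which reads in a high-coverage, substitution-only
Illumina dataset are *perfect* (error-free), using only the dataset's
k-spectrum — the multiset of all length-k substrings of the reads. A k-mer
is *valid* if it occurs in the sequenced genome; a read is perfect iff it
contains no invalid k-mer. Without a reference, validity is estimated from
frequency: at coverage c, a genomic k-mer is expected to occur ~c·(L−k+1)/L
times (L the read length), while a k-mer created by a sequencing error is
essentially unique, because a single substitution produces up to k novel
k-mers that almost surely occur nowhere else in a repeat-free genome
(|G|/4^k ≪ 1 at k = 24).

### Phase 1 — quality-filtered canonical counting

Every length-k window of every read is counted, but an instance contributes
only if all k of its bases have quality ≥ Q_E (*Excellent Quality*,
inclusive ≥ — the boundary value counts). A k-mer and its reverse
complement are merged under the lexicographically smaller of the two
(A < C < G < T). Windows containing N are never counted. The quality filter
is what couples the spectrum to the error process: when base-callers assign
low quality to unreliable bases, most error k-mers never enter the
spectrum at all, which is far stronger evidence than a frequency threshold
alone.

Internally k-mers are 2-bit codes in sorted int64 arrays; windows are
extracted for a whole dataset at once with vectorized shifts, so counting
10 Mbp takes a few seconds. The public `counts` mapping (string → f) is a
lazily materialized view.

### Hamming neighborhood

Rules 3–5 ask whether a k-mer has close variants in the spectrum. The
`HammingIndex` answers "all stored k-mers within Hamming distance ≤ d of
T" exactly, by XOR-enumerating every ≤ d-substitution variant of the query
code (3k variants at d = 1, plus 9·C(k,2) at d = 2) and testing membership
in the sorted code array. Nothing is materialized; query results are
memoized. Distance is computed between canonical representations only —
no strand-aware minimum — and queries are canonicalized before lookup.
This is declared (and property-tested) rather than inherited from any
particular graph layout.

### Phase 2 — the read scan

A read is scanned at k-mer start offsets 0, k/2, k, … ; when a further
k/2 stride would leave fewer than a full window before the read end, the
scan jumps to the final window |r|−k. Consecutive windows overlap by k/2,
so every base is covered by at least one visited window while only ~2|r|/k
lookups are spent per read. The read is Erroneous at the first invalid
window, Perfect if all pass. A window is valid under Rule i if it
satisfies any one of P1..Pi:

- **P1** f(T) ≥ C_E — high frequency alone.
- **P2** f(T) ≥ C_G and every base of this window instance has quality ≥ Q_G.
- **P3** f(T) ≥ C_G and no neighbor T′ has f(T′) ≥ C_G.
- **P4** f(T) ≥ C_G and no neighbor T′ has f(T′) ≥ f(T)·F_H.
- **P5** f(T) ≥ C_G and for every neighbor T′, each position where T
  differs from T′ has instance quality ≥ Q_G.

Properties short-circuit in order. Rules are nested by construction, so
relaxing the level can only grow the predicted-perfect set — the
monotonicity the tests assert. A k-mer containing N, or absent from the
spectrum, has f = 0 and fails everything. P2/P5 use the qualities of the
instance in the read being classified (the only qualities available at
classification time). For P5, positions are mapped through the
canonical-strand flip: when the stored key is the reverse complement of
the window, canonical index i corresponds to instance position k−1−i.

Reads shorter than k are undefined under the scan; they are routed to the
erroneous stream and tallied separately (`n_short`), with a configurable
hard-error mode.

### Parameters

| name | meaning | default | unit |
|------|---------|---------|------|
| k    | k-mer length (even, so k/2 strides are whole) | 24 | bp |
| C_E  | excellent count: trust outright | 8 | occurrences |
| C_G  | good count: minimum evidence (C_E > C_G) | 1 | occurrences |
| Q_G  | good quality, used by P2/P5 | 45 | raw ASCII |
| Q_E  | excellent quality, used in counting (Q_E > Q_G) | 73 | raw ASCII |
| F_H  | neighbor-frequency factor for P4 (> 1) | 2 | — |
| d    | Hamming neighbor distance | 1 | substitutions |
| rule_level | classification stringency (1 strictest) | 2 | — |

Quality thresholds are interpreted as **raw ASCII codes** of the quality
characters by default (`quality_unit="ascii"`), because the defaults above
lie far outside any Phred scale: with the usual Phred+33 encoding, ASCII 73
is Phred 40 and ASCII 45 is Phred 12. `quality_unit="phred"` (or
`RuleConfig.from_decoded`) accepts decoded values directly.

### Data-driven parameter suggestion

`auto_configure` operationalizes the histogram heuristics:

- Q_G / Q_E: the largest thresholds met by ≥ 80% / ≥ 20% of sampled base
  qualities. The raw percentiles may coincide on degenerate distributions;
  since the classifier requires Q_E > Q_G, Q_E is bumped to Q_G+1 — unless
  that exceeds the maximum observed quality (which would leave no countable
  instance), in which case Q_G is lowered to Q_E−1 instead.
- C_E: the first local minimum of the frequency histogram **of the spectrum
  actually used for classification** (counted at Q_E). The dip is found on a
  3-point moving-average of the counts to suppress shot noise, then walked
  left over the raw counts while the left value is ≤ the current one, so a
  flat-bottomed dip resolves deterministically to its leftmost frequency.
  Fallback when the histogram is monotone: the default 8.
- C_G: the largest c such that ≥ 95% of distinct k-mers have f ≥ c. On
  strongly quality-filtered spectra the f = 1 error mass is small and this
  rule can exceed C_E; it is clamped to min(value, C_E−1) to preserve
  C_E > C_G.

### Applicability diagnostics

With ground truth, each k-mer is *good* (all its window occurrences are
error-free), *bad* (all erroneous) or *mixed*; an occurrence is erroneous
iff its window overlaps an error offset of its read. The category
histograms sum to the all-k-mer histogram bin by bin (tested). The
`pattern_ok` verdict uses only the all curve: a first minimum must exist,
counts beyond it must rise to a peak and fall again, the peak must lie
within a factor 2 of the coverage hint when given, and |G|/4^k ≤ 0.01 when
a genome size is given. The factor 2, the 0.01, and the smoothing window
are this package's choices — the qualitative shape criterion itself does
not fix them. The crossover threshold is the smallest frequency where the
good count reaches the bad count (falling back to the first minimum
without truth).

### Corrector

The corrector exists to demonstrate one contrast, not to compete as an
error-correction engine: trusted k-mers (f ≥ C_E) can be counted from
**all reads** or from **predicted-perfect reads only**, in which case only
predicted-erroneous reads are corrected. It is a deliberately simple
greedy engine: walk the classification schedule; for an untrusted window,
collect trusted neighbors within distance d, substitute the unique
highest-frequency one (lexicographic tie-break, or skip on ties),
preserving qualities. The substituted window is trusted by construction,
so the scan simply proceeds. By default the correction spectrum is counted
*without* the Q_E filter (plain count-threshold trust, as conventional
k-spectrum correctors use); this keeps the perfect-read filtering itself
as the only difference between the two modes. Gain/EBA from this engine
characterize the contrast on synthetic data only and are not comparable to
any published corrector's absolute numbers.

## The synthetic data generator

The generator emulates exactly the regime the method assumes: a single
haploid i.i.d. (hence essentially repeat-free) genome, uniform sampling
from both strands, fixed read length, substitution errors only. Defaults —
200 kb genome, 50× coverage, 100 bp reads, 0.5% mean per-base error — give
a truth perfect-read fraction of 0.995^100 ≈ 0.61; an error rate of 0.22%
gives ≈ 0.80. These are the study conditions used throughout the tests and
the acceptance script; they sit inside the published datasets' ranges
(75–101 bp, 43–1000×, 0.13–0.72% error) while staying desk-sized.

Quality models tie errors to qualities the way the method expects real
base-callers to: the default `two_level` model assigns each base q = 40
with high probability or q = 10 otherwise, with per-base error probability
10^(−q/10) rescaled so the marginal error rate equals `error_rate` exactly
(so the low-quality fraction, ~4.9% at 0.5% error, carries almost all
errors). `phred_linked` draws from a multi-tier Illumina-like profile and
calibrates the same way; `uniform` gives constant quality with
quality-independent errors — a deliberate control in which quality carries
no information. Qualities are i.i.d. per base; real Illumina data instead
shows position-dependent quality decay, run-length correlation, optical
duplicates and (rarely) indels, none of which is modeled. Passing tests
therefore show that the algorithm behaves as designed when its assumptions
hold, not that it attains the same numbers on any particular real dataset.

## Numerical and design choices

- "Exceeds a quality threshold" is implemented as inclusive ≥, so
  published boundary parameters are usable as printed.
- Counting enumerates every window position; the k/2 stride applies only
  to classification.
- Read-level and base-level metrics (Sp, Sn, Pr, Gain, EBA) return None on
  zero denominators rather than 0; Gain may be negative.
- Table comparisons in tests round half-even to the printed precision.
- Seeds: the genome and the read sampler use disjoint spawned streams of
  one user seed; identical configs are byte-identical on disk.
- SAM-derived truth labels mark a read perfect iff it is aligned, primary,
  MAPQ > 0, full-length match CIGAR, and NM = 0 when present; such labels
  carry no error positions (error_positions = None) and cannot feed the
  good/bad/mixed categorization, which needs position-level truth.

## Problem sizes

Unit tests run on toy universes (≤ 2000 8-mers) and small genomes
(5–50 kb); the end-to-end checks use the 200 kb / 50× / 100 bp study
condition (100 000 reads, ~10 Mbp), where spectrum construction and
classification each take a few seconds on one core. The acceptance script
runs two such datasets plus both corrector modes in about one minute.

## Known limitations

- Substitution-only: indels shift frames and are out of scope end to end.
- The classifier's FP floor is structural: an error at a high-quality base
  whose k-mers pass P2 with f ≥ C_G is indistinguishable from signal at
  C_G = 1; the published results show the same effect.
- The Hamming index is exact but enumerative; d > 2 works yet costs
  O(C(k,d)·3^d) per query.
- The corrector makes at most d substitutions per visited window and does
  not revisit earlier windows after a fix.
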