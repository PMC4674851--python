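"""Perfect-read-informed substitution error correction.

A deliberately simple greedy k-spectrum corrector: walk the same k-mer
schedule as the classifier; wherever the current k-mer is untrusted,
substitute the unique best trusted Hamming neighbor (within distance d)
into the read. Its purpose is the contrast between two trusted-spectrum
sources: ``all_reads`` (count every read — the conventional baseline) and
``perfect_only`` (count only reads the classifier predicts error-free, and
correct only the reads predicted erroneous).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from ._encode import canonical_code, revcomp_code, seq_to_ints, codes_to_strings
from .fastq_io import ReadRecord
from .hamming_index import HammingIndex, build_index
from .kmer_spectrum import KmerSpectrum, build_spectrum
from .perfect_classifier import RuleConfig, filter_dataset, kmer_positions
from .evaluation import BaseCorrectionCounts, base_metrics, evaluate_correction

__all__ = ["CorrectionPolicy", "correct_read", "run_correction_pipeline"]


@dataclass
class CorrectionPolicy:
    """How the trusted spectrum is built and substitutions are chosen.

    ``count_q_excellent=None`` counts every k-mer instance regardless of
    quality (plain count-threshold trust, as in conventional k-spectrum
    correctors); an integer applies the usual excellent-quality filter.
    A k-mer is trusted iff f >= validity.c_e.
    """

    source: Literal["all_reads", "perfect_only"] = "perfect_only"
    max_changes_per_kmer: int = 1
    tie_break: Literal["highest_frequency", "skip"] = "highest_frequency"
    validity: RuleConfig = field(default_factory=RuleConfig)
    count_q_excellent: int | None = None


def _decode_codes(codes, k):
    return codes_to_strings(np.asarray(codes, np.int64), k)


def correct_read(
    read: ReadRecord,
    spectrum: KmerSpectrum,
    index: HammingIndex,
    policy: CorrectionPolicy,
) -> tuple[ReadRecord, int]:
    """Greedy per-k-mer correction; qualities are preserved.

    For each scheduled window whose canonical k-mer has f < C_E, trusted
    neighbors within distance d (and <= max_changes_per_kmer substitutions)
    are collected; the highest-frequency one (lexicographic tie-break, or
    no change under tie_break='skip') replaces the differing bases, and the
    scan resumes at the same window. Uncorrectable windows pass through.
    """
    k = spectrum.k
    c_e = policy.validity.c_e
    if len(read) < k:
        return read, 0
    b = seq_to_ints(read.sequence).copy()
    if (b == -2).any():
        raise ValueError(f"read {read.read_id!r}: invalid character")
    n_changed = 0
    for p in kmer_positions(len(read), k):
        window = b[p : p + k]
        if (window < 0).any():
            continue  # windows with N are left alone
        code = 0
        for v in window:
            code = (code << 2) | int(v)
        canon, flipped = canonical_code(code, k)
        if spectrum.f_code(canon) >= c_e:
            continue
        ncodes, nfreqs = index.neighbor_codes(canon)
        trusted = nfreqs >= c_e
        ncodes, nfreqs = ncodes[trusted], nfreqs[trusted]
        if policy.max_changes_per_kmer < index.d and ncodes.size:
            hd = np.array(
                [_hamming(canon, int(nc), k) for nc in ncodes], dtype=np.int64
            )
            keep = hd <= policy.max_changes_per_kmer
            ncodes, nfreqs = ncodes[keep], nfreqs[keep]
        if ncodes.size == 0:
            continue
        best = int(nfreqs.max())
        cand = ncodes[nfreqs == best]
        if cand.size > 1 and policy.tie_break == "skip":
            continue
        target = int(cand.min())  # deterministic lexicographic tie-break
        # Place the neighbor back in read orientation.
        frame = revcomp_code(target, k) if flipped else target
        for j in range(k):
            nb = (frame >> (2 * (k - 1 - j))) & 3
            if nb != int(window[j]):
                window[j] = nb
                n_changed += 1
    if n_changed == 0:
        return read, 0
    seq = "".join("ACGT"[int(v)] if v >= 0 else "N" for v in b)
    return replace(read, sequence=seq), n_changed


def _hamming(a: int, b: int, k: int) -> int:
    x = a ^ b
    d = 0
    while x:
        if x & 3:
            d += 1
        x >>= 2
    return d


def run_correction_pipeline(
    reads: Sequence[ReadRecord],
    cfg: RuleConfig,
    policy: CorrectionPolicy,
    truth_sequences: Sequence[str] | Sequence[ReadRecord] | None = None,
    k: int = 24,
) -> tuple[list[ReadRecord], BaseCorrectionCounts | None, dict]:
    """Classify, build the trusted spectrum per policy, correct, evaluate.

    perfect_only: the spectrum is counted from predicted-perfect reads and
    only predicted-erroneous reads are corrected. all_reads: the spectrum
    is counted from, and correction applied to, every read. Output
    preserves input order and read count.
    """
    reads = list(reads)
    summary: dict = {"mode": policy.source, "n_input": len(reads)}
    if not reads:
        return [], None, summary

    if policy.source == "perfect_only":
        # Phase 1: predict perfect reads with the full classifier.
        class_spec = build_spectrum(reads, k=k, q_excellent=cfg.q_e_decoded)
        class_index = build_index(class_spec, cfg.d) if cfg.rule_level >= 3 else None
        perfect, erroneous, fsum = filter_dataset(reads, class_spec, class_index, cfg)
        count_source = perfect
        to_correct = {id(r) for r in erroneous}
        summary["n_predicted_perfect"] = fsum.n_perfect
        summary["n_predicted_erroneous"] = fsum.n_erroneous + fsum.n_short
    else:
        count_source = reads
        to_correct = {id(r) for r in reads}

    q_count = policy.count_q_excellent if policy.count_q_excellent is not None else 0
    spectrum = build_spectrum(count_source, k=k, q_excellent=q_count)
    index = build_index(spectrum, policy.validity.d)

    corrected: list[ReadRecord] = []
    n_bases = 0
    n_reads_changed = 0
    for r in reads:
        if id(r) in to_correct:
            new, nc = correct_read(r, spectrum, index, policy)
            corrected.append(new)
            if nc:
                n_bases += nc
                n_reads_changed += 1
        else:
            corrected.append(r)
    summary["n_bases_changed"] = n_bases
    summary["n_reads_changed"] = n_reads_changed

    counts = None
    if truth_sequences is not None:
        counts = evaluate_correction(reads, corrected, truth_sequences)
        summary["metrics"] = base_metrics(counts)
    return corrected, counts, summary
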