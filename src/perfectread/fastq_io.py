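"""FASTQ input/output and SAM-derived ground-truth labels.

Quality values are stored decoded: ``q = ASCII(code) - quality_offset``.
``quality_offset=0`` keeps the raw ASCII codes, which is the unit the
classifier's published quality thresholds (Q_G=45, Q_E=71/73) are written
in; offsets 33 and 64 give the usual Phred scales.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pysam
from Bio import SeqIO


class FastqParseError(ValueError):
    """Malformed FASTQ record (names the failing record index)."""


@dataclass
class ReadRecord:
    """One sequencing read: id, bases over {A,C,G,T,N}, decoded qualities."""

    read_id: str
    sequence: str
    qualities: np.ndarray
    mate_info: str | None = None

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"read {self.read_id!r}: sequence length {len(self.sequence)} "
                f"!= quality length {len(self.qualities)}"
            )
        if len(self.qualities) and self.qualities.min() < 0:
            raise ValueError(f"read {self.read_id!r}: negative quality value")

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReadRecord):
            return NotImplemented
        return (
            self.read_id == other.read_id
            and self.sequence == other.sequence
            and np.array_equal(self.qualities, other.qualities)
            and self.mate_info == other.mate_info
        )


@dataclass
class GroundTruthLabel:
    """Truth for one read: perfect iff it carries no substitution errors.

    ``error_positions`` holds 0-based read offsets; ``None`` means the
    positions are unknown (e.g. labels derived from an aligner's edit
    distance alone). A perfect read always has an empty position list.
    """

    read_id: str
    is_perfect: bool
    error_positions: list[int] | None = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.is_perfect and self.error_positions != []:
            raise ValueError(
                f"read {self.read_id!r}: perfect read must have no error positions"
            )
        if not self.is_perfect and self.error_positions == []:
            raise ValueError(
                f"read {self.read_id!r}: erroneous read needs error positions "
                "(or None if unknown)"
            )


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path, quality_offset: int = 33) -> Iterator[ReadRecord]:
    """Stream records from a 4-line FASTQ file (gzip accepted).

    Qualities are decoded as ``ASCII - quality_offset``; offset 0 yields raw
    ASCII codes. Malformed records raise FastqParseError naming the record
    index.
    """
    if quality_offset not in (0, 33, 64):
        raise ValueError("quality_offset must be one of 0, 33, 64")
    index = 0
    with _open_text(path) as handle:
        # Biopython validates structure and decodes at offset 33; re-shift.
        shift = 33 - quality_offset
        try:
            for rec in SeqIO.parse(handle, "fastq"):
                quals = np.asarray(
                    rec.letter_annotations["phred_quality"], dtype=np.int16
                ) + shift
                yield ReadRecord(rec.id, str(rec.seq).upper(), quals)
                index += 1
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ record #{index}: {exc}") from exc


def write_fastq(records: Iterable[ReadRecord], path, quality_offset: int = 33) -> int:
    """Write 4-line FASTQ; returns the number of records written.

    Written directly (not via Biopython) so that offset 0 / raw-ASCII
    round-trips exactly: quality char = chr(q + quality_offset).
    """
    if quality_offset not in (0, 33, 64):
        raise ValueError("quality_offset must be one of 0, 33, 64")
    n = 0
    with _open_text(path, "wt") as out:
        for rec in records:
            qual = "".join(chr(int(q) + quality_offset) for q in rec.qualities)
            out.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")
            n += 1
    return n


_MATCH_OPS = {0, 7}  # CIGAR M, =
_CLIP_INDEL_OPS = {1, 2, 3, 4, 5}  # I, D, N, S, H


def labels_from_sam(path) -> dict[str, GroundTruthLabel]:
    """Derive perfect/not-perfect labels from a SAM alignment.

    A read is perfect iff it is aligned (not unmapped, not secondary or
    supplementary, not multi-mapped with MAPQ 0), its CIGAR consists solely
    of match operations spanning the full read, and its edit-distance (NM)
    tag, when present, is 0. Aligned records without a CIGAR are skipped
    with a warning count.
    """
    labels: dict[str, GroundTruthLabel] = {}
    n_skipped = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_secondary or aln.is_supplementary:
                continue
            perfect = False
            if not aln.is_unmapped:
                if aln.cigartuples is None:
                    n_skipped += 1
                    continue
                ambiguous = aln.mapping_quality == 0
                ops = {op for op, _ in aln.cigartuples}
                full_match = (
                    ops <= _MATCH_OPS
                    and sum(ln for op, ln in aln.cigartuples if op in _MATCH_OPS)
                    == aln.query_length
                )
                nm_zero = (not aln.has_tag("NM")) or aln.get_tag("NM") == 0
                perfect = full_match and nm_zero and not ambiguous
            labels[aln.query_name] = GroundTruthLabel(
                aln.query_name, perfect, [] if perfect else None
            )
    if n_skipped:
        import warnings

        warnings.warn(f"{n_skipped} aligned record(s) without CIGAR skipped")
    return labels


def write_truth_tsv(labels: Iterable[GroundTruthLabel], path) -> int:
    """Truth table TSV: read_id <tab> is_perfect <tab> comma-joined offsets."""
    n = 0
    with _open_text(path, "wt") as out:
        for lab in labels:
            pos = ",".join(str(p) for p in lab.error_positions or [])
            out.write(f"{lab.read_id}\t{int(lab.is_perfect)}\t{pos}\n")
            n += 1
    return n


def read_truth_tsv(path) -> dict[str, GroundTruthLabel]:
    labels: dict[str, GroundTruthLabel] = {}
    with _open_text(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            read_id, flag, pos = line.split("\t")
            perfect = flag == "1"
            if pos:
                positions: list[int] | None = [int(p) for p in pos.split(",")]
            else:
                positions = [] if perfect else None
            labels[read_id] = GroundTruthLabel(read_id, perfect, positions)
    return labels
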