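"""Synthetic haploid genome + short reads with quality-linked errors.

Emulates the regime the classifier assumes: a single repeat-free genome
sampled uniformly at high coverage by fixed-length reads carrying only
substitution errors. Quality models:

  uniform(q)             every base quality q; errors i.i.d. at error_rate
                         (quality carries no information — a control).
  two_level(q_hi, q_lo)  each base independently q_lo with probability
                         p_lo, else q_hi; the per-base error probability is
                         10^(-q/10), so errors concentrate at low-quality
                         bases. When p_lo is None it is derived so the
                         marginal per-base error probability equals
                         error_rate exactly.
  phred_linked           per-base quality drawn from an Illumina-like
                         discrete profile (mass concentrated at the cap),
                         error probability 10^(-q/10); the profile is mixed
                         toward q=10 (or toward all-cap) so the marginal
                         error probability matches error_rate.

Error-free reads match the genome exactly on their source strand; truth
records 0-based error offsets in the read frame (after reverse
complementing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .fastq_io import GroundTruthLabel, ReadRecord

__all__ = [
    "QualityModel",
    "SyntheticConfig",
    "SyntheticDataset",
    "generate_genome",
    "generate_reads",
    "make_dataset",
]

_ACGT = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class QualityModel:
    kind: str = "two_level"  # uniform | two_level | phred_linked
    q: int = 40  # uniform level
    q_hi: int = 40
    q_lo: int = 10
    p_lo: float | None = None  # None: derive from error_rate
    profile: dict[int, float] = field(
        default_factory=lambda: {
            40: 0.30, 38: 0.25, 35: 0.20, 30: 0.12, 25: 0.06,
            20: 0.03, 15: 0.02, 10: 0.02,
        }
    )

    @staticmethod
    def uniform(q: int = 40) -> "QualityModel":
        return QualityModel(kind="uniform", q=q)

    @staticmethod
    def two_level(q_hi: int = 40, q_lo: int = 10, p_lo: float | None = None) -> "QualityModel":
        return QualityModel(kind="two_level", q_hi=q_hi, q_lo=q_lo, p_lo=p_lo)

    @staticmethod
    def phred_linked() -> "QualityModel":
        return QualityModel(kind="phred_linked")


@dataclass
class SyntheticConfig:
    genome_length: int = 200_000
    gc_content: float = 0.5
    read_length: int = 100
    mean_coverage: float = 50.0
    error_rate: float = 0.005
    quality_model: QualityModel = field(default_factory=QualityModel)
    seed: int = 0
    strand_fraction: float = 0.5
    # tandem duplications planted in the genome to stress the neighbor
    # rules (P3/P4) with genuinely repeated k-mers; 0 = repeat-free
    n_repeats: int = 0
    repeat_length: int = 500

    def __post_init__(self) -> None:
        if not 0 <= self.error_rate <= 0.1:
            raise ValueError("error_rate must be in [0, 0.1]")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must be in [0, 1]")


@dataclass
class SyntheticDataset:
    genome: str
    reads: list[ReadRecord]
    truth: dict[str, GroundTruthLabel]
    truth_sequences: list[str]  # error-free version of each read, same order
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    reverse: np.ndarray = field(default_factory=lambda: np.empty(0, bool))


def _phred_err(q) -> np.ndarray | float:
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


def generate_genome(cfg: SyntheticConfig) -> str:
    """I.i.d. genome with P(G)+P(C)=gc_content split evenly; seeded."""
    rng = np.random.default_rng([cfg.seed, 0])
    at = (1 - cfg.gc_content) / 2
    gc = cfg.gc_content / 2
    bases = rng.choice(4, size=cfg.genome_length, p=[at, gc, gc, at])
    for _ in range(cfg.n_repeats):
        # tandem duplication: the segment overwrites the stretch after it
        L = min(cfg.repeat_length, cfg.genome_length // 2)
        start = int(rng.integers(0, cfg.genome_length - 2 * L + 1))
        bases[start + L : start + 2 * L] = bases[start : start + L]
    return _ACGT[bases].tobytes().decode("ascii")


def _qualities_and_error_prob(
    cfg: SyntheticConfig, rng: np.random.Generator, shape: tuple[int, ...]
) -> tuple[np.ndarray, np.ndarray]:
    qm = cfg.quality_model
    if qm.kind == "uniform":
        q = np.full(shape, qm.q, dtype=np.int16)
        return q, np.full(shape, cfg.error_rate)
    if qm.kind == "two_level":
        e_hi, e_lo = _phred_err(qm.q_hi), _phred_err(qm.q_lo)
        p_lo = qm.p_lo
        derived = p_lo is None
        if derived:
            p_lo = float(np.clip((cfg.error_rate - e_hi) / (e_lo - e_hi), 0.0, 1.0))
        low = rng.random(shape) < p_lo
        q = np.where(low, qm.q_lo, qm.q_hi).astype(np.int16)
        err = _phred_err(q)
        if derived:
            # exact calibration: marginal per-base error prob == error_rate
            mean = p_lo * e_lo + (1 - p_lo) * e_hi
            err = err * (cfg.error_rate / mean if mean > 0 else 0.0)
        return q, err
    if qm.kind == "phred_linked":
        levels = np.array(sorted(qm.profile), dtype=np.int16)
        probs = np.array([qm.profile[int(l)] for l in levels])
        probs = probs / probs.sum()
        mean_err = float((_phred_err(levels) * probs).sum())
        e_lo, e_cap = _phred_err(10), _phred_err(levels.max())
        if cfg.error_rate >= mean_err:
            # mix toward an all-q10 component
            lam = float(np.clip((cfg.error_rate - mean_err) / (e_lo - mean_err), 0, 1))
            probs = (1 - lam) * probs
            probs[levels == 10] += lam
        else:
            # mix toward an all-cap component
            lam = float(np.clip((mean_err - cfg.error_rate) / (mean_err - e_cap), 0, 1))
            probs = (1 - lam) * probs
            probs[levels == levels.max()] += lam
        q = rng.choice(levels, size=shape, p=probs).astype(np.int16)
        err = _phred_err(q)
        mean = float((_phred_err(levels) * probs).sum())
        err = err * (cfg.error_rate / mean if mean > 0 else 0.0)
        return q, err
    raise ValueError(f"unknown quality model {qm.kind!r}")


def generate_reads(genome: str, cfg: SyntheticConfig) -> SyntheticDataset:
    """Sample reads uniformly from both strands and inject errors.

    n_reads = round(mean_coverage * genome_length / read_length); the
    substituted base is one of the three alternatives, uniformly.
    """
    if cfg.read_length > len(genome):
        raise ValueError("read_length exceeds genome length")
    rng = np.random.default_rng([cfg.seed, 1])
    g = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    g = lut[g]
    n_reads = int(round(cfg.mean_coverage * len(genome) / cfg.read_length))
    rl = cfg.read_length
    starts = rng.integers(0, len(genome) - rl + 1, size=n_reads)
    reverse = rng.random(n_reads) < cfg.strand_fraction
    mat = g[starts[:, None] + np.arange(rl)[None, :]].astype(np.int8)
    mat[reverse] = 3 - mat[reverse][:, ::-1]  # reverse complement extraction

    quals, err_p = _qualities_and_error_prob(cfg, rng, mat.shape)
    errs = rng.random(mat.shape) < err_p
    shift = rng.integers(1, 4, size=mat.shape, dtype=np.int8)
    truth_mat = mat.copy()
    mat[errs] = (mat[errs] + shift[errs]) % 4

    seq_bytes = _ACGT[mat]
    truth_bytes = _ACGT[truth_mat]
    reads: list[ReadRecord] = []
    truth: dict[str, GroundTruthLabel] = {}
    truth_sequences: list[str] = []
    err_rows = [np.nonzero(errs[i])[0] for i in range(n_reads)]
    for i in range(n_reads):
        rid = f"r{i}"
        seq = seq_bytes[i].tobytes().decode("ascii")
        reads.append(ReadRecord(rid, seq, quals[i]))
        pos = err_rows[i].tolist()
        truth[rid] = GroundTruthLabel(rid, len(pos) == 0, pos)
        truth_sequences.append(truth_bytes[i].tobytes().decode("ascii"))
    return SyntheticDataset(
        genome, reads, truth, truth_sequences, starts.astype(np.int64), reverse
    )


def make_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Genome + reads in one call, fully determined by cfg (incl. seed)."""
    return generate_reads(generate_genome(cfg), cfg)


def coverage_per_window(dataset: SyntheticDataset, window: int = 1000) -> np.ndarray:
    """Mean per-base coverage in consecutive genome windows (simple report)."""
    glen = len(dataset.genome)
    lengths = np.array([len(r) for r in dataset.reads], dtype=np.int64)
    diff = np.zeros(glen + 1, dtype=np.int64)
    np.add.at(diff, dataset.starts, 1)
    np.add.at(diff, np.minimum(dataset.starts + lengths, glen), -1)
    depth = np.cumsum(diff[:-1])
    n_win = glen // window
    return depth[: n_win * window].reshape(n_win, window).mean(axis=1)
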