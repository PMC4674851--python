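import numpy as np
import pytest

from perfectread import (
    ReadRecord,
    SyntheticConfig,
    build_index,
    make_dataset,
)
from perfectread.spectrum_diagnostics import auto_configure


def make_reads(seqs, quality=40):
    """Uniform-quality ReadRecords from plain strings."""
    return [
        ReadRecord(f"r{i}", s, np.full(len(s), quality, dtype=np.int16))
        for i, s in enumerate(seqs)
    ]


@pytest.fixture(scope="session")
def study_dataset():
    """The standard synthetic study condition: 200 kb haploid genome,
    50x coverage, 100 bp reads, 0.5% mean substitution error tied to
    two-level base qualities."""
    cfg = SyntheticConfig(
        genome_length=200_000,
        mean_coverage=50,
        read_length=100,
        error_rate=0.005,
        seed=11,
    )
    return make_dataset(cfg)


@pytest.fixture(scope="session")
def study_autoconfig(study_dataset):
    """Data-driven RuleConfig and the quality-filtered spectrum it uses."""
    return auto_configure(study_dataset.reads, k=24)


@pytest.fixture(scope="session")
def study_index(study_autoconfig):
    cfg, spectrum = study_autoconfig
    return build_index(spectrum, cfg.d)


@pytest.fixture(scope="session")
def small_dataset():
    """A small, fast dataset for unit-level pipeline checks."""
    cfg = SyntheticConfig(
        genome_length=20_000,
        mean_coverage=40,
        read_length=100,
        error_rate=0.005,
        seed=5,
    )
    return make_dataset(cfg)
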