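import numpy as np
import pytest

from perfectread import (
    GroundTruthLabel,
    KmerHistogram,
    ReadRecord,
    assess_applicability,
    build_spectrum,
    categorize_kmers,
    categorized_histogram,
    crossover_threshold,
    first_local_minimum,
    histogram,
    suggest_quality_thresholds,
)
from perfectread.spectrum_diagnostics import auto_configure

from conftest import make_reads


class TestCategorize:
    def test_good_bad_mixed_definitions(self):
        # k=4: an occurrence is erroneous iff its window overlaps an error
        # offset of its read; occurrences pool over canonical identity.
        reads = make_reads(["ACGTACGT", "ACTTACGT", "ACGTACGT"])
        truth = {
            "r0": GroundTruthLabel("r0", True, []),
            "r1": GroundTruthLabel("r1", False, [2]),
            "r2": GroundTruthLabel("r2", False, [0]),
        }
        cats = categorize_kmers(reads, truth, 4)
        assert cats["ACTT"] == "bad"  # every occurrence overlaps an error
        assert cats["TACG"] == "good"  # all windows avoid the error offsets
        assert cats["GTAC"] == "good"
        assert cats["ACGT"] == "mixed"  # erroneous at r2[0:4], error-free elsewhere

    def test_missing_truth_raises(self):
        reads = make_reads(["ACGTACGT"])
        with pytest.raises(KeyError):
            categorize_kmers(reads, {}, 4)

    def test_unknown_positions_rejected(self):
        reads = make_reads(["ACGTACGT"])
        truth = {"r0": GroundTruthLabel("r0", False, None)}
        with pytest.raises(ValueError):
            categorize_kmers(reads, truth, 4)


def test_categorized_histogram_conserves(small_dataset):
    spec = build_spectrum(small_dataset.reads, k=24, q_excellent=0)
    cats = categorize_kmers(small_dataset.reads, small_dataset.truth, 24)
    ch = categorized_histogram(spec, cats)
    assert set(ch.bins_all) >= set(ch.bins_good)
    for x, n in ch.bins_all.items():
        assert n == (
            ch.bins_good.get(x, 0) + ch.bins_bad.get(x, 0) + ch.bins_mixed.get(x, 0)
        )
    assert sum(ch.bins_all.values()) == spec.n_distinct


class TestFirstLocalMinimum:
    def test_clear_dip(self):
        h = KmerHistogram({1: 1000, 2: 400, 3: 120, 4: 60, 5: 80, 6: 150})
        assert first_local_minimum(h) == 4

    def test_monotone_decreasing_has_none(self):
        h = KmerHistogram({1: 100, 2: 60, 3: 30, 4: 10, 5: 2})
        assert first_local_minimum(h) is None

    def test_plateau_resolves_leftmost(self):
        h = KmerHistogram({1: 10, 2: 5, 3: 5, 4: 9})
        assert first_local_minimum(h) == 2


def test_crossover_threshold_good_reaches_bad():
    from perfectread.spectrum_diagnostics import CategorizedHistogram

    ch = CategorizedHistogram(
        bins_all={1: 105, 2: 22, 3: 10, 4: 40},
        bins_good={1: 5, 2: 2, 3: 8, 4: 40},
        bins_bad={1: 100, 2: 20, 3: 2, 4: 0},
        bins_mixed={},
    )
    assert crossover_threshold(ch) == 3


class TestAssessApplicability:
    def test_expected_pattern_detected(self, study_dataset):
        spec = build_spectrum(study_dataset.reads, k=24, q_excellent=0)
        rep = assess_applicability(
            histogram(spec),
            24,
            genome_size_hint=len(study_dataset.genome),
            mean_coverage_hint=50,
        )
        assert rep.pattern_ok
        assert rep.first_minimum is not None
        assert 25 <= rep.peak_frequency <= 100

    def test_monotone_histogram_not_applicable(self):
        h = KmerHistogram({1: 1000, 2: 300, 3: 90, 4: 30, 5: 9})
        rep = assess_applicability(h, 24)
        assert not rep.pattern_ok
        assert rep.first_minimum is None

    def test_peak_far_from_coverage_hint_fails(self):
        h = KmerHistogram({1: 1000, 2: 100, 3: 40, 4: 60, 5: 300, 6: 500, 7: 300, 8: 60, 9: 5})
        assert assess_applicability(h, 24).pattern_ok
        assert not assess_applicability(h, 24, mean_coverage_hint=50).pattern_ok

    def test_repeat_heavy_genome_hint_fails(self):
        h = KmerHistogram({1: 1000, 2: 100, 3: 40, 4: 60, 5: 300, 6: 500, 7: 300, 8: 60, 9: 5})
        assert not assess_applicability(h, 4, genome_size_hint=1e9).pattern_ok

    def test_95_percent_rule_for_c_g(self):
        h = KmerHistogram({1: 4, 2: 96})
        rep = assess_applicability(h, 24)
        assert rep.suggested["C_G"] == 2


class TestQualityThresholds:
    def test_degenerate_distribution(self):
        q_g, q_e = suggest_quality_thresholds(np.full(100, 40))
        assert q_g == q_e == 40

    def test_single_base_sample(self):
        assert suggest_quality_thresholds([27]) == (27, 27)

    def test_uniform_range_order_statistics(self):
        sample = np.repeat(np.arange(10, 41), 50)
        assert suggest_quality_thresholds(sample) == (16, 34)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            suggest_quality_thresholds([])


def test_auto_configure_enforces_threshold_order(small_dataset):
    cfg, spec = auto_configure(small_dataset.reads, k=24)
    assert cfg.q_e_decoded > cfg.q_g_decoded
    assert cfg.c_e > cfg.c_g >= 1
    assert spec.q_excellent == cfg.q_e_decoded
    assert spec.n_instances_counted > 0


def test_crossover_separates_good_and_bad(study_dataset):
    """On data following the expected histogram pattern, nearly all bad
    k-mers sit below the crossover frequency and nearly all good ones at or
    above it."""
    spec = build_spectrum(study_dataset.reads, k=24, q_excellent=0)
    cats = categorize_kmers(study_dataset.reads, study_dataset.truth, 24)
    ch = categorized_histogram(spec, cats)
    x = crossover_threshold(ch)
    assert x is not None
    f = spec.f_codes(cats.codes)
    bad = cats.cats == 1
    good = cats.cats == 0
    assert (f[bad] < x).mean() >= 0.90
    assert (f[good] >= x).mean() >= 0.90
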