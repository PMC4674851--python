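import numpy as np
import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from perfectread import (
    ReadRecord,
    RuleConfig,
    ShortReadError,
    build_index,
    build_spectrum,
    classify_many,
    classify_read,
    filter_dataset,
    kmer_is_valid,
    kmer_positions,
)
from perfectread._encode import encode_kmer
from perfectread.kmer_spectrum import KmerSpectrum

from conftest import make_reads


def spectrum_of(freqs_by_kmer, k):
    items = sorted((encode_kmer(u), f) for u, f in freqs_by_kmer.items())
    return KmerSpectrum(
        k=k,
        q_excellent=0,
        codes=np.array([c for c, _ in items], np.int64),
        freqs=np.array([f for _, f in items], np.int64),
    )


class TestSchedule:
    @pytest.mark.parametrize(
        "length,k,expected",
        [
            (101, 24, [0, 12, 24, 36, 48, 60, 72, 77]),
            (24, 24, [0]),
            (75, 24, [0, 12, 24, 36, 48, 51]),
            (76, 24, [0, 12, 24, 36, 48, 52]),
            (90, 24, [0, 12, 24, 36, 48, 60, 66]),
        ],
    )
    def test_hand_simulated_offsets(self, length, k, expected):
        assert kmer_positions(length, k) == expected

    def test_short_read_raises(self):
        with pytest.raises(ShortReadError):
            kmer_positions(23, 24)

    @given(length=st.integers(24, 500))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_schedule_invariants(self, length):
        k = 24
        pos = kmer_positions(length, k)
        assert pos[0] == 0
        assert pos[-1] == length - k
        assert all(b > a for a, b in zip(pos, pos[1:]))
        # every base position is inside at least one visited window
        covered = set()
        for p in pos:
            covered.update(range(p, p + k))
        assert covered == set(range(length))


class TestRuleConfig:
    def test_invariants(self):
        with pytest.raises(ValueError):
            RuleConfig(c_e=1, c_g=1)
        with pytest.raises(ValueError):
            RuleConfig(q_g=73, q_e=73)
        with pytest.raises(ValueError):
            RuleConfig(rule_level=6)
        with pytest.raises(ValueError):
            RuleConfig(f_h=1.0)

    def test_ascii_unit_decodes_with_offset(self):
        cfg = RuleConfig(q_g=45, q_e=73, quality_unit="ascii", quality_offset=33)
        assert cfg.q_g_decoded == 12
        assert cfg.q_e_decoded == 40
        cfg = RuleConfig.from_decoded(q_g=12, q_e=40)
        assert cfg.q_e_decoded == 40


class TestKmerValidity:
    def test_p1_inclusive_boundary(self):
        spec = spectrum_of({"AAAA" * 6: 8}, 24)
        cfg = RuleConfig.from_decoded(q_g=12, q_e=40, c_e=8, c_g=1, rule_level=1)
        q = np.full(24, 40)
        assert kmer_is_valid("A" * 24, q, spec, None, cfg) == (True, "P1")
        spec7 = spectrum_of({"A" * 24: 7}, 24)
        assert kmer_is_valid("A" * 24, q, spec7, None, cfg) == (False, None)

    def test_property_chain_reaches_p4(self):
        # f(T)=3 with one neighbor at f=5: P2 fails on quality, P3 fails on
        # the neighbor, P4 holds since 5 < 3 * 2.
        k = 4
        spec = spectrum_of({"AAAA": 3, "AAAC": 5}, k)
        idx = build_index(spec, 1)
        cfg = RuleConfig.from_decoded(
            q_g=30, q_e=40, c_e=10, c_g=1, f_h=2.0, rule_level=4
        )
        q = np.array([40, 40, 40, 10])
        assert kmer_is_valid("AAAA", q, spec, idx, cfg) == (True, "P4")
        cfg3 = RuleConfig.from_decoded(q_g=30, q_e=40, c_e=10, c_g=1, rule_level=3)
        assert kmer_is_valid("AAAA", q, spec, idx, cfg3) == (False, None)

    def test_p4_fails_on_high_cardinality_neighbor(self):
        spec = spectrum_of({"AAAA": 3, "AAAC": 6}, 4)
        idx = build_index(spec, 1)
        cfg = RuleConfig.from_decoded(
            q_g=30, q_e=40, c_e=10, c_g=1, f_h=2.0, rule_level=4
        )
        q = np.array([40, 40, 40, 10])
        assert kmer_is_valid("AAAA", q, spec, idx, cfg) == (False, None)

    def test_n_or_absent_kmer_always_fails(self):
        spec = spectrum_of({"AAAA": 100}, 4)
        cfg = RuleConfig.from_decoded(q_g=12, q_e=40, c_e=2, c_g=1, rule_level=5)
        idx = build_index(spec, 1)
        q = np.full(4, 40)
        assert kmer_is_valid("ANAA", q, spec, idx, cfg) == (False, None)
        assert kmer_is_valid("GGCC", q, spec, idx, cfg) == (False, None)

    def test_p5_quality_positions_follow_strand_flip(self):
        # Window TTTG canonicalizes to CAAA (revcomp). Its stored neighbor
        # CAAC differs from CAAA at canonical index 3, which is instance
        # position 0 of TTTG. P5 must therefore test the quality of the
        # FIRST base of the instance.
        k = 4
        spec = spectrum_of({"CAAA": 2, "CAAC": 6}, k)  # P4 fails: 6 >= 2*2
        idx = build_index(spec, 1)
        cfg = RuleConfig.from_decoded(q_g=30, q_e=40, c_e=10, c_g=1, rule_level=5)
        q_first_low = np.array([10, 40, 40, 40])
        q_last_low = np.array([40, 40, 40, 10])
        assert kmer_is_valid("TTTG", q_first_low, spec, idx, cfg) == (False, None)
        assert kmer_is_valid("TTTG", q_last_low, spec, idx, cfg) == (True, "P5")

    def test_rule5_chain_matches_string_oracle_on_random_cases(self):
        """Full P2..P5 disjunction against an independent string-arithmetic
        oracle, exercising the canonical-strand flip in P5."""
        rng = np.random.default_rng(0)
        k = 6
        q_g = 30
        cfg = RuleConfig.from_decoded(
            q_g=q_g, q_e=40, c_e=1000, c_g=1, f_h=2.0, rule_level=5
        )
        for _ in range(300):
            kmers = {"".join(rng.choice(list("ACGT"), size=k)) for _ in range(8)}
            freqs = {
                min(u, str(Seq(u).reverse_complement())): int(rng.choice([1, 10]))
                for u in kmers
            }
            spec = spectrum_of(freqs, k)
            idx = build_index(spec, 1)
            inst = "".join(rng.choice(list("ACGT"), size=k))
            q = rng.choice([10, 40], size=k)
            got, _prop = kmer_is_valid(inst, q, spec, idx, cfg)

            inst_canon = min(inst, str(Seq(inst).reverse_complement()))
            flipped = inst_canon != inst
            f = freqs.get(inst_canon, 0)
            if f < 1:
                expect = False
            elif q.min() >= q_g:
                expect = True  # P2
            else:
                neigh = [
                    u
                    for u in freqs
                    if u != inst_canon
                    and sum(a != b for a, b in zip(u, inst_canon)) <= 1
                ]
                if not any(freqs[u] >= 1 for u in neigh):
                    expect = True  # P3
                elif not any(freqs[u] >= f * 2.0 for u in neigh):
                    expect = True  # P4
                else:  # P5
                    expect = True
                    for u in neigh:
                        for i in range(k):
                            if u[i] != inst_canon[i]:
                                ip = k - 1 - i if flipped else i
                                if q[ip] < q_g:
                                    expect = False
            assert got == expect


class TestClassifyRead:
    def make_perfect_setup(self):
        seq = "ACGTTGCAACGGTCAG" * 4  # 64 bp
        reads = make_reads([seq] * 10)
        spec = build_spectrum(reads, k=8, q_excellent=0)
        cfg = RuleConfig.from_decoded(q_g=12, q_e=40, c_e=2, c_g=1, rule_level=1)
        return reads, spec, cfg

    def test_all_valid_is_perfect(self):
        reads, spec, cfg = self.make_perfect_setup()
        c = classify_read(reads[0], spec, None, cfg)
        assert c.is_perfect
        assert c.checked_positions == kmer_positions(64, 8)
        assert c.first_invalid_position is None

    def test_first_invalid_recorded(self):
        reads, spec, cfg = self.make_perfect_setup()
        mutated = reads[0].sequence[:30] + "A" + reads[0].sequence[31:]
        if mutated == reads[0].sequence:
            mutated = reads[0].sequence[:30] + "C" + reads[0].sequence[31:]
        bad = ReadRecord("bad", mutated, reads[0].qualities)
        c = classify_read(bad, spec, None, cfg)
        assert not c.is_perfect
        assert c.first_invalid_position is not None
        assert c.first_invalid_kmer == mutated[
            c.first_invalid_position : c.first_invalid_position + 8
        ]
        assert c.checked_positions[-1] == c.first_invalid_position

    def test_short_read_policies(self):
        reads, spec, cfg = self.make_perfect_setup()
        short = ReadRecord("s", "ACGT", np.full(4, 40))
        c = classify_read(short, spec, None, cfg)
        assert c.label == "Erroneous" and c.is_short
        with pytest.raises(ShortReadError):
            classify_read(short, spec, None, cfg, short_read="error")


@pytest.mark.parametrize("rule_level", [1, 2, 3, 4, 5])
def test_batch_equals_scalar(small_dataset, rule_level):
    """The vectorized batch classifier and the per-read scan agree."""
    reads = small_dataset.reads[:400]
    spec = build_spectrum(small_dataset.reads, k=24, q_excellent=38)
    idx = build_index(spec, 1)
    cfg = RuleConfig.from_decoded(
        q_g=39, q_e=40, c_e=3, c_g=1, rule_level=rule_level
    )
    batch = classify_many(reads, spec, idx, cfg)
    for r, c in zip(reads, batch):
        s = classify_read(r, spec, idx, cfg)
        assert (c.label, c.first_invalid_position, c.checked_positions) == (
            s.label,
            s.first_invalid_position,
            s.checked_positions,
        )


def test_filter_dataset_partition_and_determinism(small_dataset):
    reads = small_dataset.reads[:2000] + [ReadRecord("tiny", "ACGT", np.full(4, 40))]
    spec = build_spectrum(small_dataset.reads, k=24, q_excellent=38)
    cfg = RuleConfig.from_decoded(q_g=39, q_e=40, c_e=3, c_g=1, rule_level=2)
    p1, e1, s1 = filter_dataset(reads, spec, None, cfg)
    p2, e2, s2 = filter_dataset(reads, spec, None, cfg)
    assert s1.n_perfect + s1.n_erroneous + s1.n_short == s1.n_input == len(reads)
    assert s1.n_short == 1
    assert len(p1) + len(e1) == len(reads)
    assert {r.read_id for r in p1}.isdisjoint({r.read_id for r in e1})
    assert [r.read_id for r in p1] == [r.read_id for r in p2]
    assert s1 == s2


def test_filter_empty_input():
    spec = spectrum_of({"A" * 24: 5}, 24)
    cfg = RuleConfig.from_decoded(q_g=12, q_e=40)
    p, e, s = filter_dataset([], spec, None, cfg)
    assert (p, e) == ([], [])
    assert s.n_input == 0


def test_repeated_base_read_boundary(small_dataset):
    """A homopolymer read alone in the dataset: its single canonical k-mer
    frequency equals its own window count, and P1 follows C_E exactly."""
    read = ReadRecord("homo", "A" * 30, np.full(30, 40))
    spec = build_spectrum([read], k=24, q_excellent=0)
    assert spec.f("A" * 24) == 7  # 30-24+1 windows, all the same k-mer
    ok = RuleConfig.from_decoded(q_g=12, q_e=40, c_e=7, c_g=1, rule_level=1)
    too_high = RuleConfig.from_decoded(q_g=12, q_e=40, c_e=8, c_g=1, rule_level=1)
    assert classify_read(read, spec, None, ok).is_perfect
    assert not classify_read(read, spec, None, too_high).is_perfect
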