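import numpy as np
import pytest

from ampliseq.demux import AmpliconPool
from ampliseq.io_sheets import ReadPair
from ampliseq.reduce import (
    JoinedRead,
    ReduceConfig,
    call_alleles,
    consensus,
    join_pair,
    reduce_pool,
    reduce_to_modal_length,
    revcomp,
    trim_pair,
)
from ampliseq.simulate import SimConfig, simulate_pool


def _pair(r1, r2, q1=None, q2=None):
    return ReadPair("r", r1, r2, q1 or "I" * len(r1), q2 or "I" * len(r2))


def _jr(seq):
    return JoinedRead(seq, "I" * len(seq), True)


class TestTrim:
    def test_trims_3prime_ends_independently(self):
        pair = _pair("A" * 300, "C" * 300)
        out = trim_pair(pair, 75, 150)
        assert len(out.r1_seq) == 225 and len(out.r2_seq) == 150
        assert len(out.r1_qual) == 225 and len(out.r2_qual) == 150

    def test_zero_trim_is_identity(self):
        pair = _pair("ACGT", "TTTT")
        out = trim_pair(pair, 0, 0)
        assert out.r1_seq == "ACGT" and out.r2_seq == "TTTT"

    def test_trim_to_empty_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            out = trim_pair(_pair("ACGTACGTAC", "ACGT"), 10, 0)
        assert out.r1_seq == ""


class TestJoin:
    def test_exact_overlap_merges(self, rng):
        amplicon = "".join(rng.choice(list("ACGT"), 150))
        r1, r2 = amplicon[:100], revcomp(amplicon[50:])
        out = join_pair(_pair(r1, r2))
        assert out.joined and out.sequence == amplicon
        assert len(out.sequence) == 100 + 100 - 50

    def test_nine_base_overlap_is_below_default_minimum(self, rng):
        left = "".join(rng.choice(list("ACGT"), 40))
        shared = "ACGTTGCAA"  # 9 identical terminal bases
        right = "".join(rng.choice(list("ACGT"), 40))
        r1 = left + shared
        r2 = revcomp(shared + right)
        out = join_pair(_pair(r1, r2))
        assert not out.joined
        assert out.sequence == r1 + shared + right
        assert out.junction == len(r1)

    def test_nonoverlapping_trimmed_mates_concatenate(self, rng):
        # 400 nt amplicon read as 300 nt mates trimmed to 225/150: windows
        # [0,225) and [250,400) cannot overlap
        amplicon = "".join(rng.choice(list("ACGT"), 400))
        pair = trim_pair(_pair(amplicon[:300], revcomp(amplicon)[:300]), 75, 150)
        out = join_pair(pair)
        assert not out.joined
        assert out.sequence == amplicon[:225] + amplicon[250:]

    def test_disagreement_resolves_to_higher_quality_base(self):
        r1 = "AAAAAAAAAAAA"
        r2_template = "AAAAAAAAAAGA"  # one disagreement inside the overlap
        out = join_pair(_pair(r1, revcomp(r2_template), q1="#" * 12, q2="I" * 12), min_overlap=10)
        assert out.joined and "G" in out.sequence


class TestModalLength:
    def test_keeps_majority_length(self):
        reads = [_jr("A" * 300)] * 90 + [_jr("A" * 299)] * 10
        kept, modal = reduce_to_modal_length(reads)
        assert modal == 300 and len(kept) == 90

    def test_all_equal_is_identity(self):
        reads = [_jr("ACGT")] * 5
        kept, modal = reduce_to_modal_length(reads)
        assert kept == reads and modal == 4

    def test_tie_prefers_longer(self):
        reads = [_jr("A" * 300)] * 50 + [_jr("A" * 310)] * 50
        _, modal = reduce_to_modal_length(reads)
        assert modal == 310


class TestConsensus:
    def test_unanimous_reads_in_both_modes(self):
        reads = [_jr("ACGTAC")] * 10
        assert consensus(reads, "consensus") == "ACGTAC"
        assert consensus(reads, "ambiguity") == "ACGTAC"

    def test_supported_variant_becomes_iupac_code(self):
        reads = [_jr("A")] * 60 + [_jr("G")] * 40
        assert consensus(reads, "ambiguity", s=5, f=0.05) == "R"
        assert consensus(reads, "consensus") == "A"

    def test_variant_below_read_support_is_dropped(self):
        reads = [_jr("A")] * 96 + [_jr("G")] * 4
        assert consensus(reads, "ambiguity", s=5, f=0.05) == "A"
        assert consensus(reads, "consensus") == "A"

    def test_plurality_tie_breaks_alphabetically(self):
        reads = [_jr("G")] * 5 + [_jr("C")] * 5
        assert consensus(reads, "consensus", s=100) == "C"

    def test_strict_thresholds_reduce_ambiguity_to_majority_consensus(self):
        reads = [_jr("A")] * 70 + [_jr("G")] * 30
        assert consensus(reads, "ambiguity", s=1, f=0.51) == consensus(reads, "consensus")


class TestCallAlleles:
    def test_diploid_heterozygote_with_error_singletons(self, rng):
        p = "".join(rng.choice(list("ACGT"), 80))
        q = p[:40] + ("A" if p[40] != "A" else "C") + p[41:]
        singles = []
        while len(singles) < 5:
            s = "".join(rng.choice(list("ACGT"), 80))
            if s not in (p, q) and s not in singles:
                singles.append(s)
        reads = [_jr(p)] * 55 + [_jr(q)] * 40 + [_jr(s) for s in singles]
        aset = call_alleles(reads, "S", "T")
        assert [(a.sequence, a.read_count) for a in aset.alleles] == [(p, 55), (q, 40)]
        assert aset.status == "ok"
        assert sum(a.frequency for a in aset.alleles) <= 1

    def test_single_allele_frequency_one(self):
        aset = call_alleles([_jr("ACGT")] * 100, "S", "T")
        assert len(aset.alleles) == 1 and aset.alleles[0].frequency == 1.0

    def test_tetraploid_four_alleles_at_quarter_frequency(self):
        seqs = ["AAAA", "CCCC", "GGGG", "TTTT"]
        reads = [_jr(s) for s in seqs for _ in range(25)]
        aset = call_alleles(reads, "S", "T")
        assert len(aset.alleles) == 4
        assert all(a.read_count == 25 for a in aset.alleles)

    def test_all_distinct_reads_discards_target(self, rng):
        reads = []
        seen = set()
        while len(reads) < 100:
            s = "".join(rng.choice(list("ACGT"), 30))
            if s not in seen:
                seen.add(s)
                reads.append(_jr(s))
        aset = call_alleles(reads, "S", "T")
        assert aset.status == "discarded" and aset.alleles == []

    def test_five_read_five_percent_boundary_retained(self):
        reads = [_jr("A" * 20)] * 95 + [_jr("C" * 20)] * 5
        aset = call_alleles(reads, "S", "T", s=5, f=0.05)
        assert len(aset.alleles) == 2  # 5 reads and exactly 5% both pass


class TestReducePool:
    def test_noise_free_diploid_pool_recovers_both_alleles(self, rng):
        config = SimConfig(error_rate=0.0, seed=11)
        base = "".join(rng.choice(list("ACGT"), 420))
        alt = base[:100] + ("T" if base[100] != "T" else "G") + base[101:]
        reads, truth = simulate_pool([base, alt], [0.5, 0.5], 60, config, rng)
        aset, category = reduce_pool(
            AmpliconPool("S", "T", reads), ReduceConfig(mode="occurrence")
        )
        assert sorted(a.sequence for a in aset.alleles) == sorted(set(truth.reduced))
        assert category == "joined"

    def test_empty_pool_fails(self):
        result, category = reduce_pool(AmpliconPool("S", "T", []), ReduceConfig(mode="occurrence"))
        assert result is None and category == "failed"

    def test_pool_below_absolute_threshold_discarded(self):
        reads = [ReadPair(f"r{i}", "ACGTACGTACGTACG", "CGTACGTACGTACGT",
                          "I" * 15, "I" * 15) for i in range(4)]
        aset, category = reduce_pool(
            AmpliconPool("S", "T", reads), ReduceConfig(mode="occurrence")
        )
        assert aset.status == "discarded" and category == "failed"

    def test_reduction_is_deterministic(self, noise_free_pools):
        pools, _ = noise_free_pools
        config = ReduceConfig(mode="occurrence")
        pool = next(iter(pools.values()))
        first = reduce_pool(pool, config)
        second = reduce_pool(pool, config)
        assert [(a.sequence, a.read_count) for a in first[0].alleles] == [
            (a.sequence, a.read_count) for a in second[0].alleles
        ]
        assert first[1] == second[1]

    def test_single_sequence_pool_is_idempotent_fixture(self):
        seq = "ACGTACGTAC" * 6
        reads = [ReadPair(f"r{i}", seq, revcomp(seq), "I" * 60, "I" * 60) for i in range(10)]
        aset, _ = reduce_pool(AmpliconPool("S", "T", reads), ReduceConfig(mode="occurrence"))
        assert [a.sequence for a in aset.alleles] == [seq]
        rereads = [ReadPair("r", aset.alleles[0].sequence, revcomp(aset.alleles[0].sequence),
                            "I" * 60, "I" * 60) for _ in range(10)]
        aset2, _ = reduce_pool(AmpliconPool("S", "T", rereads), ReduceConfig(mode="occurrence"))
        assert aset2.alleles[0].sequence == seq
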