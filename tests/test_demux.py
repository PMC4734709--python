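import numpy as np
import pytest

from ampliseq.demux import DemuxConfig, UNASSIGNED, demultiplex, match_barcode, match_primer
from ampliseq.io_sheets import BarcodeEntry, ReadPair
from ampliseq.simulate import SimConfig, simulate_run

from oracles import firm_end_match, nearest_barcode

CFG = DemuxConfig()


def _bc(name, seq):
    return BarcodeEntry(name, "P5", seq)


class TestMatchBarcode:
    table = [_bc("b1", "ACGTACGT"), _bc("b2", "TTGGCCAA")]

    def test_exact_match(self):
        assert match_barcode("ACGTACGT", self.table) == ("b1", 0)

    def test_one_substitution_within_default_threshold(self):
        assert match_barcode("ACGTACGA", self.table) == ("b1", 1)

    def test_two_substitutions_rejected(self):
        # brute force: distance 2 to b1, 8 to b2
        assert match_barcode("ACGTACAA", self.table) == (None, -1)

    def test_equidistant_candidates_rejected(self):
        # two barcodes differing at 2 positions; observed midway (dist 1 to each)
        table = [_bc("x", "AAAAAAAA"), _bc("y", "AAAAAATT")]
        assert match_barcode("AAAAAAAT", table, max_dist=1) == (None, -1)

    def test_agrees_with_brute_force_search(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(300):
            table = []
            seen = set()
            while len(table) < 6:
                seq = "".join(rng.choice(bases, 8))
                if seq not in seen:
                    seen.add(seq)
                    table.append(_bc(f"b{len(table)}", seq))
            observed = "".join(rng.choice(bases, 8))
            got = match_barcode(observed, table, max_dist=1)
            exp = nearest_barcode(observed, [(b.name, b.sequence) for b in table], max_dist=1)
            assert got == exp


class TestMatchPrimer:
    primer = "ACGGTTCAGATTACAGCGTA"  # 20 nt

    def _primers(self):
        return [("T1", self.primer)]

    def test_exact_prefix(self):
        read = self.primer + "GGGGGGGGGG"
        assert match_primer(read, self._primers(), CFG) == ("T1", 0, 20)

    def test_four_substitutions_outside_firm_end_accepted(self):
        mutated = list(self.primer)
        for pos, base in [(1, "T"), (5, "A"), (9, "C"), (13, "T")]:
            assert mutated[pos] != base
            mutated[pos] = base
        read = "".join(mutated) + "GGGGGGGGGG"
        target, dist, consumed = match_primer(read, self._primers(), CFG)
        assert (target, dist, consumed) == ("T1", 4, 20)

    def test_substitution_in_firm_end_rejected(self):
        mutated = self.primer[:-2] + "A" + self.primer[-1]  # edit inside last 4
        assert mutated != self.primer
        read = mutated + "GGGGGGGGGG"
        assert match_primer(read, self._primers(), CFG) == (None, -1, 0)

    def test_five_edits_rejected(self):
        mutated = list(self.primer)
        for pos, base in [(0, "T"), (3, "C"), (6, "A"), (9, "T"), (12, "G")]:
            assert mutated[pos] != base
            mutated[pos] = base
        read = "".join(mutated) + "GGGGGGGGGG"
        assert match_primer(read, self._primers(), CFG) == (None, -1, 0)

    def test_read_shorter_than_primer_rejected(self):
        assert match_primer(self.primer[:-1], self._primers(), CFG) == (None, -1, 0)

    def test_indel_before_firm_end_shifts_consumed_bases(self):
        read = self.primer[:8] + self.primer[9:] + "GGGGGGGGGG"  # delete base 8
        target, dist, consumed = match_primer(read, self._primers(), CFG)
        assert (target, dist, consumed) == ("T1", 1, 19)

    def test_agrees_with_exhaustive_firm_end_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(500):
            plen = int(rng.integers(12, 30))
            primer = "".join(rng.choice(bases, plen))
            read = "".join(rng.choice(bases, int(rng.integers(plen, plen + 15))))
            if rng.random() < 0.5:  # half the cases: plant a corrupted primer
                noisy = list(primer)
                for _ in range(int(rng.integers(0, 6))):
                    i = int(rng.integers(0, len(noisy)))
                    noisy[i] = str(rng.choice(bases))
                read = "".join(noisy) + read[len(noisy):]
            got = match_primer(read, [("T", primer)], CFG)
            exp = firm_end_match(read, primer, CFG.max_primer_dist, CFG.firm_end_len)
            if exp is None:
                assert got == (None, -1, 0)
            else:
                assert got[0] == "T"
                assert (got[1], got[2]) == exp


class TestDemultiplex:
    def test_error_free_run_fully_assigned(self, noise_free_run, noise_free_pools):
        pools, report = noise_free_pools
        assert report.fraction_matched == 1.0
        assert report.n_pools == 4 * 3
        assert all(len(p) == 50 for p in pools.values())

    def test_primer_bases_stripped_from_pooled_reads(self, noise_free_run, noise_free_pools):
        pools, _ = noise_free_pools
        for (sample, target), pool in pools.items():
            primer = noise_free_run.primers.get(target)
            insert_alleles = noise_free_run.truth.pools[(sample, target)].alleles
            for read in pool.reads[:3]:
                assert any(read.r1_seq == a[: len(read.r1_seq)] for a in insert_alleles)
                assert not read.r1_seq.startswith(primer.fwd_seq)

    def test_corrupted_barcode_goes_unassigned_with_reason(self, noise_free_run):
        reads = [ReadPair(**vars(r)) for r in noise_free_run.reads[:20]]
        victim = reads[7]
        victim.r1_bc = "GG" + victim.r1_bc[2:] if victim.r1_bc[:2] != "GG" else "TT" + victim.r1_bc[2:]
        assignments = []
        pools, report = demultiplex(
            reads, noise_free_run.barcodes, noise_free_run.primers, noise_free_run.samples,
            assignments_out=assignments,
        )
        assert report.n_fail_barcode == 1
        failed = [a for a in assignments if a.fail_reason == "barcode"]
        assert len(failed) == 1 and failed[0].read_id == victim.id
        assert failed[0].sample_id == UNASSIGNED

    def test_read_conservation(self, noise_free_run):
        config = SimConfig(n_samples=4, n_targets=3, depth_mean=30, depth_dispersion=5,
                           error_rate=0.01, barcode_error_rate=0.05, seed=99)
        res = simulate_run(config)
        pools, report = demultiplex(res.reads, res.barcodes, res.primers, res.samples)
        assert report.n_assigned + report.n_unassigned == report.n_total == len(res.reads)
        assert sum(report.pool_counts.values()) == report.n_assigned

    def test_assigned_count_monotone_in_primer_threshold(self):
        config = SimConfig(n_samples=4, n_targets=3, depth_mean=30, depth_dispersion=0,
                           error_rate=0.02, barcode_error_rate=0.0, seed=5)
        res = simulate_run(config)
        counts = []
        for max_dist in (0, 2, 4, 6):
            _, report = demultiplex(
                res.reads, res.barcodes, res.primers, res.samples,
                DemuxConfig(max_primer_dist=max_dist),
            )
            counts.append(report.n_assigned)
        assert counts == sorted(counts)

    def test_sample_relabeling_permutes_pools_only(self, noise_free_run, noise_free_pools):
        from ampliseq.io_sheets import SampleRecord, SampleTable

        _, report = noise_free_pools
        relabeled = SampleTable(
            [SampleRecord("X_" + s.sample_id, s.p5_barcode, s.p7_barcode, s.project)
             for s in noise_free_run.samples]
        )
        _, report2 = demultiplex(
            noise_free_run.reads, noise_free_run.barcodes, noise_free_run.primers, relabeled
        )
        assert report2.n_assigned == report.n_assigned
        assert sorted(report2.pool_counts.values()) == sorted(report.pool_counts.values())
        assert {("X_" + s, t) for s, t in report.pool_counts} == set(report2.pool_counts)
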