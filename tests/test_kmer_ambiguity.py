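"""Exact k-mer exclusivity: enumeration, genome scanning, summaries, reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from trfspace import (
    GenomeSequence,
    TRNASpaceIntervals,
    brute_force_occurrences,
    cca_terminal_report,
    count_sequence_occurrences,
    crosstalk_report,
    enumerate_mature_kmers,
    filter_short_trna_repeats,
    read_repeatmasker_out,
    reverse_complement,
    scan_genome,
    summarize_ambiguity,
)
from trfspace.kmer_ambiguity import RepeatFeature, round_half_up

EMPTY = TRNASpaceIntervals.empty()


def _genome(seq, name="g"):
    return {name: GenomeSequence(name=name, seq=seq)}


def _oracle_counts(genome, query, space):
    hits = brute_force_occurrences(genome, query)
    inside = sum(1 for c, a, b, _ in hits if space.contains(c, a, b))
    return inside, len(hits) - inside


class TestEnumerate:
    def test_all_windows_distinct(self):
        t = enumerate_mature_kmers([("m", "ACGTACG")], k=4)
        assert set(t.entries) == {"ACGT", "CGTA", "GTAC", "TACG"}
        assert t.n_distinct == 4

    def test_degenerate_repeat_collects_sources(self):
        t = enumerate_mature_kmers([("m", "AAAAA")], k=3)
        assert set(t.entries) == {"AAA"}
        assert t.entries["AAA"].sources == [("m", 1), ("m", 2), ("m", 3)]

    def test_identical_matures_dedup_keys_double_sources(self):
        one = enumerate_mature_kmers([("a", "ACGTACG")], k=4)
        two = enumerate_mature_kmers([("a", "ACGTACG"), ("b", "ACGTACG")], k=4)
        assert set(two.entries) == set(one.entries)
        assert all(len(e.sources) == 2 for e in two.entries.values())

    def test_n_windows_skipped(self):
        t = enumerate_mature_kmers([("m", "ACNGT")], k=2)
        assert set(t.entries) == {"AC", "GT"}

    def test_oversized_k_warns_and_empties(self):
        with pytest.warns(UserWarning, match="exceeds"):
            t = enumerate_mature_kmers([("m", "ACGT")], k=10)
        assert t.n_distinct == 0


class TestScanGenome:
    def _scan_one(self, genome_seq, key, space=EMPTY):
        table = enumerate_mature_kmers([("m", key)], k=len(key))
        scan_genome(_genome(genome_seq), [table], space)
        return table.entries[key]

    def test_palindromic_window_counts_once(self):
        e = self._scan_one("TTACGTTT", "ACGT")
        assert (e.inside_count, e.outside_count) == (0, 1)

    def test_contained_hit_is_inside(self):
        space = TRNASpaceIntervals({"g": [(2, 6)]})
        e = self._scan_one("TTAAACTT", "AAAC", space)
        assert (e.inside_count, e.outside_count) == (1, 0)

    def test_reverse_complement_hit(self):
        e = self._scan_one("GTTT", "AAAC")
        assert (e.inside_count, e.outside_count) == (0, 1)

    def test_empty_genome_warns(self):
        table = enumerate_mature_kmers([("m", "ACGT")], k=4)
        with pytest.warns(UserWarning, match="empty genome"):
            scan_genome({}, [table], EMPTY)
        assert table.entries["ACGT"].outside_count == 0

    def test_random_50kb_genome_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        genome = _genome(seq)
        space = TRNASpaceIntervals({"g": [(1000, 2000), (30_000, 31_000)]})
        k = 16
        starts = rng.integers(0, len(seq) - k, size=20)
        keys = [seq[s : s + k] for s in starts]
        table = enumerate_mature_kmers([(f"m{i}", q) for i, q in enumerate(keys)], k=k)
        scan_genome(genome, [table], space)
        for key in keys:
            expected = _oracle_counts(genome, key, space)
            e = table.entries[key]
            assert (e.inside_count, e.outside_count) == expected

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.data())
    def test_scan_equals_oracle_property(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 800))))
        k = int(rng.integers(2, 9))
        genome = _genome(seq)
        a = int(rng.integers(0, max(1, len(seq) - 10)))
        space = TRNASpaceIntervals({"g": [(a, a + 10)]})
        start = int(rng.integers(0, len(seq) - k))
        key = seq[start : start + k]
        table = enumerate_mature_kmers([("m", key)], k=k)
        scan_genome(genome, [table], space)
        e = table.entries[key]
        assert (e.inside_count, e.outside_count) == _oracle_counts(genome, key, space)

    def test_strand_symmetry(self, small_fixture):
        """Reverse-complementing every genome record leaves counts unchanged."""
        fx = small_fixture
        table_fwd = enumerate_mature_kmers(fx.matures, 16)
        scan_genome(fx.genome, [table_fwd], EMPTY)
        rc_genome = {
            name: GenomeSequence(name=name, seq=reverse_complement(g.seq))
            for name, g in fx.genome.items()
        }
        table_rc = enumerate_mature_kmers(fx.matures, 16)
        scan_genome(rc_genome, [table_rc], EMPTY)
        for key, e in table_fwd.entries.items():
            assert table_rc.entries[key].outside_count == e.outside_count

    def test_space_nesting_never_increases_outside(self, small_fixture):
        fx = small_fixture
        small = enumerate_mature_kmers(fx.matures, 16)
        scan_genome(fx.genome, [small], fx.space)
        bigger_ivs = {
            c: [(max(0, a - 50), b + 50) for a, b in ivs]
            for c, ivs in fx.space.intervals.items()
        }
        big = enumerate_mature_kmers(fx.matures, 16)
        scan_genome(fx.genome, [big], TRNASpaceIntervals(bigger_ivs))
        for key, e in small.entries.items():
            assert big.entries[key].outside_count <= e.outside_count


class TestSummarize:
    def _table(self, outsides):
        t = enumerate_mature_kmers([("m", "ACGTACGT")], k=4)
        assert t.n_distinct == len(outsides)
        for e, o in zip(t.entries.values(), outsides):
            e.outside_count = o
        return t

    def test_basic_arithmetic(self):
        row = summarize_ambiguity(self._table([0, 1, 2, 5]))
        assert (row.n_distinct, row.n_exclusive, row.n_nonexclusive) == (4, 1, 3)
        assert (row.pct_exclusive, row.pct_nonexclusive) == (25.0, 75.0)

    def test_all_exclusive(self):
        row = summarize_ambiguity(self._table([0, 0, 0, 0]))
        assert row.pct_exclusive == 100.0

    def test_rounding_is_half_up(self):
        assert round_half_up(6.25) == 6.3
        assert round_half_up(92.35) == 92.4

    def test_percentages_sum_to_hundred(self):
        row = summarize_ambiguity(self._table([0, 1, 1, 1]))
        assert abs(row.pct_exclusive + row.pct_nonexclusive - 100.0) <= 0.1

    def test_empty_table_rejected(self):
        from trfspace import ExclusivityTable

        with pytest.raises(ValueError):
            summarize_ambiguity(ExclusivityTable(k=4))

    def test_junction_kmer_with_zero_genomic_copies_is_exclusive(self, fixture100k):
        """A k-mer existing only across a splice junction or the CCA has zero
        genomic occurrences yet must count as exclusive."""
        fx = fixture100k
        table = enumerate_mature_kmers(fx.matures, 16)
        scan_genome(fx.genome, [table], fx.space)
        zero_total = [
            k for k, e in table.entries.items()
            if e.inside_count == 0 and e.outside_count == 0
        ]
        assert zero_total, "fixture should contain junction/CCA-spanning k-mers"
        row = summarize_ambiguity(table)
        assert row.n_exclusive >= len(zero_total)


class TestCountOccurrences:
    def test_forward_copies(self):
        assert count_sequence_occurrences(_genome("AAGGAAGG"), "AAGG", EMPTY) == (0, 2)

    def test_inside_when_space_covers(self):
        space = TRNASpaceIntervals({"g": [(0, 4)]})
        assert count_sequence_occurrences(_genome("AAGGTTTT"), "AAGG", space) == (1, 0)

    def test_query_with_n_rejected(self):
        with pytest.raises(ValueError, match="A,C,G,T"):
            count_sequence_occurrences(_genome("ACGT"), "AN", EMPTY)

    def test_palindromic_query_counted_once(self):
        assert count_sequence_occurrences(_genome("TTACGTTT"), "ACGT", EMPTY) == (0, 1)

    def test_planted_locus_counts_inside(self, small_fixture):
        fx = small_fixture
        locus = fx.loci[0]
        query = fx.genome[locus.chrom].seq[locus.start : locus.end]
        inside, _ = count_sequence_occurrences(fx.genome, query, fx.space)
        assert inside >= 1


class TestCCAReport:
    def test_decoy_totals_match_oracle(self, fixture100k):
        fx = fixture100k
        n_with, grand_total, per_trna = cca_terminal_report(
            fx.matures, fx.genome, fx.space, k=16
        )
        expected_per = {
            m.name: _oracle_counts(fx.genome, m.seq[-16:], fx.space)[1]
            for m in fx.matures
        }
        assert per_trna == expected_per
        assert grand_total == sum(expected_per.values())
        assert n_with == sum(1 for v in expected_per.values() if v)
        assert grand_total >= fx.spec.n_cca_decoys  # the planted decoys at least

    def test_no_decoys_means_zero(self):
        from trfspace import SyntheticGenomeSpec, generate_genome

        fx = generate_genome(
            SyntheticGenomeSpec(
                genome_length=20_000, n_trnas=3, n_intronic_trnas=0,
                n_partial_copies=0, n_lookalikes=0, n_cca_decoys=0, seed=3,
            )
        )
        n_with, grand_total, _ = cca_terminal_report(fx.matures, fx.genome, fx.space)
        assert (n_with, grand_total) == (0, 0)

    def test_short_mature_skipped_with_warning(self):
        matures = [("short", "TTCCA"), ("ok", "ACGTACGTACGTACGTCCA")]
        with pytest.warns(UserWarning, match="skipped"):
            _, _, per = cca_terminal_report(matures, _genome("ACGT"), EMPTY, k=16)
        assert "short" not in per and "ok" in per


class TestCrosstalk:
    def test_foreign_identical_to_mature_shares_all_kmers(self):
        seq = "ACGTTGCAGGCATCGATCGT"
        report = crosstalk_report([("m", seq)], [("f", seq)], k=16)
        assert report.per_trna["m"] == len(seq) - 16 + 1

    def test_no_overlap(self):
        report = crosstalk_report(
            [("m", "A" * 20)], [("f", "G" * 20)], k=16
        )
        assert (report.n_trnas_sharing, report.n_shared_kmers) == (0, 0)
        assert report.per_trna == {}

    def test_reverse_complement_sharing_counts_once(self):
        seq = "ACGTTGCAGGCATCGA"  # 16-mer
        report = crosstalk_report(
            [("m", seq)], [("f", reverse_complement(seq))], k=16
        )
        assert (report.n_trnas_sharing, report.n_shared_kmers) == (1, 1)

    def test_invalid_k_rejected(self):
        with pytest.raises(ValueError):
            crosstalk_report([("m", "ACGT")], [("f", "ACGT")], k=0)

    def test_lookalikes_share_kmers_on_fixture(self, fixture100k):
        fx = fixture100k
        report = crosstalk_report(fx.matures, fx.lookalike_seqs, k=16)
        # lookalikes are mutated tRNA bodies: sharing is partial but non-zero
        assert 1 <= report.n_trnas_sharing <= len(fx.matures)
        assert report.n_shared_kmers >= 1
        assert report.n_trnas_sharing == sum(1 for v in report.per_trna.values() if v >= 1)


RM_HEADER = (
    "   SW   perc perc perc  query  position in query  matching repeat\n"
    "score   div. del. ins.  sequence begin end (left) repeat class/family begin end (left) ID\n"
    "\n"
)


class TestRepeatMasker:
    def _write(self, tmp_path, lines):
        p = tmp_path / "rm.out"
        p.write_text(RM_HEADER + "".join(lines))
        return p

    def test_classes_parsed_and_split(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                "  463 1.3 0.6 1.7 chr1 101 148 (900) + tRNA-Gly tRNA 1 48 (0) 1\n",
                "  300 2.0 0.0 0.0 chr1 500 800 (200) C AluY SINE/Alu 1 300 (0) 2\n",
            ],
        )
        feats = read_repeatmasker_out(p)
        assert len(feats) == 2
        assert feats[0].repeat_class == "tRNA"
        assert feats[0].length == 48
        assert feats[1].repeat_class == "SINE"
        assert feats[1].strand == "-"

    def test_malformed_line_names_line_number(self, tmp_path):
        p = self._write(tmp_path, ["garbage line\n"])
        with pytest.raises(ValueError, match="line 4"):
            read_repeatmasker_out(p)

    def test_header_lines_skipped(self, tmp_path):
        p = self._write(tmp_path, [])
        assert read_repeatmasker_out(p) == []


class TestRepeatFilter:
    def _feat(self, start, end, cls="tRNA"):
        return RepeatFeature(chrom="c", start=start, end=end, strand="+",
                             repeat_name="r", repeat_class=cls)

    def test_short_trna_repeat_outside_space_kept(self):
        count, _ = filter_short_trna_repeats([self._feat(101, 148)], EMPTY)
        assert count == 1

    def test_inside_space_dropped(self):
        space = TRNASpaceIntervals({"c": [(50, 200)]})
        count, _ = filter_short_trna_repeats([self._feat(101, 148)], space)
        assert count == 0

    @pytest.mark.parametrize("end,expected", [(150, 1), (151, 0)])
    def test_length_boundary_at_max_len(self, end, expected):
        count, _ = filter_short_trna_repeats([self._feat(101, end)], EMPTY)
        assert count == expected

    def test_non_trna_class_dropped(self):
        count, _ = filter_short_trna_repeats([self._feat(101, 148, cls="SINE")], EMPTY)
        assert count == 0

    def test_fixture_partial_copies_recovered(self, fixture100k, tmp_path):
        from trfspace import write_fixture

        paths = write_fixture(fixture100k, tmp_path)
        feats = read_repeatmasker_out(paths["repeats"])
        count, kept = filter_short_trna_repeats(feats, fixture100k.space)
        assert count == fixture100k.spec.n_partial_copies
        bed = tmp_path / "kept.bed"
        filter_short_trna_repeats(feats, fixture100k.space, bed_path=bed)
        assert len(bed.read_text().splitlines()) == count
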