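"""Read parsing, filtering, duplicate collapse, merging and counting."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import adnasex as ax
from adnasex.read_processing import ChromCountTable
from adnasex.reads import AlignmentParseError, parse_sam, revcomp, write_sam, write_tsv
from adnasex.simulate import MT_NAME

from conftest import make_read

SAM_FIXTURE = """\
@HD\tVN:1.6\tSO:unsorted
@SQ\tSN:chr1\tLN:1000
@SQ\tSN:chrX\tLN:500
r1\t0\tchr1\t11\t60\t5M\t*\t0\t0\tACGTA\tIIIII\tMD:Z:5\tNM:i:0
r2\t4\t*\t0\t0\t*\t*\t0\t0\tACGT\tIIII\n\
r3\t16\tchrX\t101\t37\t4M\t*\t0\t0\tTTCA\tIIII\tMD:Z:0G3\tNM:i:1
"""


class TestParsing:
    def test_empty_stream_gives_empty_sequence(self, tmp_path):
        path = tmp_path / "empty.sam"
        path.write_text("@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:1000\n")
        assert parse_sam(path) == []

    def test_unmapped_records_are_skipped(self, tmp_path):
        path = tmp_path / "three.sam"
        path.write_text(SAM_FIXTURE)
        reads = parse_sam(path)
        assert [r.read_id for r in reads] == ["r1", "r3"]
        r1, r3 = reads
        assert (r1.chrom, r1.start, r1.strand, r1.mapq) == ("chr1", 10, "+", 60)
        # r3 is minus strand with a mismatch against reference G at its left
        assert (r3.chrom, r3.start, r3.strand) == ("chrX", 100, "-")
        assert r3.ref_bases == "GTCA"
        assert r3.mismatches == [(3, "C", "A")]  # molecule 5' is the right end

    def test_molecule_orientation(self):
        r = make_read(strand="-", seq="AAA", ref="AAG")
        assert r.molecule_ref == "CTT"
        assert r.molecule_seq == "TTT"
        assert r.mismatches == [(0, "C", "T")]

    def test_tsv_round_trip(self, tmp_path, xy_sim):
        subset = xy_sim.reads[:500]
        path = tmp_path / "reads.tsv"
        write_tsv(subset, path)
        back = ax.parse_alignments(path)
        assert back == subset

    def test_sam_round_trip(self, tmp_path, xy_sim):
        # origin-wrapping mito fragments are TSV-only; SAM holds the rest
        subset = [r for r in xy_sim.reads[:800]
                  if r.end <= xy_sim.ref.lengths[r.chrom]]
        path = tmp_path / "reads.sam"
        n = write_sam(subset, path, xy_sim.ref.lengths)
        assert n == len(subset)
        back = ax.parse_alignments(path)
        assert back == subset

    def test_malformed_tsv_is_reported(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("read_id\tchrom\tstart\n" "r1\tchr1\t0\n")
        with pytest.raises(AlignmentParseError, match="missing column"):
            ax.parse_alignments(path)


class TestFilter:
    def test_length_window_is_36_to_70_inclusive(self):
        reads = [make_read(read_id=f"r{n}", seq="A" * n) for n in (35, 36, 70, 71)]
        kept, stats = ax.filter_reads(reads)
        assert [r.length for r in kept] == [36, 70]
        assert (stats.removed_short, stats.removed_long) == (1, 1)

    def test_mapq_floor_is_30(self):
        reads = [make_read(read_id=f"q{q}", mapq=q, seq="A" * 50) for q in (29, 30)]
        kept, stats = ax.filter_reads(reads)
        assert [r.mapq for r in kept] == [30]
        assert stats.removed_mapq == 1

    def test_empty_input(self):
        kept, stats = ax.filter_reads([])
        assert kept == [] and stats.n_input == 0

    def test_filtering_is_monotone_and_idempotent(self, xy_sim):
        sample = xy_sim.reads[:2000]
        kept, _ = ax.filter_reads(sample)
        assert set(id(r) for r in kept) <= set(id(r) for r in sample)
        again, stats = ax.filter_reads(kept)
        assert again == kept
        assert stats.n_retained == stats.n_input


class TestDeduplicate:
    def test_highest_mapq_wins(self):
        a = make_read(read_id="a", mapq=37, seq="ACGTACGT")
        b = make_read(read_id="b", mapq=25, seq="ACGTACGT")
        assert ax.remove_duplicates([b, a]) == [a]

    def test_read_id_breaks_mapq_ties(self):
        a = make_read(read_id="a", seq="ACGT")
        b = make_read(read_id="b", seq="ACGT")
        assert ax.remove_duplicates([b, a]) == [a]

    def test_different_lengths_are_distinct_molecules(self):
        a = make_read(read_id="a", seq="ACGT")
        b = make_read(read_id="b", seq="ACGTA")
        assert len(ax.remove_duplicates([a, b])) == 2

    def test_strand_aware_five_prime_key(self):
        # same span, opposite strands: distinct molecules
        a = make_read(read_id="a", seq="ACGT", strand="+")
        b = make_read(read_id="b", seq="ACGT", strand="-")
        assert len(ax.remove_duplicates([a, b])) == 2

    def test_idempotent_and_order_invariant(self, xy_sim):
        sample = list(xy_sim.reads[:1000]) * 2
        once = ax.remove_duplicates(sample)
        assert ax.remove_duplicates(once) == once
        shuffled = sample[:]
        random.Random(0).shuffle(shuffled)
        assert set(r.read_id for r in ax.remove_duplicates(shuffled)) == \
            set(r.read_id for r in once)

    def test_identity_on_simulator_output(self, xy_sim):
        # the simulator guarantees unique duplicate keys at duplication 0
        assert ax.remove_duplicates(xy_sim.reads) == xy_sim.reads

    def test_duplicate_fraction_is_collapsed(self):
        cfg = ax.SimConfig(seed=11, n_reads=2000, duplicate_fraction=0.25)
        ref = ax.simulate_reference(cfg)
        reads, _ = ax.simulate_reads(cfg, ref)
        assert len(reads) == 2500
        assert len(ax.remove_duplicates(reads)) == 2000


class TestMerge:
    def test_merge_with_empty_is_dedup(self):
        a = [make_read(read_id="a", seq="ACGT"), make_read(read_id="b", seq="ACGT")]
        assert ax.merge_datasets([a, []]) == ax.remove_duplicates(a)

    def test_shared_duplicate_key_collapses(self):
        a = [make_read(read_id="a1", seq="ACGT"),
             make_read(read_id="a2", chrom="chr2", seq="ACGT")]
        b = [make_read(read_id="b1", seq="ACGT"),
             make_read(read_id="b2", chrom="chr3", seq="ACGT")]
        assert len(ax.merge_datasets([a, b])) == len(a) + len(b) - 1

    def test_merge_is_symmetric_as_a_set(self, xy_sim):
        a, b = xy_sim.reads[:300], xy_sim.reads[300:600]
        ab = {r.read_id for r in ax.merge_datasets([a, b])}
        ba = {r.read_id for r in ax.merge_datasets([b, a])}
        assert ab == ba

    def test_incompatible_naming_is_rejected(self):
        a = [make_read(chrom="chr1")]
        b = [make_read(chrom="1")]
        with pytest.raises(ValueError, match="incompatible reference naming"):
            ax.merge_datasets([a, b])


class TestCounting:
    def test_single_chromosome_counts(self):
        lengths = {"chrX": 100, "chrY": 50, "chr1": 100}
        reads = [make_read(read_id=f"r{i}", chrom="chrX") for i in range(10)]
        table = ax.count_by_chromosome(reads, lengths)
        assert table.counts == {"X": 10, "Y": 0, "1": 0}
        assert table.total == 10

    def test_missing_length_is_an_error(self):
        with pytest.raises(KeyError, match="chr9"):
            ax.count_by_chromosome([make_read(chrom="chr9")], {"chr1": 10})

    def test_counts_match_simulator_truth(self, xy_sim):
        table = ax.count_by_chromosome(xy_sim.reads, xy_sim.ref.lengths)
        truth_counts = xy_sim.truth.groupby("chrom").size()
        for chrom, n in truth_counts.items():
            key = chrom[3:].upper() if chrom.startswith("chr") else chrom
            key = "MT" if key == "M" else key
            assert table.counts[key] == n
        assert table.total == len(xy_sim.reads)

    def test_counts_conserved_under_partition(self, xy_sim):
        reads = xy_sim.reads[:5000]
        lengths = xy_sim.ref.lengths
        whole = ax.count_by_chromosome(reads, lengths)
        parts = (ax.count_by_chromosome(reads[:1700], lengths)
                 + ax.count_by_chromosome(reads[1700:4100], lengths)
                 + ax.count_by_chromosome(reads[4100:], lengths))
        assert parts.counts == whole.counts

    def test_table_addition_rejects_length_mismatch(self):
        a = ChromCountTable(counts={"1": 5}, lengths={"1": 100})
        b = ChromCountTable(counts={"1": 5}, lengths={"1": 200})
        with pytest.raises(ValueError, match="length mismatch"):
            a + b

    def test_table_tsv_round_trip(self, tmp_path):
        t = ChromCountTable(counts={"1": 5, "X": 2}, lengths={"1": 100, "X": 50})
        path = tmp_path / "counts.tsv"
        t.to_tsv(path)
        back = ChromCountTable.from_tsv(path)
        assert back.counts == t.counts and back.lengths == t.lengths


@settings(derandomize=True, max_examples=50)
@given(st.lists(st.tuples(st.integers(0, 3), st.integers(20, 80),
                          st.booleans(), st.integers(0, 60)), max_size=30))
def test_filter_output_is_subset_and_stable(entries):
    """Property: filtering preserves order, retains a subset, and is a
    no-op on its own output."""
    reads = [make_read(read_id=f"r{i}", chrom=f"chr{c + 1}", seq="A" * ln,
                       strand="-" if neg else "+", mapq=q)
             for i, (c, ln, neg, q) in enumerate(entries)]
    kept, _ = ax.filter_reads(reads)
    ids = [r.read_id for r in reads]
    assert [r.read_id for r in kept] == [i for i in ids
                                         if i in {k.read_id for k in kept}]
    assert all(r.mapq >= 30 and 36 <= r.length <= 70 for r in kept)
    again, _ = ax.filter_reads(kept)
    assert again == kept
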