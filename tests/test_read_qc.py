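import random

import pytest

from cfnipt import (
    AlignedRead,
    QCConfig,
    SequencedRead,
    SimulationConfig,
    is_uniquely_mapped,
    passes_gc,
    passes_length,
    remove_duplicates,
    run_qc,
    simulate_reads,
    trim_3prime,
)
from cfnipt.read_qc import (
    FLAG_SECONDARY,
    FLAG_UNMAPPED,
    gc_fraction,
    qc_reads,
    read_fastq,
    read_sam,
)
from cfnipt.synthetic_data import QualityDecay, truth_to_alignments, write_fastq


def _read(bases, quals):
    return SequencedRead("r1", bases, tuple(quals))


class TestTrim3Prime:
    @pytest.mark.parametrize(
        "quals, expected_len",
        [
            ([30, 30, 30, 30], 4),  # no low-quality tail
            ([30, 30, 10, 10], 2),  # trailing run removed
            ([10, 10], 0),  # whole read at/below threshold
            ([30, 10, 30], 3),  # internal low base kept: only the tail is trimmed
            ([30, 30, 16], 3),  # quality must be strictly > threshold to stop
            ([30, 30, 15], 2),
        ],
    )
    def test_trailing_low_quality_removed(self, quals, expected_len):
        trimmed = trim_3prime(_read("A" * len(quals), quals), quality_threshold=15)
        assert len(trimmed) == expected_len
        assert trimmed.bases == "A" * expected_len


class TestLengthAndGC:
    @pytest.mark.parametrize("length, expected", [(50, True), (49, False), (0, False)])
    def test_length_boundary(self, length, expected):
        read = _read("A" * length, [30] * length)
        assert passes_length(read, min_length=50) is expected

    @pytest.mark.parametrize(
        "n_gc, expected",
        [(16, True), (20, False), (14, True), (18, True), (13, False)],  # /40 bases
    )
    def test_gc_band_inclusive(self, n_gc, expected):
        bases = "G" * n_gc + "A" * (40 - n_gc)
        read = _read(bases, [30] * 40)
        assert passes_gc(read, 0.35, 0.45) is expected

    def test_ambiguous_bases_count_as_non_gc(self):
        assert gc_fraction("GCNN") == pytest.approx(0.5)

    def test_empty_read_gc_is_an_error(self):
        with pytest.raises(ValueError):
            gc_fraction("")


class TestDedupAndUniqueness:
    def test_duplicates_collapse_opposite_strands_kept(self):
        alns = [
            AlignedRead("a", "chr1", 100, "+"),
            AlignedRead("b", "chr1", 100, "+"),  # duplicate of a
            AlignedRead("c", "chr1", 100, "-"),  # opposite strand: kept
            AlignedRead("d", "chr2", 100, "+"),
        ]
        kept = remove_duplicates(alns)
        assert [a.read_id for a in kept] == ["a", "c", "d"]

    def test_dedup_idempotent_and_order_independent(self):
        rng = random.Random(0)
        alns = [
            AlignedRead(f"r{i}", "chr1", rng.randrange(20), rng.choice("+-"))
            for i in range(60)
        ]
        once = remove_duplicates(alns)
        assert remove_duplicates(once) == once
        shuffled = alns[:]
        rng.shuffle(shuffled)
        assert remove_duplicates(shuffled) == once
        assert len(once) <= len(alns)

    @pytest.mark.parametrize(
        "mapq, flags, expected",
        [
            (37, 0, True),
            (0, 0, False),  # mapq 0: ambiguous placement
            (37, FLAG_UNMAPPED, False),
            (37, FLAG_SECONDARY, False),
        ],
    )
    def test_default_uniqueness_predicate(self, mapq, flags, expected):
        aln = AlignedRead("r", "chr1", 0, "+", mapq=mapq, flags=flags)
        assert is_uniquely_mapped(aln) is expected


class TestQCPipelineOracle:
    def test_vacuous_filters_retain_every_unique_read(self, toy_layout):
        # high plateau quality, no decay, long reads, exact 0.40 GC, no dups:
        # the read-level filters remove nothing, so retention is the count of
        # distinct unique-mapped sites.
        config = SimulationConfig(
            n_euploid=1, n_t18=0, n_t21=0, reads_per_sample=500,
            duplicate_rate=0.0, read_length_mean=60, read_length_sd=0.0,
            read_gc_mean=0.40, read_gc_sd=0.0,
            quality_decay=QualityDecay(start=30, end=30, tail=0),
            seed=13,
        )
        reads, truth = simulate_reads(config, toy_layout)
        seq_reads = [SequencedRead(r.read_id, r.bases, r.qualities) for r in reads]
        retained, report = run_qc(seq_reads, truth_to_alignments(truth))
        unique_truth = truth[truth["unique"] == 1]
        expected = len(unique_truth[["chrom", "start0", "strand"]].drop_duplicates())
        assert report.n_after_gc == len(reads)
        assert len(retained) == expected

    def test_retained_counts_match_brute_force_predicates(self, toy_layout):
        # independent oracle: re-apply the four filters inline on the truth table
        config = SimulationConfig(
            n_euploid=2, n_t18=1, n_t21=1, reads_per_sample=400,
            duplicate_rate=0.1, read_length_mean=55, read_length_sd=6.0,
            seed=21,
        )
        reads, truth = simulate_reads(config, toy_layout)
        seq_reads = [SequencedRead(r.read_id, r.bases, r.qualities) for r in reads]
        retained, _ = run_qc(seq_reads, truth_to_alignments(truth))

        unique_flag = dict(zip(truth["read_id"], truth["unique"]))
        surviving = set()
        for r in reads:
            quals = list(r.qualities)
            while quals and quals[-1] <= 15:
                quals.pop()
            n = len(quals)
            if n < 50:
                continue
            gc = sum(b in "GC" for b in r.bases[:n]) / n
            if not 0.35 <= gc <= 0.45:
                continue
            if not unique_flag[r.read_id]:
                continue
            surviving.add(r.read_id)
        brute_sites = {
            (row.chrom, row.start0, row.strand)
            for row in truth.itertuples()
            if row.read_id in surviving
        }
        assert len(retained) == len(brute_sites)

    def test_attrition_report_is_monotone(self, toy_layout):
        config = SimulationConfig(
            n_euploid=1, n_t18=0, n_t21=0, reads_per_sample=300,
            read_length_mean=52, read_length_sd=5.0, seed=3,
        )
        reads, truth = simulate_reads(config, toy_layout)
        seq_reads = [SequencedRead(r.read_id, r.bases, r.qualities) for r in reads]
        _, report = run_qc(seq_reads, truth_to_alignments(truth))
        counts = [report.n_input, report.n_after_trim_length, report.n_after_gc,
                  report.n_after_unique, report.n_after_dedup]
        assert counts == sorted(counts, reverse=True)
        assert report.to_frame()["removed"].sum() == report.n_input - report.n_after_dedup


class TestFileParsing:
    def test_fastq_roundtrip(self, tmp_path, toy_layout):
        config = SimulationConfig(n_euploid=1, n_t18=0, n_t21=0, reads_per_sample=20, seed=1)
        reads, _ = simulate_reads(config, toy_layout)
        path = tmp_path / "reads.fastq"
        write_fastq(reads, path)
        parsed = list(read_fastq(path))
        assert [p.id for p in parsed] == [r.read_id for r in reads]
        assert [p.bases for p in parsed] == [r.bases for r in reads]
        assert [p.qualities for p in parsed] == [r.qualities for r in reads]

    def test_sam_parsing_converts_coordinates_and_strand(self, tmp_path):
        sam = tmp_path / "toy.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unsorted\n"
            "@SQ\tSN:chr1\tLN:10000\n"
            # POS is 1-based in SAM; flag 16 = reverse strand; flag 4 = unmapped
            "r1\t0\tchr1\t101\t37\t4M\t*\t0\t0\tACGT\tIIII\n"
            "r2\t16\tchr1\t201\t37\t4M\t*\t0\t0\tGGCC\tIIII\n"
            "r3\t4\t*\t0\t0\t*\t*\t0\t0\tAAAA\tIIII\n"
            "r4\t0\tchr1\t301\t0\t4M\t*\t0\t0\tAATT\tIIII\n"
        )
        alns = list(read_sam(sam))
        assert (alns[0].start, alns[0].strand, alns[0].gc) == (100, "+", 0.5)
        assert (alns[1].start, alns[1].strand) == (200, "-")
        assert not is_uniquely_mapped(alns[2])  # unmapped
        assert not is_uniquely_mapped(alns[3])  # mapq 0
        assert is_uniquely_mapped(alns[0])


def test_qc_config_validation():
    with pytest.raises(ValueError):
        QCConfig(gc_min=0.5, gc_max=0.4)
    with pytest.raises(ValueError):
        QCConfig(min_length=0)
    with pytest.raises(ValueError):
        QCConfig(quality_threshold=-1)


def test_qc_reads_reports_stage_counts():
    good = SequencedRead("good", "G" * 20 + "A" * 30, tuple([30] * 50))
    short = SequencedRead("short", "ACGT", tuple([30] * 4))
    ids, report = qc_reads([good, short], QCConfig())
    assert ids == {"good"}
    assert (report.n_input, report.n_after_trim_length, report.n_after_gc) == (2, 1, 1)
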