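"""Probe scanning, SJ-file extraction/annotation and normalization."""

import pytest

from vegfa_splice import (
    SimConfig,
    annotate_sj_records,
    filter_junctions,
    normalize_per_billion_bases,
    normalize_per_million,
    parse_sj_file,
    scan_reads,
    simulate_reads,
)
from vegfa_splice.errors import ParseError, ValidationError
from vegfa_splice.junction_scan import JunctionCountTable, SJRecord, iter_reads
from vegfa_splice.locus_model import JunctionProbe
from vegfa_splice.sequtils import reverse_complement
from vegfa_splice.synthetic_data import truth_junction_counts, write_fastq


def brute_force_scan(reads, probes, both_strands=True):
    """Independent oracle: test every probe against every read directly."""
    counts = {p.junction_name: 0 for p in probes}
    for _, read in reads:
        views = [read]
        if both_strands:
            views.append(reverse_complement(read))
        for p in probes:
            if any(p.sequence in v for v in views):
                counts[p.junction_name] += 1
    return counts


class TestScanReads:
    def test_read_equal_to_probe_counts_once(self, toy_probes):
        probe = toy_probes[0]
        result = scan_reads([("r1", probe.sequence)], toy_probes)
        assert result.counts[probe.junction_name] == 1
        assert sum(result.counts.values()) == 1

    def test_reverse_complement_needs_both_strands(self, toy_probes):
        probe = toy_probes[3]
        read = "ACGT" * 5 + reverse_complement(probe.sequence) + "TTGCA"
        assert scan_reads([("r", read)], toy_probes).counts[probe.junction_name] == 1
        single = scan_reads([("r", read)], toy_probes, both_strands=False)
        assert single.counts[probe.junction_name] == 0

    def test_read_with_n_never_matches(self, toy_probes):
        probe = toy_probes[0]
        read = probe.sequence[:10] + "N" + probe.sequence[11:]
        assert sum(scan_reads([("r", read)], toy_probes).counts.values()) == 0

    def test_case_insensitive_matching(self, toy_probes, tmp_path):
        probe = toy_probes[0]
        path = tmp_path / "reads.fa"
        path.write_text(f">r1\n{probe.sequence.lower()}\n")
        assert scan_reads(path, toy_probes).counts[probe.junction_name] == 1

    def test_matches_brute_force_oracle_on_simulated_mixture(
        self, toy_locus, canonical, toy_probes
    ):
        sim = simulate_reads(
            toy_locus, canonical, SimConfig(seed=13, n_reads=5_000, error_rate=0.002)
        )
        result = scan_reads(sim.reads, toy_probes, sample_id="mix")
        assert result.counts == brute_force_scan(sim.reads, toy_probes)
        assert result.total_reads == 5_000

    def test_error_free_counts_equal_truth_and_8b_zero(self, toy_locus, canonical, toy_probes):
        sim = simulate_reads(
            toy_locus, canonical,
            SimConfig(seed=14, n_reads=20_000,
                      isoform_weights={"VEGFA_121": 1.0, "VEGFA_165": 1.0}),
        )
        result = scan_reads(sim.reads, toy_probes)
        truth = truth_junction_counts(sim.truth, min_overhang=11)
        for probe in toy_probes:
            assert result.counts[probe.junction_name] == truth.get(probe.junction_name, 0)
        assert all(result.counts[n] == 0 for n in result.counts if n.endswith("-8b"))

    def test_invalid_probe_rejected(self):
        with pytest.raises(ValidationError):
            scan_reads([("r", "ACGT")], [])
        bad = JunctionProbe("x-y", 2, "AN", "GT")
        with pytest.raises(ValidationError, match="non-ACGT"):
            scan_reads([("r", "ACGT")], [bad])

    def test_malformed_fastq_names_record(self, toy_probes, tmp_path):
        path = tmp_path / "broken.fq"
        path.write_text("@r1\nACGT\n+\nII\n")  # quality shorter than sequence
        with pytest.raises(ParseError, match="record 0"):
            scan_reads(path, toy_probes)

    def test_gzip_detected_by_magic_bytes(self, toy_probes, tmp_path):
        import gzip

        probe = toy_probes[0]
        path = tmp_path / "reads.fastq"  # no .gz extension on purpose
        with gzip.open(path, "wt") as handle:
            handle.write(f"@r1\n{probe.sequence}\n+\n{'I' * 22}\n")
        assert scan_reads(path, toy_probes).counts[probe.junction_name] == 1


class TestNormalizePerMillion:
    def test_simple_and_zero_counts(self, toy_probes):
        result = scan_reads([("r", "A" * 30)], toy_probes)
        result = normalize_per_million(
            type(result)(result.sample_id, 1_000_000,
                         {**result.counts, toy_probes[0].junction_name: 5})
        )
        assert result.per_million[toy_probes[0].junction_name] == 5.0
        assert result.per_million[toy_probes[1].junction_name] == 0.0

    def test_survey_scale_arithmetic(self, toy_probes):
        # 31,614 hits among 6.9e9 reads is ~4.58 hits per million.
        from vegfa_splice.junction_scan import ScanResult

        result = ScanResult("compendium2", 6_900_000_000,
                            {toy_probes[0].junction_name: 31_614})
        normalized = normalize_per_million(result)
        assert normalized.per_million[toy_probes[0].junction_name] == pytest.approx(
            31_614 / 6_900, rel=1e-9
        )

    def test_zero_total_reads_errors(self, toy_probes):
        from vegfa_splice.junction_scan import ScanResult

        with pytest.raises(ValidationError):
            normalize_per_million(ScanResult("s", 0, {"x": 0}))


class TestParseSJ:
    WINDOW = ("chr6", 43737945, 43754224)

    def write(self, tmp_path, lines):
        path = tmp_path / "SJ.out.tab"
        path.write_text("".join(line + "\n" for line in lines))
        return path

    def test_window_containment(self, tmp_path):
        path = self.write(tmp_path, [
            "chr6\t43749825\t43752277\t1\t1\t0\t12\t3\t38",   # inside
            "chr7\t43749825\t43752277\t1\t1\t0\t9\t0\t30",    # wrong chrom
            "chr6\t43737000\t43745000\t1\t1\t0\t4\t0\t20",    # straddles start
            "chr6\t43754000\t43755000\t1\t1\t0\t4\t0\t20",    # straddles end
        ])
        records = parse_sj_file(path, self.WINDOW)
        assert len(records) == 1
        assert records[0].unique_count == 12

    def test_wrong_column_count_names_line(self, tmp_path):
        path = self.write(tmp_path, ["chr6\t1\t2\t1\t1\t0\t3\t0"])
        with pytest.raises(ParseError, match="line 1"):
            parse_sj_file(path)

    def test_non_integer_coordinate_names_line(self, tmp_path):
        path = self.write(tmp_path, [
            "chr6\t43749825\t43752277\t1\t1\t0\t12\t3\t38",
            "chr6\txyz\t43752277\t1\t1\t0\t12\t3\t38",
        ])
        with pytest.raises(ParseError, match="line 2"):
            parse_sj_file(path)


class TestAnnotateSJ:
    def test_known_intron_gets_junction_name(self, real_catalog):
        from vegfa_splice import build_junction_catalog

        junctions = build_junction_catalog(real_catalog, ["7b"], ["8a"])
        record = SJRecord("chr6", 43749825, 43752277, 1, 1, 0, 7, 0, 30)
        assert annotate_sj_records([record], junctions) == {"7b-8a": 7}

    def test_unknown_intron_labeled_novel(self, toy_junctions):
        record = SJRecord("toy1", 1000, 1100, 1, 1, 0, 3, 0, 20)
        row = annotate_sj_records([record], toy_junctions)
        assert row == {"novel:1000-1100": 3}

    def test_duplicate_introns_summed(self, toy_junctions):
        j = toy_junctions[0]
        records = [
            SJRecord("toy1", j.intron_first, j.intron_last, 1, 1, 0, 4, 0, 20),
            SJRecord("toy1", j.intron_first, j.intron_last, 1, 1, 0, 6, 0, 25),
        ]
        assert annotate_sj_records(records, toy_junctions) == {j.name: 10}


class TestCountTable:
    def make(self):
        return JunctionCountTable.from_rows({
            "s1": {"5-8a": 30, "7b-8a": 100, "novel:10-20": 15},
            "s2": {"5-8a": 60, "7b-8a": 120, "novel:10-20": 10},
        })

    @pytest.mark.parametrize(
        "bounds,expected",
        [
            ((20, 200), {"5-8a", "novel:10-20"}),
            ((0, 10**9), {"5-8a", "7b-8a", "novel:10-20"}),
            ((26, 89), set()),
            ((25, 90), {"5-8a", "novel:10-20"}),  # boundary-inclusive
        ],
    )
    def test_filter_total_count_bounds(self, bounds, expected):
        table = filter_junctions(self.make(), *bounds)
        assert set(table.counts.columns) == expected

    def test_per_billion_normalization_and_round_trip(self):
        table = normalize_per_billion_bases(
            self.make(), {"s1": 2e9, "s2": 4e9}
        )
        assert table.normalized.loc["s1", "7b-8a"] == 50.0
        assert table.normalized.loc["s2", "7b-8a"] == pytest.approx(30.0)
        assert table.denormalized().equals(table.counts)

    def test_doubling_denominator_halves_values(self):
        single = normalize_per_billion_bases(self.make(), {"s1": 1e9, "s2": 1e9})
        double = normalize_per_billion_bases(self.make(), {"s1": 2e9, "s2": 2e9})
        assert ((single.normalized / double.normalized) == 2).all().all()

    def test_zero_denominator_errors(self):
        with pytest.raises(ValidationError):
            normalize_per_billion_bases(self.make(), {"s1": 0, "s2": 1e9})

    def test_filter_bounds_validated(self):
        with pytest.raises(ValidationError):
            filter_junctions(self.make(), 10, 5)
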