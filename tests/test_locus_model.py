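"""Exon catalog, junction/probe construction and terminal-ambiguity checks."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vegfa_splice import (
    ExonDef,
    assemble_transcript,
    build_junction_catalog,
    build_probes,
    extract_probe,
    probe_cross_match_audit,
    shared_terminal_ambiguity,
)
from vegfa_splice.errors import ParseError, ValidationError
from vegfa_splice.locus_model import (
    DEFAULT_ACCEPTORS,
    DEFAULT_DONORS,
    ExonCatalog,
    JunctionDef,
    JunctionProbe,
    LocusReference,
    load_exon_catalog,
    read_probe_fasta,
    write_exon_catalog,
    write_probe_fasta,
)
from vegfa_splice.sequtils import longest_shared_suffix

dna = st.text(alphabet="ACGT", min_size=0, max_size=40)


class TestExonCatalog:
    def test_default_catalog_coordinates(self, real_catalog):
        exon = real_catalog["8a"]
        assert (exon.start, exon.end) == (43752278, 43752343)
        assert exon.length == 66

    def test_contiguous_terminal_and_internal_segments(self, real_catalog):
        # 8a|8b, 6a|6b|6c, 7a|7b and 1a|1b are genomically contiguous.
        for left, right in (("8a", "8b"), ("6a", "6b"), ("6b", "6c"),
                            ("7a", "7b"), ("1a", "1b")):
            assert real_catalog[right].start == real_catalog[left].end + 1

    def test_round_trip_through_tab_format(self, real_catalog, tmp_path):
        path = tmp_path / "catalog.tsv"
        write_exon_catalog(real_catalog, path)
        reloaded = load_exon_catalog(path)
        assert reloaded.names == real_catalog.names
        assert all(reloaded[n] == real_catalog[n] for n in real_catalog)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("name\tchrom\tstart\tend\tstrand\nx\tchr6\tNaN\t5\t+\n")
        with pytest.raises(ParseError, match="line 2"):
            load_exon_catalog(path)

    def test_duplicate_name_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            ExonCatalog([ExonDef("a", "c", 1, 5), ExonDef("a", "c", 10, 20)])

    def test_inverted_coordinates_rejected(self):
        with pytest.raises(ValidationError, match="start"):
            ExonDef("a", "c", 10, 5)


class TestJunctionCatalog:
    def test_default_pairs_yield_ten_junctions(self, real_catalog):
        junctions = build_junction_catalog(real_catalog, DEFAULT_DONORS, DEFAULT_ACCEPTORS)
        assert len(junctions) == 10
        assert [j.name for j in junctions][:2] == ["4-8a", "4-8b"]

    def test_intron_coordinates_from_exon_bounds(self, real_catalog):
        junctions = build_junction_catalog(real_catalog, ["7b"], ["8a"])
        (j,) = junctions
        assert (j.intron_first, j.intron_last) == (43749825, 43752277)

    def test_reversed_orientation_rejected(self, real_catalog):
        with pytest.raises(ValidationError, match="forward"):
            build_junction_catalog(real_catalog, ["8a"], ["7b"])

    def test_name_must_match_exons(self):
        with pytest.raises(ValidationError, match="donor-acceptor"):
            JunctionDef("x-y", "a", "b", 10, 20)


class TestProbes:
    def test_default_flank_gives_22_base_probes(self, toy_probes):
        assert all(len(p.sequence) == 22 for p in toy_probes)
        assert all(p.sequence == p.donor_half + p.acceptor_half for p in toy_probes)

    @pytest.mark.parametrize("flank", [1, 2, 5, 11, 15])
    def test_probe_equals_direct_genomic_slices(self, toy_locus, toy_junctions, flank):
        # Independent oracle: slice the locus string directly.
        off = toy_locus.region_start
        for junction in toy_junctions:
            probe = extract_probe(toy_locus, junction, flank)
            donor = toy_locus.sequence[junction.donor_end - flank + 1 - off:
                                       junction.donor_end - off + 1]
            acceptor = toy_locus.sequence[junction.acceptor_start - off:
                                          junction.acceptor_start + flank - off]
            assert probe.sequence == donor + acceptor
            assert len(probe.sequence) == 2 * flank

    def test_flank_exceeding_exon_names_the_exon(self, toy_locus, toy_junctions):
        j5 = next(j for j in toy_junctions if j.name == "5-8a")
        with pytest.raises(ValidationError, match="exon 5"):
            extract_probe(toy_locus, j5, flank=31)  # exon 5 is 30 bases

    def test_probe_fasta_round_trip(self, toy_probes, tmp_path):
        path = tmp_path / "probes.fa"
        write_probe_fasta(toy_probes, path)
        reloaded = read_probe_fasta(path)
        assert [(p.junction_name, p.sequence) for p in reloaded] == [
            (p.junction_name, p.sequence) for p in toy_probes
        ]


class TestTranscripts:
    def test_real_terminal_exon_length(self, real_catalog):
        # Contiguous 8a+8b models the full canonical terminal exon 8.
        assert real_catalog["8a"].length + real_catalog["8b"].length == 66 + 1880 == 1946

    def test_assembled_length_is_sum_of_exon_lengths(self, toy_locus):
        chain = ("1a", "1b", "2", "3", "4", "5", "7a", "7b", "8a", "8b")
        t = assemble_transcript(toy_locus, "t", chain)
        assert t.length == sum(toy_locus.exons[n].length for n in chain)

    def test_single_exon_transcript(self, toy_locus):
        t = assemble_transcript(toy_locus, "solo", ["3"])
        assert t.sequence == toy_locus.exon_sequence("3")
        assert t.junction_offsets == ()

    def test_contiguous_exons_yield_no_junction(self, toy_locus):
        t = assemble_transcript(toy_locus, "t", ["8a", "8b"])
        assert t.junctions == ()

    def test_out_of_order_chain_rejected(self, toy_locus):
        with pytest.raises(ValidationError, match="out of order"):
            assemble_transcript(toy_locus, "t", ["8a", "7b"])


class TestSharedTerminalAmbiguity:
    def test_exon_vs_itself_is_full_length(self, toy_locus):
        assert shared_terminal_ambiguity(toy_locus, "5", "5") == toy_locus.exons["5"].length

    def test_engineered_7b_8a_suffix(self, toy_locus):
        assert shared_terminal_ambiguity(toy_locus, "7b", "8a") == 3
        assert shared_terminal_ambiguity(toy_locus, "8a", "7b") == 3

    def test_disjoint_alphabet_exons(self):
        exons = ExonCatalog([ExonDef("a", "c", 1, 6), ExonDef("b", "c", 11, 16)])
        locus = LocusReference("c", 1, 16, "AAAAAA" + "GGGG" + "CCCCCC", exons)
        assert shared_terminal_ambiguity(locus, "a", "b") == 0

    @settings(derandomize=True, max_examples=200)
    @given(a=dna, b=dna)
    def test_matches_brute_force_and_is_symmetric(self, a, b):
        def brute(x, y):
            best = 0
            for s in range(1, min(len(x), len(y)) + 1):
                if x[-s:] == y[-s:]:
                    best = s
            return best

        assert longest_shared_suffix(a, b) == brute(a, b) == longest_shared_suffix(b, a)


class TestProbeCrossMatchAudit:
    def test_cognate_junction_listed_specific(self, toy_probes, canonical):
        audit = {a.junction_name: a for a in
                 probe_cross_match_audit(toy_probes, list(canonical.values()))}
        entry = audit["7b-8a"]
        assert "VEGFA_165" in entry.containing_transcripts
        assert entry.specific

    def test_8b_probe_absent_from_readthrough_transcripts(self, toy_probes, canonical):
        # The 7b-8b probe differs from the contiguous 8a|8b 22-mer in its
        # donor half (shared suffix 3 < flank 11), so it cannot occur in any
        # canonical transcript carrying the read-through exon 8.
        audit = {a.junction_name: a for a in
                 probe_cross_match_audit(toy_probes, list(canonical.values()))}
        for name in ("4-8b", "5-8b", "6a-8b", "7a-8b", "7b-8b"):
            assert audit[name].containing_transcripts == ()
            assert audit[name].specific

    def test_flank_within_shared_suffix_is_non_specific(self, toy_locus, toy_junctions, canonical):
        # At flank 2 <= engineered shared suffix 3, the 7b-8b probe equals
        # the contiguous 8a|8b 2+2-mer and matches read-through transcripts.
        j = next(j for j in toy_junctions if j.name == "7b-8b")
        probe = extract_probe(toy_locus, j, flank=2)
        audit = probe_cross_match_audit([probe], list(canonical.values()))
        assert not audit[0].specific
        assert audit[0].containing_transcripts != ()

    @pytest.mark.parametrize("flank", [4, 11])
    def test_probes_absent_from_junction_free_transcripts(
        self, toy_locus, toy_junctions, canonical, b_isoforms, flank
    ):
        # Exhaustive substring oracle: with flank > shared suffix, a probe
        # never occurs in a transcript lacking its junction.
        probes = build_probes(toy_locus, toy_junctions, flank)
        pool = list(canonical.values()) + list(b_isoforms.values())
        for probe in probes:
            for t in pool:
                if probe.junction_name not in t.junctions:
                    assert probe.sequence not in t.sequence


def test_probe_halves_invariant_across_all_feasible_flanks(toy_locus, toy_junctions):
    max_flank = min(toy_locus.exons[n].length
                    for n in set(DEFAULT_DONORS) | set(DEFAULT_ACCEPTORS))
    for flank in range(1, max_flank + 1):
        for junction in toy_junctions:
            probe = extract_probe(toy_locus, junction, flank)
            assert len(probe.sequence) == 2 * flank
            assert probe.sequence == probe.donor_half + probe.acceptor_half
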