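"""Alignment column classification, lift-over, marker intersection, VCF output."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import plastokit as pk

from conftest import scan_columns_oracle


class TestReadAlignment:
    def test_toy_round_trip(self, toy_alignment, tmp_path):
        path = tmp_path / "al.fasta"
        toy_alignment.to_fasta(path)
        al = pk.read_alignment(path)
        assert al.ids == ["s1", "s2", "s3"] and al.length == 9

    def test_empty_file_rejected(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(pk.FormatError):
            pk.read_alignment(path)

    def test_ragged_lengths_name_offender(self):
        with pytest.raises(pk.FormatError, match="s2"):
            pk.Alignment(["s1", "s2"], ["ACGT", "ACG"])

    def test_mixed_case_uppercased(self):
        al = pk.Alignment(["a"], ["acgTn-"])
        assert al.seqs == ["ACGTN-"]


class TestClassifyColumns:
    def test_toy_worked_example(self, toy_alignment):
        vt, ie = pk.classify_columns(toy_alignment)
        assert vt.n_snvs == 1
        row = vt.table.iloc[0]
        assert row["aln_pos"] == 3
        assert (row["allele_s1"], row["allele_s2"], row["allele_s3"]) == ("G", "A", "G")
        assert ie.n_events == 1
        ev = ie.table.iloc[0]
        assert (ev["start"], ev["end"], ev["pattern"]) == (7, 7, "110")

    def test_invariant_alignment(self):
        al = pk.Alignment(["a", "b"], ["ACGT", "ACGT"])
        vt, ie = pk.classify_columns(al)
        assert vt.n_snvs == 0 and ie.n_events == 0

    def test_n_only_variation_is_not_snv(self):
        al = pk.Alignment(["a", "b", "c"], ["ANT", "AAT", "AAT"])
        vt, _ = pk.classify_columns(al)
        assert vt.n_snvs == 0

    def test_min_minor_count_filters_singletons(self):
        al = pk.Alignment(["a", "b", "c"], ["AAG", "AAG", "ATG"])
        assert pk.classify_columns(al, min_minor_count=1)[0].n_snvs == 1
        assert pk.classify_columns(al, min_minor_count=2)[0].n_snvs == 0

    def test_adjacent_distinct_gap_patterns_are_separate_events(self):
        al = pk.Alignment(["a", "b"], ["A-GA", "AG-A"])
        _, ie = pk.classify_columns(al)
        assert ie.n_events == 2
        assert ie.n_columns == 2

    def test_snv_count_invariant_under_reordering(self, toy_alignment):
        shuffled = pk.Alignment(
            list(reversed(toy_alignment.ids)), list(reversed(toy_alignment.seqs))
        )
        assert pk.classify_columns(shuffled)[0].n_snvs == pk.classify_columns(toy_alignment)[0].n_snvs

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.data())
    def test_matches_per_column_scan_oracle(self, data):
        nseq = data.draw(st.integers(2, 8))
        ncol = data.draw(st.integers(1, 60))
        seqs = [
            "".join(data.draw(st.sampled_from("ACGTN-")) for _ in range(ncol))
            for _ in range(nseq)
        ]
        ids = [f"s{i}" for i in range(nseq)]
        vt, ie = pk.classify_columns(pk.Alignment(ids, seqs))
        oracle_snvs, oracle_events = scan_columns_oracle(ids, [s.upper() for s in seqs])
        assert vt.positions() == oracle_snvs
        got_events = list(zip(ie.table["start"], ie.table["end"])) if ie.n_events else []
        assert got_events == oracle_events


class TestCoordinateMap:
    def test_toy_hand_counts(self, toy_alignment):
        cmap = pk.build_coordinate_map(toy_alignment, "s1")
        assert pk.liftover(cmap, 1, "to_ref") == 1
        assert pk.liftover(cmap, 7, "to_ref") is None  # gap in the reference row
        assert pk.liftover(cmap, 8, "to_ref") == 7
        assert pk.liftover(cmap, 9, "to_ref") == 8

    def test_round_trip_identity_on_nongap_columns(self, toy_alignment):
        cmap = pk.build_coordinate_map(toy_alignment, "s1")
        for col in range(1, toy_alignment.length + 1):
            ref = cmap.to_ref(col)
            if ref is not None:
                assert cmap.to_alignment(ref) == col

    def test_out_of_range_and_unknown_id(self, toy_alignment):
        cmap = pk.build_coordinate_map(toy_alignment, "s1")
        with pytest.raises(pk.ParameterError):
            cmap.to_ref(10)
        with pytest.raises(pk.ParameterError):
            pk.build_coordinate_map(toy_alignment, "nope")

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from("ACGT-"), min_size=1, max_size=80))
    def test_round_trip_on_random_reference_rows(self, chars):
        if all(c == "-" for c in chars):
            chars[0] = "A"
        row = "".join(chars)
        al = pk.Alignment(["ref", "other"], [row, "A" * len(row)])
        cmap = pk.build_coordinate_map(al, "ref")
        for col in range(1, len(row) + 1):
            ref = cmap.to_ref(col)
            if ref is None:
                assert row[col - 1] == "-"
            else:
                assert cmap.to_alignment(ref) == col


class TestIntersectMarkers:
    def test_set_arithmetic_worked_example(self, tmp_path):
        al = pk.Alignment(["ref", "x"], ["A" * 50, "A" * 50])
        cmap = pk.build_coordinate_map(al, "ref")
        table = pk.VariantTable(
            __import__("pandas").DataFrame({"aln_pos": [10, 20, 30, 40]})
        )
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        a.write_text("20\n30\n50\n")
        b.write_text("30\n40\n")
        mi = pk.intersect_markers(table, cmap, a, b)
        assert mi.shared_with_a == {20, 30}
        assert mi.shared_with_b == {30, 40}
        assert mi.high_confidence == {30}
        assert mi.high_confidence <= mi.shared_with_a and mi.high_confidence <= mi.shared_with_b

    def test_empty_lists(self, toy_alignment):
        vt, _ = pk.classify_columns(toy_alignment)
        cmap = pk.build_coordinate_map(toy_alignment, "s1")
        mi = pk.intersect_markers(vt, cmap, [], [])
        assert not mi.shared_with_a and not mi.shared_with_b and not mi.high_confidence

    def test_full_lists_give_all_snvs(self, toy_alignment):
        vt, _ = pk.classify_columns(toy_alignment)
        cmap = pk.build_coordinate_map(toy_alignment, "s1")
        refs = [cmap.to_ref(p) for p in vt.positions()]
        mi = pk.intersect_markers(vt, cmap, refs, refs)
        assert mi.high_confidence == set(refs)

    def test_malformed_tsv_reports_line(self, toy_alignment, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text("10\nxyz\n")
        vt, _ = pk.classify_columns(toy_alignment)
        cmap = pk.build_coordinate_map(toy_alignment, "s1")
        with pytest.raises(pk.FormatError, match=":2"):
            pk.intersect_markers(vt, cmap, bad, [])


class TestWriteVariants:
    def test_toy_vcf_row(self, toy_alignment, tmp_path):
        vt, _ = pk.classify_columns(toy_alignment)
        cmap = pk.build_coordinate_map(toy_alignment, "s1")
        ref_seq = toy_alignment.row("s1").replace("-", "")
        pk.write_variants(vt, cmap, ref_seq, tmp_path / "v.tsv", tmp_path / "v.vcf")
        lines = [l for l in (tmp_path / "v.vcf").read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1
        chrom, pos, _, ref, alt = lines[0].split("\t")[:5]
        assert (pos, ref, alt) == ("3", "G", "A")
        header = (tmp_path / "v.vcf").read_text().splitlines()[0]
        assert header == "##fileformat=VCFv4.2"

    def test_empty_table_headers_only(self, tmp_path):
        al = pk.Alignment(["r", "s"], ["ACGT", "ACGT"])
        vt, _ = pk.classify_columns(al)
        cmap = pk.build_coordinate_map(al, "r")
        pk.write_variants(vt, cmap, "ACGT", tmp_path / "v.tsv", tmp_path / "v.vcf")
        vcf = (tmp_path / "v.vcf").read_text().splitlines()
        assert all(l.startswith("#") for l in vcf)

    def test_multiallelic_alt_is_comma_separated(self, tmp_path):
        al = pk.Alignment(["r", "s", "t"], ["AAC", "ATC", "AGC"])
        vt, _ = pk.classify_columns(al)
        cmap = pk.build_coordinate_map(al, "r")
        pk.write_variants(vt, cmap, "AAC", tmp_path / "v.tsv", tmp_path / "v.vcf")
        row = [l for l in (tmp_path / "v.vcf").read_text().splitlines() if not l.startswith("#")][0]
        assert row.split("\t")[4] == "G,T"

    def test_ref_mismatch_raises(self, toy_alignment, tmp_path):
        vt, _ = pk.classify_columns(toy_alignment)
        cmap = pk.build_coordinate_map(toy_alignment, "s1")
        with pytest.raises(pk.FormatError, match="REF mismatch"):
            pk.write_variants(vt, cmap, "ACTTACGT", tmp_path / "v.tsv", tmp_path / "v.vcf")


class TestPipelineRecovery:
    def test_planted_substitutions_recovered_without_indels(self, small_genome):
        seq, _ = small_genome
        nwk = "((A:0.002,B:0.002):0.002,(C:0.002,D:0.002):0.002);"
        pop = pk.simulate_population(seq, pk.PopulationSpec(tree=nwk, seed=31))
        vt, ie = pk.classify_columns(pop.alignment)
        truth_cols = sorted(pop.variant_truth.query("polymorphic")["aln_col"])
        assert vt.positions() == truth_cols
        assert ie.n_events == 0

    def test_ungapped_substitutions_recovered_with_indels(self, small_genome):
        seq, _ = small_genome
        nwk = "((A:0.002,B:0.002):0.002,(C:0.002,D:0.002):0.002);"
        pop = pk.simulate_population(
            seq, pk.PopulationSpec(tree=nwk, indel_rate=0.05, seed=32)
        )
        vt, _ = pk.classify_columns(pop.alignment)
        truth_cols = set(pop.variant_truth.query("polymorphic and not has_gap")["aln_col"])
        assert truth_cols <= set(vt.positions())
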