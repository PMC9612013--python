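"""Read-to-segment mapping, conformation calling, and ratio estimation."""
import math

import numpy as np
import pytest

import plastokit as pk
from plastokit._seq import revcomp

from conftest import truth_spanning_reads


def _hit(label, rs, re, fs, fe, strand, full=False):
    return pk.SegmentHit(label, rs, re, fs, fe, strand, 1.0, covers_region=full)


class TestClassifySpanningRead:
    """Worked triples straight from the conformation definition."""

    def test_same_orientation_flanks_are_canonical(self, small_genome):
        _, part = small_genome
        hits = [
            _hit("LSC", 1, 600, 2401, 3000, "+"),
            _hit("IR1", 601, 1000, 1, 400, "+", full=True),
            _hit("SSC", 1001, 1600, 1, 600, "+"),
        ]
        call = pk.classify_spanning_read(hits, part, anchor_min=500)
        assert call.call == "canonical" and call.spanning

    def test_opposite_orientation_flanks_are_noncanonical(self, small_genome):
        _, part = small_genome
        hits = [
            _hit("LSC", 1, 600, 2401, 3000, "+"),
            _hit("IR1", 601, 1000, 1, 400, "+", full=True),
            _hit("SSC", 1001, 1600, 201, 800, "-"),
        ]
        assert pk.classify_spanning_read(hits, part, anchor_min=500).call == "noncanonical"

    def test_short_anchor_is_unclassified_but_spanning(self, small_genome):
        _, part = small_genome
        hits = [
            _hit("LSC", 1, 600, 2401, 3000, "+"),
            _hit("IR1", 601, 1000, 1, 400, "+", full=True),
            _hit("SSC", 1001, 1100, 1, 100, "+"),
        ]
        call = pk.classify_spanning_read(hits, part, anchor_min=500)
        assert call.call == "unclassified" and call.spanning

    def test_partial_ir_coverage_is_not_spanning(self, small_genome):
        _, part = small_genome
        hits = [
            _hit("LSC", 1, 600, 2401, 3000, "+"),
            _hit("IR1", 601, 900, 1, 300, "+"),
        ]
        call = pk.classify_spanning_read(hits, part, anchor_min=500)
        assert call.call == "unclassified" and not call.spanning

    def test_double_ir_span_must_agree(self, small_genome):
        _, part = small_genome
        agree = [
            _hit("LSC", 1, 600, 2401, 3000, "+"),
            _hit("IR1", 601, 1000, 1, 400, "+", full=True),
            _hit("SSC", 1001, 1800, 1, 800, "+"),
            _hit("IR2", 1801, 2200, 1, 400, "+", full=True),
            _hit("LSC", 2201, 2800, 1, 600, "+"),
        ]
        assert pk.classify_spanning_read(agree, part, anchor_min=500).call == "canonical"
        # the two triples disagree: (LSC+, IR1, SSC+) says canonical while
        # (SSC+, IR2, LSC-) says noncanonical
        conflict = agree[:4] + [_hit("LSC", 2201, 2800, 1, 600, "-")]
        assert pk.classify_spanning_read(conflict, part, anchor_min=500).call == "unclassified"


class TestMapReadSegments:
    def test_read_inside_lsc_is_one_forward_hit(self, small_genome):
        seq, part = small_genome
        read = seq[400:1600]
        hits = pk.map_read_segments(read, seq, part)
        assert len(hits) == 1
        h = hits[0]
        assert (h.label, h.strand) == ("LSC", "+")
        assert (h.ref_start, h.ref_end) == (401, 1600)

    def test_junction_read_yields_three_ordered_hits(self, small_genome):
        seq, part = small_genome
        read = seq[2400:4000]  # LSC tail -> IR1 -> SSC head on the canonical isoform
        hits = pk.map_read_segments(read, seq, part)
        assert [h.label for h in hits] == ["LSC", "IR1", "SSC"]
        assert all(h.strand == "+" for h in hits)
        assert hits[1].covers_region
        assert [h.read_start for h in hits] == sorted(h.read_start for h in hits)

    def test_reverse_strand_read(self, small_genome):
        seq, part = small_genome
        hits = pk.map_read_segments(revcomp(seq[2400:4000]), seq, part)
        assert [h.label for h in hits] == ["SSC", "IR1", "LSC"]
        assert all(h.strand == "-" for h in hits)

    def test_short_and_empty_reads(self, small_genome):
        seq, part = small_genome
        assert pk.map_read_segments("", seq, part) == []
        assert pk.map_read_segments("ACGTACGT", seq, part) == []


class TestPhaseReads:
    def test_error_free_phasing_is_perfect(self, phasing_setup):
        seq, part, iso_b, records, truth = phasing_setup
        result, calls = pk.phase_reads(records, seq, part)
        label_of = {"canonical": "A", "noncanonical": "B"}
        tr = truth.set_index("read")["isoform"]
        for call in calls.values():
            if call.call != "unclassified":
                assert tr[call.read_id] == label_of[call.call]
        # every truth-defined spanning read is classified to its truth label
        spanning = truth_spanning_reads(truth, part, len(seq))
        for rid in spanning:
            assert calls[rid].call != "unclassified"
        assert result.n_canonical + result.n_noncanonical >= len(spanning) > 0

    def test_mutual_exclusivity_of_read_sets(self, phasing_setup, tmp_path):
        seq, part, _, records, _ = phasing_setup
        result, _ = pk.phase_reads(records, seq, part, out_dir=tmp_path)
        sets = [set(result.reads_canonical), set(result.reads_noncanonical),
                set(result.reads_unclassified)]
        assert not (sets[0] & sets[1]) and not (sets[0] & sets[2]) and not (sets[1] & sets[2])
        assert sum(map(len, sets)) == result.n_reads
        for name in ("canonical", "noncanonical", "unclassified", "calls.tsv"):
            assert any(p.name.startswith(name) for p in tmp_path.iterdir())

    def test_mixture_zero_has_no_noncanonical_calls(self, small_genome):
        seq, part = small_genome
        iso_b = pk.build_isoform(seq, part, "noncanonical")
        params = pk.ReadSimParams(n_reads=80, length_mean=1800, length_sd=300,
                                  mismatch_rate=0, ins_rate=0, del_rate=0,
                                  mixture_ratio=0.0, seed=8)
        records, _ = pk.simulate_reads(seq, iso_b, params)
        result, _ = pk.phase_reads(records, seq, part)
        assert result.n_noncanonical == 0 and result.n_canonical > 0

    def test_short_reads_span_nothing(self, small_genome):
        seq, part = small_genome
        iso_b = pk.build_isoform(seq, part, "noncanonical")
        params = pk.ReadSimParams(n_reads=30, length_mean=200, length_sd=0,
                                  mismatch_rate=0, ins_rate=0, del_rate=0,
                                  mixture_ratio=0.5, seed=9)
        records, _ = pk.simulate_reads(seq, iso_b, params)
        result, _ = pk.phase_reads(records, seq, part)
        assert result.n_spanning == 0
        assert result.ratio_noncanonical is None

    def test_noisy_reads_stay_accurate(self):
        """~5% total error: classified spanning reads still match truth >=99%."""
        spec = pk.PlastomeSpec(lsc_len=6000, ssc_len=2000, ir_len=1000,
                               gc_content=0.38, seed=11)
        seq, part = pk.simulate_plastome(spec)
        iso_b = pk.build_isoform(seq, part, "noncanonical")
        params = pk.ReadSimParams(n_reads=150, length_mean=3500, length_sd=600,
                                  mismatch_rate=0.02, ins_rate=0.02, del_rate=0.01,
                                  mixture_ratio=0.5, seed=12)
        records, truth = pk.simulate_reads(seq, iso_b, params)
        _, calls = pk.phase_reads(records, seq, part)
        tr = truth.set_index("read")["isoform"]
        label_of = {"canonical": "A", "noncanonical": "B"}
        classified = [c for c in calls.values() if c.call != "unclassified"]
        assert len(classified) >= 20
        correct = sum(1 for c in classified if tr[c.read_id] == label_of[c.call])
        assert correct / len(classified) >= 0.99
        # generously-anchored truth-spanning reads are not lost to noise
        spanning = truth_spanning_reads(truth, part, len(seq), anchor_min=700)
        recovered = sum(1 for rid in spanning if calls[rid].call != "unclassified")
        assert recovered / len(spanning) >= 0.9


class TestEstimateRatio:
    def test_worked_example_nine_eleven(self):
        """The 9-vs-11 spanning-read split: ratio 0.55, no evidence against 1:1."""
        ratio, ci, p = pk.estimate_ratio(9, 11)
        assert ratio == pytest.approx(0.55)
        # exact two-sided binomial at n=20, p0=0.5: 1 - P(X=10) = 1 - 184756/2^20
        assert p == pytest.approx(1 - 184756 / 2**20, abs=1e-12)
        assert round(p, 4) == 0.8238
        assert ci[0] < 0.5 < ci[1]

    def test_one_sided_extreme(self):
        ratio, _, p = pk.estimate_ratio(0, 7)
        assert ratio == 1.0
        assert p == pytest.approx(2 * 0.5**7, abs=1e-12)

    def test_perfect_balance(self):
        ratio, _, p = pk.estimate_ratio(5, 5)
        assert ratio == 0.5 and p == 1.0

    def test_zero_counts_undefined(self):
        with pytest.raises(pk.UndefinedRatioError):
            pk.estimate_ratio(0, 0)

    def test_wilson_interval_calibration(self):
        """95% Wilson CI covers the true 0.5 in >=90/100 binomial replicates."""
        rng = np.random.default_rng(123)
        covered = 0
        for _ in range(100):
            k = rng.binomial(60, 0.5)
            _, (lo, hi), _ = pk.estimate_ratio(60 - k, k)
            covered += lo <= 0.5 <= hi
        assert covered >= 90


class TestDepthRatio:
    def test_collapsed_mapping_doubles_ir_depth(self, small_genome):
        seq, part = small_genome
        iso_b = pk.build_isoform(seq, part, "noncanonical")
        params = pk.ReadSimParams(n_reads=120, length_mean=1500, length_sd=300,
                                  mismatch_rate=0, ins_rate=0, del_rate=0,
                                  mixture_ratio=0.5, seed=21)
        records, _ = pk.simulate_reads(seq, iso_b, params)
        mapper = pk.SegmentMapper(seq, part)
        hits = [mapper.map(str(r.seq)) for r in records]
        ratio = pk.collapsed_depth_ratio(hits, part)
        assert 1.7 <= ratio <= 2.3
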