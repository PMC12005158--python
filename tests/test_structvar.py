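"""Split-read classification, breakpoint matching, frequencies, windows."""

import collections

import numpy as np
import pytest

from orgmut import synth
from orgmut.orgmodel import RepeatPair, parse_repeat_row
from orgmut.structvar import (
    GEOM_DELETION,
    GEOM_INVERTED,
    MULTI_EXCLUDED,
    SINGLE_CLEAN,
    SINGLE_INDEL,
    TWO_CIRCULAR,
    TWO_DELETION,
    TWO_INVERTED,
    UNMAPPED,
    CoverageWindows,
    GenomeKmerIndex,
    LocalHit,
    ReadStructure,
    RecombEvent,
    analyze_reads,
    call_supported_indels,
    classify_long_reads,
    classify_read,
    count_spanning,
    coverage_ratio_windows,
    find_hits,
    genome_frequency,
    match_breakpoint,
    read_blast_tab,
    read_sam_hits,
    repeat_frequency,
)


# ---------------------------------------------------------------------------
# Exhaustive two-hit oracle

READ_GAP = 20
GAP_SLOP = 50


def make_two_hits(s1, s2, step):
    """Two read-ordered hits with a signed genome step along the molecule.

    ``step`` is the displacement from hit1's junction coordinate to hit2's,
    measured along the direction the molecule reads the genome (positive =
    genome order matches read order).
    """
    if s1 == "+":
        h1 = LocalHit(1, 500, 10_000, 10_499, "+")
        j1 = 10_499
    else:
        h1 = LocalHit(1, 500, 10_000, 10_499, "-")
        j1 = 10_000
    start2 = 500 + READ_GAP + 1
    if s2 == "+":
        g2 = (j1 + step) if s1 == "+" else (j1 - step)
        h2 = LocalHit(start2, start2 + 499, g2, g2 + 499, "+")
    else:
        g2_end = (j1 - step) if s1 == "-" else (j1 + step)
        h2 = LocalHit(start2, start2 + 499, g2_end - 499, g2_end, "-")
    return [h1, h2]


def oracle_two_hit_class(s1, s2, step):
    """Hand-written truth table for the two-hit geometries."""
    if s1 != s2:
        return TWO_INVERTED
    net = step - READ_GAP
    if step < -GAP_SLOP:
        return TWO_CIRCULAR
    if net > GAP_SLOP:
        return TWO_DELETION
    if net < -GAP_SLOP:
        return SINGLE_INDEL
    return SINGLE_CLEAN


STEPS = [5_000, 2_000, 200, 106, 71, 60, 25, 0, -25, -40, -200, -2_000, -5_000]
STRANDS = [("+", "+"), ("+", "-"), ("-", "+"), ("-", "-")]


class TestTwoHitTruthTable:
    @pytest.mark.parametrize("s1,s2", STRANDS)
    @pytest.mark.parametrize("step", STEPS)
    def test_classifier_matches_oracle(self, s1, s2, step):
        hits = make_two_hits(s1, s2, step)
        rs = classify_read(hits, "r", 1_020, min_hit_len=100, gap_slop=GAP_SLOP)
        assert rs.cls == oracle_two_hit_class(s1, s2, step)

    def test_case_count_is_exhaustive(self):
        assert len(STEPS) * len(STRANDS) >= 48


class TestClassifyRead:
    def test_zero_hits_unmapped(self):
        assert classify_read([], "r", 1000).cls == UNMAPPED

    def test_single_hit_clean_within_unexplained(self):
        hits = [LocalHit(1, 990, 100, 1089, "+")]
        assert classify_read(hits, "r", 1000).cls == SINGLE_CLEAN

    def test_single_hit_with_large_remainder_is_indel(self):
        hits = [LocalHit(1, 600, 100, 699, "+")]
        assert classify_read(hits, "r", 1000).cls == SINGLE_INDEL

    def test_three_hits_excluded(self):
        hits = [
            LocalHit(1, 300, 100, 399, "+"),
            LocalHit(301, 600, 5000, 5299, "+"),
            LocalHit(601, 900, 9000, 9299, "+"),
        ]
        assert classify_read(hits, "r", 900).cls == MULTI_EXCLUDED

    def test_short_hits_dropped_before_classification(self):
        hits = [
            LocalHit(1, 900, 100, 999, "+"),
            LocalHit(901, 950, 5000, 5049, "+"),  # below min_hit_len
        ]
        assert classify_read(hits, "r", 1000, min_hit_len=100).cls == SINGLE_CLEAN

    def test_contained_duplicate_hit_ignored(self):
        # the spurious other-copy hit covers a read interval inside the main hit
        hits = [
            LocalHit(1, 2000, 100, 2099, "+"),
            LocalHit(700, 999, 40_000, 40_299, "+"),
        ]
        assert classify_read(hits, "r", 2050).cls == SINGLE_CLEAN

    def test_inverted_example_geometry(self):
        hits = [
            LocalHit(1, 5000, 10_000, 14_999, "+"),
            LocalHit(5001, 9000, 40_000, 43_999, "-"),
        ]
        rs = classify_read(hits, "r", 9000)
        assert rs.cls == TWO_INVERTED
        assert rs.event.geometry == GEOM_INVERTED

    def test_deletion_junction_difference_convention(self):
        """Junction coordinates (148490, 148596) give the printed 106 bp."""
        hits = [
            LocalHit(1, 1000, 147_491, 148_490, "+"),
            LocalHit(1001, 2000, 148_596, 149_595, "+"),
        ]
        rs = classify_read(hits, "r", 2000)
        assert rs.cls == TWO_DELETION
        assert rs.indel_candidate == ("deletion", 148_490, 106)
        assert rs.event.junction == (148_490, 148_596)


class TestMatchBreakpoint:
    @pytest.fixture
    def catalog(self):
        return [
            parse_repeat_row("A", "19,682-20,237", "346,208-346,763", 99.82, 556),
            parse_repeat_row("B", "41,464-41,999", "321,967-321,431", 99.81, 537),
            parse_repeat_row("L", "270,775-271,023", "331,877-332,125", 100, 249),
        ]

    def test_junctions_inside_copies_match(self, catalog):
        ev = RecombEvent("r", (19_700, 346_300), GEOM_DELETION)
        assert match_breakpoint(ev, catalog, tolerance=50) == "A"

    def test_far_junctions_no_match(self, catalog):
        ev = RecombEvent("r", (5_000, 100_000), GEOM_DELETION)
        assert match_breakpoint(ev, catalog, tolerance=50) is None

    def test_geometry_must_match_orientation(self, catalog):
        # repeat B is inverted; a deletion-geometry event there must not match
        ev = RecombEvent("r", (41_500, 321_500), GEOM_DELETION)
        assert match_breakpoint(ev, catalog, tolerance=50) is None
        ev = RecombEvent("r", (41_500, 321_500), GEOM_INVERTED)
        assert match_breakpoint(ev, catalog, tolerance=50) == "B"

    def test_equal_distance_tie_is_ambiguous(self):
        r1 = RepeatPair("X", (1000, 1199), (5000, 5199), False, 100.0, 200)
        r2 = RepeatPair("Y", (1000, 1199), (5000, 5199), False, 100.0, 200)
        ev = RecombEvent("r", (1100, 5100), GEOM_DELETION)
        assert match_breakpoint(ev, [r1, r2], tolerance=50) is None

    def test_synthetic_truth_recovery(self, synth_reference):
        genome, _, repeats = synth_reference
        model = synth.LongReadModel(
            n_reads=1200,
            per_repeat_recomb_freq={rp.name: 0.5 for rp in repeats},
            seed=6,
        )
        reads, truths = synth.simulate_long_reads(genome, repeats, model)
        structures = classify_long_reads(genome, reads)
        analyze_reads(structures, repeats, tolerance=100)
        smap = {s.read_id: s for s in structures}
        planted = [(t.molecule_id, t.events[0].repeat) for t in truths if t.events]
        matched = sum(
            1
            for rid, rep in planted
            if smap[rid].event is not None and smap[rid].event.repeat == rep
        )
        assert planted and matched / len(planted) >= 0.99


class TestSpanningAndFrequencies:
    @pytest.fixture
    def rp(self):
        return RepeatPair("R", (1000, 1299), (5000, 5299), False, 100.0, 300)

    def _structure(self, g_start, g_end):
        hit = LocalHit(1, g_end - g_start + 1, g_start, g_end, "+")
        return ReadStructure("r", g_end - g_start + 1, [hit], SINGLE_CLEAN)

    def test_read_covering_copy_plus_flank_counted(self, rp):
        s = self._structure(800, 1500)  # copy1 +- 200
        assert count_spanning([s], rp, flank=100) == 1

    def test_read_ending_inside_repeat_not_counted(self, rp):
        s = self._structure(800, 1200)
        assert count_spanning([s], rp, flank=100) == 0

    def test_matched_recombinant_counts_once(self, rp):
        s = self._structure(800, 1500)
        s.event = RecombEvent("r", (1100, 5100), GEOM_DELETION, repeat="R")
        assert count_spanning([s], rp, flank=100) == 1

    @pytest.mark.parametrize("rec,span,freq", [(0, 274, 0.0), (5, 20, 0.25)])
    def test_repeat_frequency(self, rec, span, freq):
        assert repeat_frequency(rec, span, "R").frequency == pytest.approx(freq)

    def test_zero_spanning_flagged_no_data(self):
        assert repeat_frequency(0, 0, "R").frequency is None

    def test_recombined_cannot_exceed_spanning(self):
        with pytest.raises(ValueError):
            repeat_frequency(5, 4, "R")


class TestGenomeFrequency:
    def _stats(self, totals):
        from orgmut.structvar import RepeatRecombStats

        return [
            [RepeatRecombStats(name, rec, rec + 50) for name, rec in totals.items()]
        ]

    def test_mt_threshold_excludes_below_ten(self):
        stats = self._stats({"a": 12, "b": 9})
        freqs, included = genome_frequency(stats, min_recombined=10)
        assert included == ["a"]
        assert freqs[0] == pytest.approx(12 / 62)

    def test_cp_threshold_includes_both(self):
        stats = self._stats({"a": 12, "b": 9})
        freqs, included = genome_frequency(stats, min_recombined=3)
        assert included == ["a", "b"]
        assert freqs[0] == pytest.approx((12 + 9) / (62 + 59))

    def test_threshold_sweep_monotone_superset(self):
        stats = self._stats({"a": 12, "b": 9, "c": 2})
        _, at3 = genome_frequency(stats, min_recombined=3)
        _, at10 = genome_frequency(stats, min_recombined=10)
        assert set(at10) <= set(at3)

    def test_all_zero_empty_result(self):
        stats = self._stats({"a": 0, "b": 0})
        freqs, included = genome_frequency(stats, min_recombined=3)
        assert freqs == [] and included == []

    def test_summed_across_replicates(self):
        from orgmut.structvar import RepeatRecombStats

        reps = [
            [RepeatRecombStats("a", 6, 100)],
            [RepeatRecombStats("a", 6, 120)],
        ]
        freqs, included = genome_frequency(reps, min_recombined=10)
        assert included == ["a"] and len(freqs) == 2


class TestSupportedIndels:
    def _del_structure(self, rid, pos, length):
        s = ReadStructure(rid, 2000, [], TWO_DELETION)
        s.indel_candidate = ("deletion", pos, length)
        return s

    def test_single_read_no_call(self):
        calls = call_supported_indels([self._del_structure("r1", 148490, 106)])
        assert calls == []

    def test_eighteen_reads_one_call(self):
        structures = [self._del_structure(f"r{i}", 148490, 106) for i in range(18)]
        (call,) = call_supported_indels(structures)
        assert call["support"] == 18 and call["length"] == 106

    def test_near_identical_candidates_do_not_pool(self):
        structures = [
            self._del_structure("r1", 148490, 106),
            self._del_structure("r2", 148491, 106),
        ]
        assert call_supported_indels(structures) == []


class TestCoverageWindows:
    def test_identical_depths_all_ones(self):
        depth = np.full(5000, 7.0)
        cw = coverage_ratio_windows(depth, depth, window=1000)
        assert np.allclose(cw.ratio, 1.0)

    def test_doubled_half_gives_four_thirds_two_thirds(self):
        wt = np.full(2000, 10.0)
        mut = np.concatenate([np.full(1000, 20.0), np.full(1000, 10.0)])
        cw = coverage_ratio_windows(mut, wt, window=1000)
        assert cw.ratio == pytest.approx([4 / 3, 2 / 3])
        assert cw.ratio.mean() == pytest.approx(1.0)

    def test_mean_exactly_one(self, rng):
        mut = rng.poisson(30, 10_000).astype(float)
        wt = rng.poisson(25, 10_000).astype(float)
        cw = coverage_ratio_windows(mut, wt, window=1000)
        assert np.nanmean(cw.ratio[~cw.flagged_zero_wt]) == pytest.approx(1.0)

    def test_zero_wt_window_flagged(self):
        wt = np.concatenate([np.zeros(1000), np.full(1000, 10.0)])
        mut = np.full(2000, 10.0)
        cw = coverage_ratio_windows(mut, wt, window=1000)
        assert cw.flagged_zero_wt[0] and not cw.flagged_zero_wt[1]

    def test_genome_shorter_than_window_single_window(self):
        cw = coverage_ratio_windows(np.full(500, 4.0), np.full(500, 2.0), window=1000)
        assert len(cw.ratio) == 1 and cw.ratio[0] == pytest.approx(1.0)


def _repeat_free_window(genome, repeats, span):
    """0-based start of a window not overlapping any repeat copy."""
    occupied = []
    for rp in repeats:
        occupied += [rp.copy1, rp.copy2]
    for s in range(0, genome.length - span, 500):
        if all(e < s + 1 or b > s + span for (b, e) in occupied):
            return s
    raise AssertionError("no repeat-free window in fixture genome")


class TestInternalAligner:
    def test_forward_hit_located(self, synth_reference):
        genome, _, repeats = synth_reference
        s = _repeat_free_window(genome, repeats, 2000)
        idx = GenomeKmerIndex(genome)
        hits = find_hits(idx, genome.sequence[s : s + 2000])
        (h,) = hits
        assert h.strand == "+"
        assert abs(h.g_start - (s + 1)) <= 5 and abs(h.g_end - (s + 2000)) <= 5

    def test_reverse_hit_located(self, synth_reference):
        from orgmut.orgmodel import revcomp

        genome, _, repeats = synth_reference
        s = _repeat_free_window(genome, repeats, 2000)
        idx = GenomeKmerIndex(genome)
        (h,) = find_hits(idx, revcomp(genome.sequence[s : s + 2000]))
        assert h.strand == "-" and abs(h.g_start - (s + 1)) <= 5

    def test_hits_survive_five_percent_error(self, synth_reference):
        genome, _, repeats = synth_reference
        s = _repeat_free_window(genome, repeats, 3000)
        idx = GenomeKmerIndex(genome)
        rng = np.random.default_rng(8)
        codes = synth.encode_seq(genome.sequence[s : s + 3000])
        noisy = synth._apply_long_read_errors(codes, 0.05, rng)
        hits = find_hits(idx, synth.decode_seq(noisy))
        assert len(hits) == 1 and hits[0].strand == "+"
        assert abs(hits[0].g_start - (s + 1)) <= 30


class TestHitParsers:
    def test_blast_tabular(self, tmp_path):
        path = tmp_path / "hits.tsv"
        path.write_text(
            "r1\tmt\t99.5\t500\t2\t0\t1\t500\t10000\t10499\t0.0\t900\n"
            "r1\tmt\t98.0\t400\t6\t1\t521\t920\t42000\t41601\t0.0\t700\n"
        )
        hits = read_blast_tab(path)
        assert len(hits["r1"]) == 2
        fwd, rev = hits["r1"]
        assert fwd.strand == "+" and rev.strand == "-"
        assert rev.g_start == 41601 and rev.g_end == 42000

    def test_sam_supplementary_hits(self, tmp_path):
        sam = tmp_path / "a.sam"
        sam.write_text(
            "@HD\tVN:1.6\tSO:unknown\n"
            "@SQ\tSN:mt\tLN:30000\n"
            "r1\t0\tmt\t1001\t60\t500M520S\t*\t0\t0\t" + "A" * 1020 + "\t*\n"
            "r1\t2048\tmt\t9001\t60\t520S500M\t*\t0\t0\t" + "A" * 1020 + "\t*\n"
        )
        out = read_sam_hits(sam)
        length, hits = out["r1"]
        assert length == 1020 and len(hits) == 2
        assert hits[0].read_start == 1 and hits[0].g_start == 1001
        assert hits[1].read_start == 521 and hits[1].g_start == 9001
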