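"""Duplex consensus, variant calling, NUMT filter, coverage, frequencies."""

import numpy as np
import pytest

from orgmut import synth
from orgmut.duplexcall import (
    END_TRIMMED,
    NUMT,
    PASS,
    CoverageProfile,
    DuplexCallParams,
    DuplexFamily,
    TaggedRead,
    build_consensus,
    call_variants,
    calls_to_frame,
    duplex_pipeline,
    family_pipeline,
    group_families,
    numt_filter,
    variant_frequency,
)
from orgmut.orgmodel import OrganelleGenome, RegionIndex
from orgmut.synth import CLASSES, MutationModel, simulate_duplex_families


def mk_reads(tag, strand, n, start=0, length=200, diffs=()):
    return [TaggedRead(tag, strand, start, length, tuple(diffs)) for _ in range(n)]


@pytest.fixture(scope="module")
def genome():
    rng = np.random.default_rng(123)
    return OrganelleGenome("g", synth.decode_seq(rng.integers(0, 4, 4000).astype(np.uint8)))


class TestGroupFamilies:
    def test_single_family_three_plus_three(self):
        reads = mk_reads("T1", "A", 3) + mk_reads("T1", "B", 3)
        fams, rejected = group_families(reads)
        assert len(fams) == 1 and rejected == 0
        assert len(fams[0].strand_a_reads) == 3 and len(fams[0].strand_b_reads) == 3

    def test_two_tags_two_families(self):
        reads = mk_reads("T1", "A", 2) + mk_reads("T2", "A", 2)
        fams, _ = group_families(reads)
        assert len(fams) == 2

    def test_one_tag_two_loci_split(self):
        reads = mk_reads("T1", "A", 2, start=0) + mk_reads("T1", "B", 2, start=10_000)
        fams, _ = group_families(reads)
        assert len(fams) == 2
        assert {f.tag for f in fams} == {"T1.1", "T1.2"}

    def test_untagged_rejected_with_count(self):
        reads = mk_reads("", "A", 2) + mk_reads("T1", "A", 1)
        fams, rejected = group_families(reads)
        assert rejected == 2 and len(fams) == 1


class TestBuildConsensus:
    def test_identical_reads_consensus_equals_read(self):
        fam = DuplexFamily("T1", mk_reads("T1", "A", 3), mk_reads("T1", "B", 3))
        cons = build_consensus(fam)
        assert cons is not None and cons.variants == {} and cons.n_positions == set()

    def test_strand_disagreement_is_n_not_a_base(self):
        d = [(50, "SNV", "A", "C")]
        fam = DuplexFamily(
            "T1", mk_reads("T1", "A", 3, diffs=d), mk_reads("T1", "B", 3)
        )
        cons = build_consensus(fam)
        assert 50 in cons.n_positions and 50 not in cons.variants

    def test_conflicting_alts_between_strands_is_n(self):
        fam = DuplexFamily(
            "T1",
            mk_reads("T1", "A", 3, diffs=[(50, "SNV", "A", "C")]),
            mk_reads("T1", "B", 3, diffs=[(50, "SNV", "A", "T")]),
        )
        cons = build_consensus(fam)
        assert 50 in cons.n_positions and not cons.variants

    def test_duplex_agreement_called(self):
        d = [(50, "SNV", "A", "C")]
        fam = DuplexFamily(
            "T1", mk_reads("T1", "A", 3, diffs=d), mk_reads("T1", "B", 3, diffs=d)
        )
        cons = build_consensus(fam)
        assert cons.variants == {50: ("SNV", "A", "C")}

    def test_minority_read_below_threshold_keeps_variant(self):
        d = [(50, "SNV", "A", "C")]
        fam = DuplexFamily(
            "T1",
            mk_reads("T1", "A", 9, diffs=d) + mk_reads("T1", "A", 1),
            mk_reads("T1", "B", 3, diffs=d),
        )
        cons = build_consensus(fam, strand_consensus_threshold=0.9)
        assert cons.variants == {50: ("SNV", "A", "C")}

    def test_empty_strand_rejected(self):
        fam = DuplexFamily("T1", mk_reads("T1", "A", 3), [])
        assert build_consensus(fam) is None

    def test_min_reads_per_strand_rejection(self):
        fam = DuplexFamily("T1", mk_reads("T1", "A", 2), mk_reads("T1", "B", 3))
        assert build_consensus(fam, min_reads_per_strand=3) is None
        assert build_consensus(fam, min_reads_per_strand=2) is not None

    def test_single_strand_error_never_passes(self):
        """Duplex guarantee: unanimous one-strand artifacts yield N, no call."""
        d = [(70, "SNV", "G", "T")]
        fam = DuplexFamily(
            "T1", mk_reads("T1", "A", 5, diffs=d), mk_reads("T1", "B", 5)
        )
        cons = build_consensus(fam)
        assert not cons.variants and 70 in cons.n_positions


class TestCallVariants:
    def test_reference_consensus_no_calls(self, genome):
        fam = DuplexFamily("T1", mk_reads("T1", "A", 3), mk_reads("T1", "B", 3))
        cons = build_consensus(fam)
        assert call_variants(cons, genome) == []

    def test_pyrimidine_convention_annotation(self, genome):
        # find a G site away from molecule ends
        pos0 = next(i for i in range(40, 150) if genome.sequence[i] == "G")
        d = [(pos0, "SNV", "G", "A")]
        fam = DuplexFamily(
            "T1", mk_reads("T1", "A", 3, diffs=d), mk_reads("T1", "B", 3, diffs=d)
        )
        calls = call_variants(build_consensus(fam), genome)
        (c,) = calls
        assert c.vtype == "SNV" and (c.ref, c.alt) == ("G", "A")
        assert c.pyr_strand == "-"  # reported as C>T on the complement
        assert c.context is not None and c.context[1] == "C"

    def test_adjacent_snvs_merge_to_dinucleotide(self, genome):
        d = [(100, "SNV", genome.sequence[100], "A" if genome.sequence[100] != "A" else "C"),
             (101, "SNV", genome.sequence[101], "G" if genome.sequence[101] != "G" else "T")]
        fam = DuplexFamily(
            "T1", mk_reads("T1", "A", 3, diffs=d), mk_reads("T1", "B", 3, diffs=d)
        )
        calls = call_variants(build_consensus(fam), genome)
        (c,) = calls
        assert c.vtype == "dinucleotide" and c.position == 101
        assert len(c.ref) == 2 and len(c.alt) == 2

    def test_end_trim_status(self, genome):
        d = [(5, "SNV", genome.sequence[5], "A" if genome.sequence[5] != "A" else "C")]
        fam = DuplexFamily(
            "T1", mk_reads("T1", "A", 3, diffs=d), mk_reads("T1", "B", 3, diffs=d)
        )
        calls = call_variants(build_consensus(fam), genome, end_trim=10)
        assert calls[0].status == END_TRIMMED
        calls = call_variants(build_consensus(fam), genome, end_trim=0)
        assert calls[0].status == PASS

    def test_deletion_left_aligned(self):
        g = OrganelleGenome("h", "GCTTTTACGTACGTACGTAC" * 10)
        # delete one T of the homopolymer at positions 3-6 (1-based)
        d = [(5, "deletion", "T", "")]
        fam = DuplexFamily(
            "T1",
            mk_reads("T1", "A", 3, start=0, length=60, diffs=d),
            mk_reads("T1", "B", 3, start=0, length=60, diffs=d),
        )
        calls = call_variants(build_consensus(fam), g, end_trim=0)
        (c,) = calls
        assert c.vtype == "deletion" and c.position == 3  # first T of the run


class TestNumtFilter:
    def test_verbatim_haplotype_filtered(self, genome):
        pos0 = 200
        alt = "A" if genome.sequence[pos0] != "A" else "C"
        call_pos = pos0 + 1
        window = genome.sequence[pos0 - 20 : pos0] + alt + genome.sequence[pos0 + 1 : pos0 + 21]
        nuclear = "TTTT" + window + "GGGG"
        from orgmut.duplexcall import VariantCall

        call = VariantCall(call_pos, "SNV", genome.sequence[pos0], alt, "T1")
        status = numt_filter(call, [(pos0, "SNV", genome.sequence[pos0], alt)], genome, [nuclear])
        assert status == NUMT

    def test_absent_haplotype_passes(self, genome):
        from orgmut.duplexcall import VariantCall

        pos0 = 200
        alt = "A" if genome.sequence[pos0] != "A" else "C"
        call = VariantCall(pos0 + 1, "SNV", genome.sequence[pos0], alt, "T1")
        rng = np.random.default_rng(5)
        nuclear = synth.decode_seq(rng.integers(0, 4, 5000).astype(np.uint8))
        assert numt_filter(call, [(pos0, "SNV", genome.sequence[pos0], alt)], genome, [nuclear]) == PASS

    def test_reverse_complement_also_searched(self, genome):
        from orgmut.orgmodel import revcomp
        from orgmut.duplexcall import VariantCall

        pos0 = 300
        alt = "A" if genome.sequence[pos0] != "A" else "C"
        window = genome.sequence[pos0 - 20 : pos0] + alt + genome.sequence[pos0 + 1 : pos0 + 21]
        nuclear = "CCCC" + revcomp(window) + "AAAA"
        call = VariantCall(pos0 + 1, "SNV", genome.sequence[pos0], alt, "T1")
        assert numt_filter(call, [(pos0, "SNV", genome.sequence[pos0], alt)], genome, [nuclear]) == NUMT

    def test_planted_paralog_fixture_full_separation(self, synth_reference):
        """All paralog-derived calls are filtered; no genuine call is lost."""
        genome, features, _ = synth_reference
        ri = RegionIndex(genome, features)
        interval = (2000, 8000)
        nuclear, paralog_variants = synth.make_numt_fixture(
            genome, interval, n_paralog_variants=12, seed=42
        )
        numt_reads = synth.simulate_numt_families(
            genome, interval, paralog_variants, 400, seed=43
        )
        model = MutationModel(
            base_rate_per_class={**{c: 0.0 for c in CLASSES}, "C>T": 3e-4},
            indel_rate=0.0,
            dinucleotide_rate=0.0,
        )
        genuine, truths = simulate_duplex_families(
            genome, features, model, 3000, seq_error=0.0, seed=44, region_index=ri
        )
        truth_keys = set()
        for t in truths:
            for e in t.events:
                truth_keys.add((e.position, e.alt))
        paralog_keys = {(e.position, e.alt) for e in paralog_variants}
        params = DuplexCallParams(numt_k_flank=20, numt_max_mismatch=0)
        res_genuine = duplex_pipeline(genuine, ri, params, nuclear_seqs=[nuclear])
        res_numt = duplex_pipeline(numt_reads, ri, params, nuclear_seqs=[nuclear])
        numt_calls = [
            c
            for c in res_numt.calls
            if (c.position, c.alt) in paralog_keys and c.status != END_TRIMMED
        ]
        assert numt_calls, "fixture produced no paralog-derived calls"
        assert all(c.status == NUMT for c in numt_calls)
        genuine_pass = [c for c in res_genuine.calls if c.status != END_TRIMMED]
        assert genuine_pass, "no genuine calls produced"
        assert all(c.status == PASS for c in genuine_pass)


class TestCoverage:
    def test_from_molecules_with_wraparound(self, genome):
        L = genome.length
        cov = CoverageProfile.from_molecules(
            genome, np.array([L - 50]), np.array([100]), end_trim=0
        )
        assert cov.depth[L - 50 :].sum() == 50 and cov.depth[:50].sum() == 50
        assert cov.total() == 100

    def test_end_trim_shrinks_denominator(self, genome):
        cov = CoverageProfile.from_molecules(genome, np.array([0]), np.array([300]), end_trim=10)
        assert cov.total() == 280

    def test_context_coverage_partitions_total(self, genome):
        cov = CoverageProfile.from_molecules(
            genome, np.arange(0, 3000, 37), np.array([250]), end_trim=0
        )
        by_ctx = sum(cov.context_coverage("C").values()) + sum(
            cov.context_coverage("T").values()
        )
        assert by_ctx == cov.total()  # N-free circular genome: exact partition

    def test_negative_depth_rejected(self, genome):
        with pytest.raises(ValueError):
            CoverageProfile(genome, np.full(genome.length, -1))


class TestVariantFrequency:
    def test_zero_calls_zero_frequency(self, genome):
        cov = CoverageProfile(genome, np.ones(genome.length, dtype=np.int64))
        assert variant_frequency([], cov) == 0.0

    def test_two_snvs_per_million(self, genome):
        from orgmut.duplexcall import VariantCall

        depth = np.zeros(genome.length, dtype=np.int64)
        depth[:1000] = 1000
        cov = CoverageProfile(genome, depth)
        calls = [
            VariantCall(10, "SNV", "A", "C", "m1"),
            VariantCall(20, "SNV", "A", "G", "m2"),
        ]
        assert variant_frequency(calls, cov, "SNV") == pytest.approx(2e-6)

    def test_dinucleotide_excluded_from_snv_numerator(self, genome):
        from orgmut.duplexcall import VariantCall

        cov = CoverageProfile(genome, np.ones(genome.length, dtype=np.int64))
        calls = [VariantCall(10, "dinucleotide", "AC", "GT", "m1")]
        assert variant_frequency(calls, cov, "SNV") == 0.0
        assert variant_frequency(calls, cov, "SNV", include_dinucleotide=True) > 0

    def test_zero_coverage_undefined(self, genome):
        cov = CoverageProfile(genome, np.zeros(genome.length, dtype=np.int64))
        with pytest.raises(ZeroDivisionError):
            variant_frequency([], cov)


class TestPipelineEquivalence:
    def test_bulk_and_family_paths_identical(self, synth_reference):
        genome, features, _ = synth_reference
        ri = RegionIndex(genome, features)
        model = MutationModel(
            base_rate_per_class={**{c: 1e-5 for c in CLASSES}, "C>T": 3e-4},
            indel_rate=5e-5,
            dinucleotide_rate=1e-5,
        )
        rs, _ = simulate_duplex_families(
            genome, features, model, 1500, seq_error=2e-3, seed=21, region_index=ri
        )
        bulk = duplex_pipeline(rs, ri)
        fam = family_pipeline(rs.to_tagged_reads(), genome, ri)
        assert calls_to_frame(bulk.calls).equals(calls_to_frame(fam.calls))
        assert np.array_equal(bulk.coverage.depth, fam.coverage.depth)

    def test_read_order_invariance(self, synth_reference):
        genome, features, _ = synth_reference
        ri = RegionIndex(genome, features)
        model = MutationModel(
            base_rate_per_class={**{c: 0.0 for c in CLASSES}, "C>T": 3e-4}
        )
        rs, _ = simulate_duplex_families(
            genome, features, model, 500, seq_error=1e-3, seed=22, region_index=ri
        )
        reads = rs.to_tagged_reads()
        shuffled = list(reads)
        np.random.default_rng(0).shuffle(shuffled)
        a = family_pipeline(reads, genome, ri)
        b = family_pipeline(shuffled, genome, ri)
        assert calls_to_frame(a.calls).equals(calls_to_frame(b.calls))

    def test_error_free_recovery_is_exact(self, synth_reference):
        """With no sequencing error, pass calls equal planted events exactly."""
        genome, features, _ = synth_reference
        ri = RegionIndex(genome, features)
        model = MutationModel(
            base_rate_per_class={**{c: 2e-5 for c in CLASSES}, "C>T": 2e-4},
            indel_rate=5e-5,
            dinucleotide_rate=2e-5,
        )
        rs, truths = simulate_duplex_families(
            genome, features, model, 4000, seq_error=0.0, seed=23, region_index=ri
        )
        res = duplex_pipeline(rs, ri, DuplexCallParams(end_trim=0))

        def left_align(pos, allele):  # independent re-statement of the rule
            p = pos
            while genome.sequence[(p - 2) % genome.length] == allele:
                p -= 1
            return p

        expected = set()
        for t in truths:
            evs = sorted(t.events, key=lambda e: e.position)
            i = 0
            while i < len(evs):
                e = evs[i]
                if (
                    e.etype == "SNV"
                    and i + 1 < len(evs)
                    and evs[i + 1].etype == "SNV"
                    and evs[i + 1].position == e.position + 1
                ):
                    expected.add((e.position, "dinucleotide", e.alt + evs[i + 1].alt))
                    i += 2
                    continue
                if e.etype == "dinucleotide":
                    expected.add((e.position, "dinucleotide", e.alt))
                elif e.etype == "deletion":
                    expected.add((left_align(e.position, e.ref), "deletion", ""))
                elif e.etype == "insertion":
                    expected.add((left_align(e.position, e.alt), "insertion", e.alt))
                else:
                    expected.add((e.position, "SNV", e.alt))
                i += 1
        got = {(c.position, c.vtype, c.alt) for c in res.calls if c.status == PASS}
        assert got == expected
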