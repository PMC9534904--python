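"""Filtering and coordinate-assignment logic of the site-calling pipeline."""

import numpy as np
import pytest

from ssingleap.io_formats import AlignedRead, AlignedReadPair, Genome
from ssingleap.sim_data import SimParams, plant_sites, simulate_reads
from ssingleap.sitecall import (
    assign_sites,
    dedup_pairs,
    filter_alignments_genomic,
    filter_alignments_spike,
    filter_tag_structure,
    genomic_polyA_filter,
    run_pipeline,
)


def _pair(
    r1_pos=100, r1_strand="+", r2_pos=200, r2_strand="-",
    mapq=60, flag=None, cigar="50M", chrom="c1", name="p", seq="",
):
    if flag is None:
        flag = 147 if r2_strand == "-" else 163
    r1 = AlignedRead(chrom, r1_pos, r1_strand, mapq, 99, "50M", seq)
    r2 = AlignedRead(chrom, r2_pos, r2_strand, mapq, flag, cigar, seq)
    return AlignedReadPair(name, r1, r2)


class TestTagFilter:
    R1_OK = "AGTTGCGGAT" + "G" * 10 + "ACTGACTG"
    R2_OK = "T" * 12 + "CAGTCAGT"

    def test_canonical_pair_accepted_and_trimmed(self):
        t1, t2 = filter_tag_structure("p", self.R1_OK, self.R2_OK)
        assert (t1, t2) == ("ACTGACTG", "CAGTCAGT")

    @pytest.mark.parametrize("g_run,ok", [(8, False), (9, True), (11, True), (12, False)])
    def test_g_run_bounds(self, g_run, ok):
        r1 = "AGTTGCGGAT" + "G" * g_run + "ACTG"
        t1, t2 = filter_tag_structure("p", r1, self.R2_OK)
        assert (t1 is not None) == ok
        if not ok:
            assert t2 == "r1_tag"

    @pytest.mark.parametrize("t_run,ok", [(10, False), (11, True), (13, True), (14, False)])
    def test_t_run_bounds(self, t_run, ok):
        # a 14-run cannot arise from the tailing primer (non-T follows T13)
        r2 = "T" * t_run + "CAGT"
        t1, t2 = filter_tag_structure("p", self.R1_OK, r2)
        assert (t1 is not None) == ok
        if not ok:
            assert t2 == "r2_tag"

    def test_empty_reads_rejected_not_raised(self):
        assert filter_tag_structure("p", "", "")[0] is None

    def test_wrong_literal_rejected(self):
        t1, reason = filter_tag_structure("p", "AGTTGCGGAA" + "G" * 10, self.R2_OK)
        assert t1 is None and reason == "r1_tag"


class TestDedup:
    def test_identical_coordinates_collapse(self):
        pairs = [_pair(name="a"), _pair(name="b")]
        assert [p.name for p in dedup_pairs(pairs)] == ["a"]

    def test_higher_mapq_wins(self):
        pairs = [_pair(name="low", mapq=10), _pair(name="hi", mapq=60)]
        assert [p.name for p in dedup_pairs(pairs)] == ["hi"]

    def test_different_r1_start_both_kept(self):
        pairs = [_pair(name="a", r1_pos=100), _pair(name="b", r1_pos=101)]
        assert len(dedup_pairs(pairs)) == 2

    def test_simulated_duplicates_reduce_to_template_count(self, small_genome):
        genome, annotations, _ = small_genome
        params = SimParams(
            n_site_reads=1000, n_hotspots=0, duplicate_rate=0.2,
            unblocked_background_rate=0.0, seed=5,
        )
        truth = plant_sites(genome, annotations, params)
        reads, truth_map = simulate_reads(genome, truth, params)
        n_templates = sum(1 for n in truth_map if not n.endswith("_dup"))
        _, stats = run_pipeline(reads, genome, mode="ap")
        assert stats.dedup_pass == n_templates


class TestGenomicFilter:
    def test_clean_pair_passes(self):
        assert filter_alignments_genomic(_pair())[0]

    def test_mapq_threshold_is_strict(self):
        assert not filter_alignments_genomic(_pair(mapq=20))[0]
        assert filter_alignments_genomic(_pair(mapq=21))[0]

    def test_flag_restricted_to_proper_second_mate(self):
        ok, reason = filter_alignments_genomic(_pair(flag=99))
        assert not ok and reason == "flag"

    def test_leading_softclip_fails_first_base(self):
        ok, reason = filter_alignments_genomic(
            _pair(cigar="1S49M", r2_strand="+", flag=163))
        assert not ok and reason == "first_base"

    def test_trailing_softclip_fails_on_minus_strand(self):
        # on "-" the first sequenced base is the rightmost CIGAR op
        ok, reason = filter_alignments_genomic(_pair(cigar="49M1S", r2_strand="-"))
        assert not ok and reason == "first_base"

    def test_first_base_mismatch_with_genome(self, toy_genome):
        seq = "G" + toy_genome.sequences["c1"][21:40]  # first base wrong
        pair = _pair(r2_pos=20, r2_strand="+", flag=163, cigar="20M", seq=seq)
        ok, reason = filter_alignments_genomic(pair, toy_genome)
        assert not ok and reason == "first_base"


class TestSpikeFilter:
    LENGTHS = {"c1": 500}

    def test_mapq_threshold_is_inclusive(self):
        assert filter_alignments_spike(_pair(mapq=20), self.LENGTHS)[0]
        assert not filter_alignments_spike(_pair(mapq=19), self.LENGTHS)[0]

    def test_same_strand_mates_fail(self):
        pair = _pair(r1_strand="-", r2_strand="-")
        ok, reason = filter_alignments_spike(pair, self.LENGTHS)
        assert not ok and reason == "strand"

    def test_distance_bound_is_strict(self):
        ok, reason = filter_alignments_spike(
            _pair(r1_pos=0, r2_pos=500), self.LENGTHS)
        assert not ok and reason == "distance"
        assert filter_alignments_spike(_pair(r1_pos=0, r2_pos=499), self.LENGTHS)[0]


class TestPolyAFilter:
    def _genome_with_window(self, upstream: str, downstream: str = ""):
        # read 2 on "+" starting at position 20: window is [0, 20)
        seq = upstream + "ACGT" * 20
        return Genome(sequences={"c1": seq}), len(upstream)

    def test_window_over_40_percent_t_fails(self):
        genome, pos = self._genome_with_window("T" * 9 + "ACG" * 3 + "AC")
        pair = _pair(r2_pos=pos, r2_strand="+", flag=163, cigar="20M")
        assert genomic_polyA_filter(pair, genome) is False

    def test_window_at_exactly_40_percent_passes(self):
        genome, pos = self._genome_with_window("T" * 8 + "ACG" * 4)
        pair = _pair(r2_pos=pos, r2_strand="+", flag=163, cigar="20M")
        assert genomic_polyA_filter(pair, genome) is True

    def test_minus_strand_window_reads_complement(self):
        # all-A reference downstream: the "-" strand window is all T -> fail
        seq = "CG" * 15 + "A" * 30
        genome = Genome(sequences={"c1": seq})
        pair = _pair(r2_pos=10, r2_strand="-", flag=147, cigar="20M")
        # first sequenced base at pos 10+20-1=29, window [30, 50) revcomp
        assert genomic_polyA_filter(pair, genome) is False

    def test_matches_brute_force_on_random_genome(self, small_genome, rng):
        genome, _, _ = small_genome
        chrom = "chr1"
        seq = genome.sequences[chrom]
        for _ in range(300):
            strand = "+" if rng.random() < 0.5 else "-"
            pos = int(rng.integers(50, genome.lengths[chrom] - 100))
            cigar = "30M"
            pair = _pair(
                r2_pos=pos, r2_strand=strand,
                flag=147 if strand == "-" else 163, cigar=cigar, chrom=chrom,
            )
            # brute force: walk the reference base by base
            if strand == "+":
                window = seq[max(0, pos - 20) : pos]
                t_frac = window.count("T") / len(window)
            else:
                first = pos + 30 - 1
                window = seq[first + 1 : first + 21]
                comp = window.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                t_frac = comp.count("T") / len(comp)
            assert genomic_polyA_filter(pair, genome) == (t_frac <= 0.40)


class TestAssignSites:
    LENGTHS = {"c1": 10_000}

    def test_plus_read_maps_to_minus_site_one_left(self):
        pair = _pair(r2_pos=1000, r2_strand="+", flag=163)
        out = assign_sites([pair], 1, self.LENGTHS)
        assert out.sites == {("c1", 999, "-"): 1}

    def test_minus_read_maps_to_plus_site_one_right(self):
        pair = _pair(r2_pos=1951, r2_strand="-", flag=147, cigar="50M")
        # 5' end of the read is the rightmost base: 1951 + 50 - 1 = 2000
        out = assign_sites([pair], 1, self.LENGTHS)
        assert out.sites == {("c1", 2001, "+"): 1}

    def test_ssb_mode_is_unshifted(self):
        pairs = [
            _pair(r2_pos=1000, r2_strand="+", flag=163),
            _pair(r2_pos=1951, r2_strand="-", flag=147, cigar="50M", name="q"),
        ]
        out = assign_sites(pairs, 0, self.LENGTHS)
        assert out.sites == {("c1", 1000, "-"): 1, ("c1", 2000, "+"): 1}

    def test_out_of_bounds_site_dropped_and_counted(self):
        from ssingleap.sitecall import FilterStats

        stats = FilterStats()
        pair = _pair(r2_pos=0, r2_strand="+", flag=163)
        out = assign_sites([pair], 1, self.LENGTHS, stats)
        assert out.sites == {} and stats.out_of_bounds == 1


class TestPipeline:
    def test_clean_simulation_calls_equal_truth(self, small_genome):
        genome, annotations, _ = small_genome
        params = SimParams(
            n_site_reads=1500, n_hotspots=30, duplicate_rate=0.0,
            unblocked_background_rate=0.0, seed=9,
        )
        truth = plant_sites(genome, annotations, params)
        reads, _ = simulate_reads(genome, truth, params)
        sites, stats = run_pipeline(reads, genome, mode="ap")
        assert sites.sites == truth.sites  # positions, strands and depths
        assert stats.tag_pass == len(reads)

    def test_all_reject_input_gives_empty_set(self, small_genome):
        genome, _, _ = small_genome
        reads = [("r1", "AAAA" * 25, "CCCC" * 25)]
        sites, stats = run_pipeline(reads, genome, mode="ap")
        assert sites.sites == {} and stats.tag_pass == 0

    def test_filter_stats_counters_conserve(self, small_genome):
        genome, annotations, _ = small_genome
        params = SimParams(
            n_site_reads=2000, n_hotspots=40, duplicate_rate=0.15,
            unblocked_background_rate=0.02, seed=17,
        )
        truth = plant_sites(genome, annotations, params)
        reads, _ = simulate_reads(genome, truth, params)
        sites, stats = run_pipeline(reads, genome, mode="ap")
        # monotone through stages
        assert (
            stats.input_pairs >= stats.tag_pass >= stats.align_pass
            >= stats.dedup_pass >= stats.quality_pass >= stats.polya_pass
            >= stats.site_reads
        )
        # tag rejections account for the first gap
        tag_rejects = sum(
            v for k, v in stats.rejections.items() if k.startswith("r")
        )
        assert stats.input_pairs == stats.tag_pass + tag_rejects
        # polyA rejections account for that stage's gap
        assert stats.quality_pass - stats.polya_pass == stats.rejections.get("polya", 0)
        assert stats.site_reads == sites.site_reads
        assert stats.polya_pass == stats.site_reads + stats.out_of_bounds

    def test_ap_and_ssb_differ_by_exact_shift(self, small_genome):
        genome, annotations, _ = small_genome
        params = SimParams(
            n_site_reads=800, n_hotspots=0, duplicate_rate=0.0,
            unblocked_background_rate=0.0, seed=23,
        )
        truth = plant_sites(genome, annotations, params)
        reads, _ = simulate_reads(genome, truth, params)
        ap, _ = run_pipeline(reads, genome, mode="ap")
        ssb, _ = run_pipeline(reads, genome, mode="ssb")
        shifted = {
            (c, pos - 1 if strand == "+" else pos + 1, strand): d
            for (c, pos, strand), d in ap.sites.items()
        }
        assert shifted == ssb.sites
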