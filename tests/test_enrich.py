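"""Odds-ratio procedures, strand analyses, signatures and correlations,
each checked against independent brute-force oracles on small genomes."""

import numpy as np
import pandas as pd
import pytest

from ssingleap.enrich import (
    expression_stratum,
    mito_strand_analysis,
    nucleotide_composition,
    or_elements,
    or_pairwise,
    or_repeats,
    select_tpcn_het_snps,
    spearman_age_correlation,
    strand_purine_fractions,
    stratify_and_density,
    technical_bias_r2,
    template_nontemplate_ratio,
    tpcn_variant_or,
)
from ssingleap.io_formats import (
    APSiteSet,
    Genome,
    Interval,
    IntervalSet,
    Variant,
    VariantTable,
)
from ssingleap.sim_data import (
    SimParams,
    make_genome,
    make_mito_genome,
    plant_sites,
    plant_uniform_sites,
)


def _sites(d, **kw):
    return APSiteSet(sites=d, **kw)


class TestPairwise:
    def test_identical_sets(self):
        a = {("c1", i, "+") for i in range(10)}
        result = or_pairwise(a, set(a), genome_len=1000)
        # (10/10) / (10/1000) = 100
        assert result.odds_ratio == pytest.approx(100.0)

    def test_disjoint_sets(self):
        a = {("c1", i, "+") for i in range(10)}
        b = {("c1", i + 100, "+") for i in range(10)}
        assert or_pairwise(a, b, 1000).odds_ratio == 0.0

    def test_random_sets_near_one(self, rng):
        g = 200_000
        a = {("c1", int(p), "+") for p in rng.choice(g, 5_000, replace=False)}
        b = {("c1", int(p), "+") for p in rng.choice(g, 5_000, replace=False)}
        assert or_pairwise(a, b, g).odds_ratio == pytest.approx(1.0, abs=0.25)

    def test_empty_b_undefined(self):
        r = or_pairwise({("c1", 1, "+")}, set(), 100)
        assert r.observed_frac is None and r.odds_ratio is None


class TestRepeats:
    def test_uniform_sites_or_one(self, rng):
        genome_len = 10_000
        repeats = IntervalSet([Interval("c1", 0, 1_000, ".", "Satellite", ".")])
        d = {("c1", int(p), "+"): 1 for p in rng.choice(genome_len, 2_000, replace=False)}
        result = or_repeats(_sites(d), repeats, genome_len)["Satellite"]
        assert result.odds_ratio == pytest.approx(1.0, abs=0.25)

    def test_all_reads_in_class(self):
        repeats = IntervalSet([Interval("c1", 0, 100, ".", "LINE", ".")])
        d = {("c1", 5, "+"): 3, ("c1", 50, "-"): 7}
        result = or_repeats(_sites(d), repeats, 1_000)["LINE"]
        assert result.odds_ratio == pytest.approx(10.0)

    def test_depth_counts_separately_matches_per_read_oracle(self, rng):
        genome_len = 5_000
        repeats = IntervalSet([
            Interval("c1", 100, 600, ".", "SINE", "."),
            Interval("c1", 2_000, 2_800, ".", "SINE", "."),
        ])
        d = {
            ("c1", int(p), "+" if rng.random() < 0.5 else "-"): int(rng.integers(1, 6))
            for p in rng.choice(genome_len, 400, replace=False)
        }
        sites = _sites(d)
        result = or_repeats(sites, repeats, genome_len)["SINE"]
        # oracle: expand the multiset to individual reads, scan each
        reads_in = total = 0
        for (c, p, s), depth in d.items():
            for _ in range(depth):
                total += 1
                if (100 <= p < 600) or (2_000 <= p < 2_800):
                    reads_in += 1
        assert result.n_obs == reads_in and result.n_total == total
        expected = 1_300 / genome_len
        assert result.odds_ratio == pytest.approx(
            (reads_in / total) / expected, abs=1e-12)


class TestElements:
    def test_depth_collapses_to_one_matches_distinct_oracle(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 4_000))
        mask = IntervalSet([Interval("c1", 0, 500, ".", "rep", ".")])
        genome = Genome(sequences={"c1": seq}, repeat_mask=mask)
        elements = IntervalSet([Interval("c1", 1_000, 1_700, "+", "exon", "g1")])
        d = {
            ("c1", int(p), "+"): int(rng.integers(1, 6))
            for p in rng.choice(4_000, 600, replace=False)
        }
        result = or_elements(_sites(d), elements, genome)["exon"]
        distinct_nonrep = [k for k in d if k[1] >= 500]
        n_in = sum(1 for _, p, _ in distinct_nonrep if 1_000 <= p < 1_700)
        assert result.n_obs == n_in and result.n_total == len(distinct_nonrep)
        expected = 700 / 3_500
        assert result.odds_ratio == pytest.approx(
            (n_in / len(distinct_nonrep)) / expected, abs=1e-12)
        assert 0 < result.p_two_sided <= 1

    def test_masked_class_is_undefined(self, rng):
        seq = "ACGT" * 250
        mask = IntervalSet([Interval("c1", 0, 1_000, ".", "rep", ".")])
        genome = Genome(sequences={"c1": seq}, repeat_mask=mask)
        elements = IntervalSet([Interval("c1", 10, 20, "+", "exon", "g")])
        result = or_elements(_sites({}), elements, genome)["exon"]
        assert result.odds_ratio is None and result.expected_frac == 0.0

    def test_planted_enrichment_recovered(self, small_genome):
        genome, annotations, _ = small_genome
        params = SimParams(
            n_site_reads=10_000, n_hotspots=0, seed=55,
            element_enrichment={"exon": 3.0},
        )
        truth = plant_sites(genome, annotations, params)
        result = or_elements(truth.as_site_set(), annotations, genome)["exon"]
        assert result.odds_ratio == pytest.approx(3.0, abs=0.3)


class TestTemplateRatio:
    ELEMENTS = IntervalSet(
        [Interval("c1", 0, 1_000, "+", "gene", "g1")], stranded=True)

    def test_equal_counts_give_one(self):
        d = {("c1", 10, "+"): 1, ("c1", 20, "-"): 1}
        r = template_nontemplate_ratio(_sites(d), self.ELEMENTS)["gene"]
        assert r.ratio == 1.0

    def test_template_is_opposite_of_gene_strand(self):
        # "+" gene: template is "-"; 3 template vs 6 nontemplate -> 0.5
        d = {("c1", i, "-"): 1 for i in range(3)}
        d.update({("c1", i + 10, "+"): 1 for i in range(6)})
        r = template_nontemplate_ratio(_sites(d), self.ELEMENTS)["gene"]
        assert (r.template_count, r.nontemplate_count) == (3, 6)
        assert r.ratio == pytest.approx(0.5)

    def test_overlapping_elements_count_twice(self):
        elements = IntervalSet(
            [
                Interval("c1", 0, 100, "+", "gene", "a"),
                Interval("c1", 50, 150, "-", "gene", "b"),
            ],
            stranded=True,
        )
        d = {("c1", 60, "+"): 1}  # nontemplate for "a", template for "b"
        r = template_nontemplate_ratio(_sites(d), elements)["gene"]
        assert (r.template_count, r.nontemplate_count) == (1, 1)

    def test_strand_asymmetric_simulation_recovered(self, small_genome):
        genome, annotations, _ = small_genome
        params = SimParams(
            n_site_reads=10_000, n_hotspots=0, seed=66, strand_asymmetry=0.5)
        truth = plant_sites(genome, annotations, params)
        r = template_nontemplate_ratio(
            truth.as_site_set(), annotations, genome)["gene"]
        assert r.ratio == pytest.approx(0.5, abs=0.07)


class TestStratification:
    @pytest.mark.parametrize(
        "tpm,stratum", [(0.0, "non"), (1.0, "non"), (1.01, "low"),
                        (10.0, "low"), (10.1, "high")])
    def test_stratum_boundaries(self, tpm, stratum):
        assert expression_stratum(tpm) == stratum

    def test_uniform_sites_give_similar_densities(self, small_genome, rng):
        genome, annotations, expression = small_genome
        params = SimParams(n_site_reads=20_000, n_hotspots=0, seed=77)
        truth = plant_sites(genome, annotations, params)
        table = stratify_and_density(
            truth.as_site_set(), annotations, expression, genome)
        exon = table[table["class"] == "exon"]
        dens = (
            exon["template_density"].astype(float)
            + exon["nontemplate_density"].astype(float)
        )
        assert dens.max() / dens.min() < 2.0
        assert set(exon["stratum"]) == {"non", "low", "high"}

    def test_expression_coupled_planting_increases_density(self, small_genome):
        genome, annotations, expression = small_genome
        high_genes = [g for g, t in expression.items() if t > 10]
        high_exons = IntervalSet(
            [r for r in annotations.records
             if r.class_label == "exon" and r.name in high_genes],
            stranded=True,
        )
        params = SimParams(
            n_site_reads=15_000, n_hotspots=0, seed=88,
            element_enrichment={"exon": 1.0},
        )
        # plant extra density on high-expression exons only
        boosted = IntervalSet(
            [Interval(r.chrom, r.start, r.end, r.strand, "exon_hi", r.name)
             for r in high_exons.records]
            + annotations.records,
            stranded=True,
        )
        params = SimParams(
            n_site_reads=15_000, n_hotspots=0, seed=88,
            element_enrichment={"exon_hi": 3.0},
        )
        truth = plant_sites(genome, boosted, params)
        table = stratify_and_density(
            truth.as_site_set(), annotations, expression, genome)
        exon = table[table["class"] == "exon"].set_index("stratum")
        dens = exon["template_density"] + exon["nontemplate_density"]
        assert dens["high"] > 1.5 * dens["non"]


class TestComposition:
    def test_minus_strand_site_reads_complement(self):
        genome = Genome(sequences={"c1": "TTTT"})
        comp = nucleotide_composition(
            _sites({("c1", 1, "-"): 1}), genome, (1,), mask_repeats=False)
        assert comp[1]["A"] == 1.0

    def test_balanced_background_quarters(self):
        genome = Genome(sequences={"c1": "ACGT" * 100})
        comp = nucleotide_composition(_sites({}), genome, (1,))
        assert all(v == pytest.approx(0.25) for v in comp["background"].values())

    def test_planted_weights_recovered(self):
        genome, annotations, _ = make_genome(
            n_chrom=2, chrom_len=100_000, gc=0.5, repeat_frac=0.0,
            n_genes=10, seed=90,
        )
        params = SimParams(n_site_reads=10_000, n_hotspots=0, seed=91)
        truth = plant_sites(genome, annotations, params)
        comp = nucleotide_composition(truth.as_site_set(), genome, (1,))[1]
        for base, weight in zip("AGCT", params.purine_weights):
            assert comp[base] == pytest.approx(weight, abs=0.03)


class TestTechnicalBias:
    def test_identical_vectors_r2_one(self):
        d = {("c1", 1, "+"): 3, ("c1", 2, "+"): 7, ("c1", 3, "-"): 1}
        assert technical_bias_r2(_sites(d), _sites(dict(d))) == pytest.approx(1.0)

    def test_all_zero_control_undefined(self):
        d = {("c1", 1, "+"): 3, ("c1", 2, "+"): 7}
        assert technical_bias_r2(_sites(d), _sites({("c2", 1, "+"): 5})) is None

    def test_independent_simulations_near_zero(self, small_genome):
        genome, annotations, _ = small_genome
        a = plant_sites(genome, annotations, SimParams(
            n_site_reads=5_000, n_hotspots=100, seed=92)).as_site_set()
        b = plant_sites(genome, annotations, SimParams(
            n_site_reads=5_000, n_hotspots=100, seed=93)).as_site_set()
        r2 = technical_bias_r2(a, b)
        assert r2 is not None and r2 < 0.02


def _variant(chrom, pos, ref, alt, context, zyg="het"):
    return Variant(chrom, pos, ref, alt, "SNP", zyg, context)


class TestTpcnSignature:
    def test_selection_requires_tpc_context(self):
        table = VariantTable([
            _variant("c1", 10, "C", "G", "TCA"),   # kept: TpC on +
            _variant("c1", 20, "C", "G", "ACA"),   # dropped: no 5' T
            _variant("c1", 30, "G", "C", "TGA"),   # kept: TpC on - (A 3' of G)
            _variant("c1", 40, "G", "C", "TGT"),   # dropped
            _variant("c1", 50, "C", "T", "TCC", zyg="hom"),  # dropped: hom
        ])
        selected = select_tpcn_het_snps(table)
        assert [(v.pos, m) for v, m in selected] == [(10, "C>G"), (30, "C>G")]

    def test_direct_arithmetic_oracle(self):
        records = []
        pos = 0
        # 50 C>G, 25 C>A, 25 C>T in TpCpN context
        for mtype, alt, n in (("C>G", "G", 50), ("C>A", "A", 25), ("C>T", "T", 25)):
            for _ in range(n):
                records.append(_variant("c1", pos, "C", alt, "TCA"))
                pos += 10
        table = VariantTable(records)
        # overlap 8 C>G, 1 C>A, 1 C>T
        overlaps = (
            [r.pos for r in records[:8]]
            + [records[50].pos]
            + [records[75].pos]
        )
        sites = _sites({("c1", p, "+"): 1 for p in overlaps})
        out = tpcn_variant_or(table, sites)
        assert out["C>G"].odds_ratio == pytest.approx((8 / 10) / (50 / 100))
        assert out["C>A"].odds_ratio == pytest.approx((1 / 10) / (25 / 100))

    def test_proportional_overlap_gives_unit_ors(self):
        records, pos = [], 0
        for alt, n in (("G", 40), ("A", 20), ("T", 20)):
            for _ in range(n):
                records.append(_variant("c1", pos, "C", alt, "TCA"))
                pos += 5
        table = VariantTable(records)
        chosen = records[0:20] + records[40:50] + records[60:70]  # half of each
        sites = _sites({("c1", v.pos, "+"): 1 for v in chosen})
        out = tpcn_variant_or(table, sites)
        for mtype in ("C>G", "C>A", "C>T"):
            assert out[mtype].odds_ratio == pytest.approx(1.0)

    def test_preferential_planting_recovered(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 50_000))
        genome = Genome(sequences={"c1": seq})
        records = []
        for p in range(1, 49_999):
            if seq[p] == "C" and seq[p - 1] == "T":
                alt = str(rng.choice(["G", "A", "T"]))
                records.append(_variant("c1", p, "C", alt, seq[p - 1 : p + 2]))
        table = VariantTable(records[:600])
        cg = [v for v in table.records if v.alt == "G"]
        others = [v for v in table.records if v.alt != "G"]
        d = {("c1", v.pos, "+"): 1 for v in cg[: len(cg) // 2]}
        d.update({("c1", v.pos, "+"): 1 for v in others[: len(others) // 10]})
        out = tpcn_variant_or(table, _sites(d))
        assert out["C>G"].odds_ratio > out["C>A"].odds_ratio
        assert out["C>G"].odds_ratio > out["C>T"].odds_ratio


class TestMito:
    def test_equal_strands_fold_one(self):
        d = {("chrM", 10, "+"): 5, ("chrM", 20, "-"): 5}
        out = mito_strand_analysis(_sites(d))
        assert out["fold"] == 1.0

    def test_all_reads_in_excluded_window_undefined(self):
        d = {("chrM", 15_700, "-"): 10}
        assert mito_strand_analysis(_sites(d), exclude=(15_650, 15_900)) is None

    def test_planted_asymmetry_recovered(self):
        genome = make_mito_genome(seed=5)
        truth = plant_uniform_sites(
            genome, 20_000, strand_weights=(1.0, 2.55), seed=6,
            exclude=("chrM", 15_650, 15_900),
        )
        out = mito_strand_analysis(
            truth.as_site_set(), exclude=(15_650, 15_900))
        assert out["fold"] == pytest.approx(2.55, rel=0.1)

    def test_purine_fraction_of_synthetic_mito(self):
        genome = make_mito_genome(heavy_purine_frac=0.5311, seed=5)
        heavy, light = strand_purine_fractions(genome, "chrM")
        assert heavy == pytest.approx(0.5311, abs=0.01)
        assert heavy + light == pytest.approx(1.0)


class TestAgeCorrelation:
    def test_monotone_metric_gives_unit_rho(self):
        table = pd.DataFrame({
            "tissue": ["heart"] * 4,
            "age": [3, 12, 19, 22],
            "apf": [0.1, 0.2, 0.3, 0.4],
        })
        out = spearman_age_correlation(table)
        assert out["heart"] == pytest.approx(1.0)

    def test_declining_metric_gives_negative_rho(self, rng):
        ages = np.repeat([3, 12, 19, 22], 3)
        apf = 0.4 - 0.01 * ages + rng.normal(0, 0.005, size=len(ages))
        table = pd.DataFrame({"tissue": ["liver"] * len(ages), "age": ages, "apf": apf})
        out = spearman_age_correlation(table)
        assert out["liver"] < -0.5

    def test_independent_metric_near_zero(self, rng):
        n = 200
        table = pd.DataFrame({
            "tissue": ["x"] * n,
            "age": rng.integers(1, 30, n),
            "apf": rng.random(n),
        })
        out = spearman_age_correlation(table)
        assert abs(out["x"]) < 0.2

    def test_constant_metric_undefined(self):
        table = pd.DataFrame({
            "tissue": ["x"] * 4, "age": [1, 2, 3, 4], "apf": [0.5] * 4})
        assert spearman_age_correlation(table)["x"] is None
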