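"""Enrichment and association statistics.

Three odds-ratio procedures are used, each defined as observed fraction over
expected fraction:

1. *pairwise* — overlap between two site catalogs (technical replicates or
   two AP endonucleases) on the whole stranded genome: expected is
   ``|A| / G`` with ``G`` the stranded genome size, observed is
   ``|A intersect B| / |B|``.
2. *repeats* — read-weighted enrichment in repeat classes on the unmasked
   genome: sites with the same coordinates count separately (per read).
3. *elements* — enrichment of distinct, repeat-masked site coordinates in
   genomic element classes; coordinates are collapsed and the expected
   fraction uses nonrepeat lengths only. Significance is an exact two-sided
   binomial test.

The module also provides template/nontemplate strand ratios, expression
stratification, nucleotide composition of site positions, the
unblocked-control technical-bias r-squared, the TpCpN heterozygous-variant
signature, mitochondrial strand asymmetry and age correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io_formats import (
    APSiteSet,
    Genome,
    IntervalSet,
    PointIndex,
    VariantTable,
    merge_intervals,
)

__all__ = [
    "EnrichmentResult",
    "StrandRatio",
    "or_pairwise",
    "or_repeats",
    "or_elements",
    "template_nontemplate_ratio",
    "stratify_and_density",
    "nucleotide_composition",
    "technical_bias_r2",
    "tpcn_variant_or",
    "select_tpcn_het_snps",
    "mito_strand_analysis",
    "spearman_age_correlation",
    "strand_purine_fractions",
]

SiteKey = tuple[str, int, str]


@dataclass
class EnrichmentResult:
    feature_class: str
    observed_frac: float | None
    expected_frac: float
    odds_ratio: float | None
    n_obs: int
    n_total: int
    p_two_sided: float | None
    mode: str

    def __post_init__(self) -> None:
        if self.odds_ratio is not None and self.odds_ratio < 0:
            raise ValueError("odds ratio cannot be negative")


@dataclass
class StrandRatio:
    element_class: str
    template_count: int
    nontemplate_count: int

    @property
    def ratio(self) -> float | None:
        if self.nontemplate_count == 0:
            return None
        return self.template_count / self.nontemplate_count


def _binom_p(k: int, n: int, p: float) -> float | None:
    if n == 0 or not 0 < p < 1:
        return None
    return float(stats.binomtest(k, n, p, alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Odds-ratio procedures


def or_pairwise(
    set_a: set[SiteKey] | APSiteSet,
    set_b: set[SiteKey] | APSiteSet,
    genome_len: int,
    label: str = "pairwise",
) -> EnrichmentResult:
    """Overlap odds ratio between two position catalogs.

    ``genome_len`` is the size of the position space; stranded site catalogs
    should pass twice the base count. Expected = |A| / G; observed =
    |A & B| / |B|. Repeats are *not* masked here (whole-genome analysis).
    """
    a = set(set_a.sites) if isinstance(set_a, APSiteSet) else set(set_a)
    b = set(set_b.sites) if isinstance(set_b, APSiteSet) else set(set_b)
    expected = len(a) / genome_len
    if len(b) == 0:
        return EnrichmentResult(label, None, expected, None, 0, 0, None, "pairwise")
    n_obs = len(a & b)
    observed = n_obs / len(b)
    odds = observed / expected if expected > 0 else None
    return EnrichmentResult(
        label, observed, expected, odds, n_obs, len(b),
        _binom_p(n_obs, len(b), expected), "pairwise",
    )


def or_repeats(
    sites: APSiteSet, repeat_classes: IntervalSet, genome_len: int
) -> dict[str, EnrichmentResult]:
    """Read-weighted enrichment per repeat class over the unmasked genome.

    Observed = site reads inside the class / all site reads (depth counts);
    expected = merged class length / genome base length.
    """
    total_reads = sites.site_reads
    out: dict[str, EnrichmentResult] = {}
    for cls in repeat_classes.classes():
        merged = repeat_classes.by_class(cls).merged()
        index = PointIndex(merged)
        class_len = sum(int((m[:, 1] - m[:, 0]).sum()) for m in merged.values())
        expected = class_len / genome_len
        in_class = sum(
            depth for (chrom, pos, _), depth in sites.sites.items()
            if index(chrom, pos)
        )
        observed = in_class / total_reads if total_reads else None
        odds = (observed / expected) if (observed is not None and expected > 0) else None
        out[cls] = EnrichmentResult(
            cls, observed, expected, odds, in_class, total_reads,
            _binom_p(in_class, total_reads, expected) if total_reads else None,
            "repeats",
        )
    return out


def or_elements(
    sites: APSiteSet, elements: IntervalSet, genome: Genome
) -> dict[str, EnrichmentResult]:
    """Collapsed-coordinate enrichment per element class on the
    repeat-masked genome.

    Sites inside the repeat mask are removed and duplicate coordinates
    collapsed; expected = nonrepeat class length / nonrepeat genome length.
    """
    distinct = [
        k for k in sites.sites if not genome.is_masked(k[0], k[1])
    ]
    n_total = len(distinct)
    nonrepeat = genome.nonrepeat_intervals()
    nonrepeat_len = genome.nonrepeat_len
    out: dict[str, EnrichmentResult] = {}
    for cls in elements.classes():
        merged = elements.by_class(cls).merged()
        class_nonrep = _intersect_length(merged, nonrepeat)
        index = PointIndex(merged)
        expected = class_nonrep / nonrepeat_len if nonrepeat_len else 0.0
        if expected == 0:
            out[cls] = EnrichmentResult(cls, None, 0.0, None, 0, n_total, None, "elements")
            continue
        n_obs = sum(1 for chrom, pos, _ in distinct if index(chrom, pos))
        observed = n_obs / n_total if n_total else None
        odds = observed / expected if observed is not None else None
        out[cls] = EnrichmentResult(
            cls, observed, expected, odds, n_obs, n_total,
            _binom_p(n_obs, n_total, expected) if n_total else None, "elements",
        )
    return out


def _intersect_length(
    merged_a: dict[str, np.ndarray], merged_b: dict[str, np.ndarray]
) -> int:
    total = 0
    for chrom, a in merged_a.items():
        b = merged_b.get(chrom)
        if b is None or len(b) == 0 or len(a) == 0:
            continue
        i = j = 0
        while i < len(a) and j < len(b):
            lo = max(a[i, 0], b[j, 0])
            hi = min(a[i, 1], b[j, 1])
            if hi > lo:
                total += int(hi - lo)
            if a[i, 1] < b[j, 1]:
                i += 1
            else:
                j += 1
    return total


# ---------------------------------------------------------------------------
# Strand analyses


def _element_trees(elements: IntervalSet) -> dict[tuple[str, str], IntervalTree]:
    """(class, chrom) -> interval tree with element strands as payloads."""
    trees: dict[tuple[str, str], IntervalTree] = {}
    for r in elements.records:
        trees.setdefault((r.class_label, r.chrom), IntervalTree()).addi(
            r.start, r.end, r.strand
        )
    return trees


def template_nontemplate_ratio(
    sites: APSiteSet, elements: IntervalSet, genome: Genome | None = None
) -> dict[str, StrandRatio]:
    """Template vs nontemplate counts of distinct sites per stranded element
    class; the template strand is the strand opposite the element's strand.
    A site overlapping several elements counts once per element. Sites in
    the repeat mask are excluded when a genome is given."""
    if not elements.stranded:
        raise ValueError("template/nontemplate analysis needs stranded elements")
    trees = _element_trees(elements)
    out: dict[str, StrandRatio] = {}
    for cls in elements.classes():
        template = nontemplate = 0
        for chrom, pos, strand in sites.sites:
            if genome is not None and genome.is_masked(chrom, pos):
                continue
            tree = trees.get((cls, chrom))
            if tree is None:
                continue
            for hit in tree.at(pos):
                if hit.data not in ("+", "-"):
                    continue
                if strand != hit.data:
                    template += 1
                else:
                    nontemplate += 1
        out[cls] = StrandRatio(cls, template, nontemplate)
    return out


STRATA = (("non", 0.0, 1.0), ("low", 1.0, 10.0), ("high", 10.0, float("inf")))


def expression_stratum(tpm: float) -> str:
    """Stratum boundaries: non (TPM <= 1), low (1 < TPM <= 10), high (> 10)."""
    for name, lo, hi in STRATA:
        if lo < tpm <= hi or (name == "non" and tpm <= lo):
            return name
    return "high"


def stratify_and_density(
    sites: APSiteSet,
    elements: IntervalSet,
    expression: dict[str, float],
    genome: Genome,
    classes: tuple[str, ...] = ("exon", "intron", "tss_1kb"),
) -> pd.DataFrame:
    """Expression-stratified enrichment, strand densities and strand ratios.

    Gene-linked elements (matched by element ``name``) are partitioned into
    the three expression strata; per class and stratum the collapsed-site
    odds ratio, per-strand site densities (distinct nonrepeat sites per bp
    of merged element length) and the template/nontemplate ratio are
    reported. Genes without a TPM fall into the "non" stratum.
    """
    rows = []
    for cls in classes:
        cls_set = elements.by_class(cls)
        for stratum, _, _ in STRATA:
            recs = [
                r for r in cls_set.records
                if expression_stratum(expression.get(r.name, 0.0)) == stratum
            ]
            subset = IntervalSet(recs, stranded=True)
            if not recs:
                continue
            er = or_elements(sites, subset, genome)[cls]
            ratios = template_nontemplate_ratio(sites, subset, genome)[cls]
            merged = subset.merged()
            length = sum(int((m[:, 1] - m[:, 0]).sum()) for m in merged.values())
            rows.append({
                "class": cls,
                "stratum": stratum,
                "n_elements": len(recs),
                "element_bp": length,
                "odds_ratio": er.odds_ratio,
                "p_two_sided": er.p_two_sided,
                "template_sites": ratios.template_count,
                "nontemplate_sites": ratios.nontemplate_count,
                "template_density": ratios.template_count / length if length else None,
                "nontemplate_density": ratios.nontemplate_count / length if length else None,
                "template_ratio": ratios.ratio,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Composition, bias and signatures


def nucleotide_composition(
    sites: APSiteSet,
    genome: Genome,
    min_depths: tuple[int, ...] = (1, 2, 3),
    mask_repeats: bool = True,
) -> dict[str | int, dict[str, float]]:
    """Fractions of A/C/G/T at distinct site positions (base read on the
    site strand) for each depth threshold, plus the nonrepeat genomic
    background over both strands under key ``"background"``. Sites on N
    bases are excluded."""
    out: dict[str | int, dict[str, float]] = {}
    for md in min_depths:
        counts = {b: 0 for b in "ACGT"}
        for (chrom, pos, strand), depth in sites.sites.items():
            if depth < md:
                continue
            if mask_repeats and genome.is_masked(chrom, pos):
                continue
            base = genome.base(chrom, pos, strand)
            if base in counts:
                counts[base] += 1
        n = sum(counts.values())
        out[md] = {b: (c / n if n else 0.0) for b, c in counts.items()}

    bg = {b: 0 for b in "ACGT"}
    for chrom, arr in genome.nonrepeat_intervals().items():
        seq = genome.sequences[chrom]
        for s, e in arr:
            segment = seq[int(s):int(e)]
            for b in "ACGT":
                bg[b] += segment.count(b)
    # both strands: each base pairs with its complement
    pair = {"A": "T", "T": "A", "C": "G", "G": "C"}
    total = 2 * sum(bg.values())
    out["background"] = {
        b: ((bg[b] + bg[pair[b]]) / total if total else 0.0) for b in "ACGT"
    }
    return out


def technical_bias_r2(
    sample: APSiteSet,
    control: APSiteSet,
    universe: str = "all",
    include_repeats: bool = True,
    genome: Genome | None = None,
    min_depth: int = 2,
) -> float | None:
    """Variance attributable to protocol steps shared with the unblocked
    control: squared Pearson correlation of read depths over the sample's
    site universe (``"all"`` or ``"hotspots"``), control depth 0 where
    absent. None when either vector is constant."""
    if universe not in ("all", "hotspots"):
        raise ValueError("universe must be 'all' or 'hotspots'")
    keys = [
        k for k, d in sample.sites.items()
        if (universe == "all" or d >= min_depth)
        and (include_repeats or genome is None or not genome.is_masked(k[0], k[1]))
    ]
    if len(keys) < 2:
        return None
    x = np.array([sample.sites[k] for k in keys], dtype=float)
    y = np.array([control.sites.get(k, 0) for k in keys], dtype=float)
    if x.std() == 0 or y.std() == 0:
        return None
    r = float(np.corrcoef(x, y)[0, 1])
    return r * r


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def select_tpcn_het_snps(variants: VariantTable) -> list[tuple]:
    """Heterozygous SNPs with a C allele in TpCpN context on either strand.

    Returns (variant, mutation_type) tuples where mutation_type is "C>G",
    "C>A" or "C>T" read on the strand where the allele is a C; for a
    reference G the context is evaluated on the reverse complement.
    """
    out = []
    for v in variants:
        if v.vtype != "SNP" or v.zygosity != "het" or v.context is None:
            continue
        if v.ref == "C" and v.context[0] == "T":
            out.append((v, f"C>{v.alt}"))
        elif v.ref == "G" and v.context[2] == "A":
            out.append((v, f"C>{_COMP[v.alt]}"))
    return out


def tpcn_variant_or(
    variants: VariantTable, sites: APSiteSet
) -> dict[str, EnrichmentResult]:
    """Odds ratios of site overlap for C>G / C>A / C>T heterozygous SNPs in
    TpCpN context.

    Expected fraction of a type = its share among the three types genome
    wide; observed = its share among the variants whose position carries a
    site on either strand.
    """
    selected = select_tpcn_het_snps(variants)
    positions = {(k[0], k[1]) for k in sites.sites}
    type_counts = {"C>G": 0, "C>A": 0, "C>T": 0}
    overlap_counts = {"C>G": 0, "C>A": 0, "C>T": 0}
    for v, mtype in selected:
        if mtype not in type_counts:
            continue
        type_counts[mtype] += 1
        if (v.chrom, v.pos) in positions:
            overlap_counts[mtype] += 1
    total = sum(type_counts.values())
    total_overlap = sum(overlap_counts.values())
    out = {}
    for mtype in type_counts:
        expected = type_counts[mtype] / total if total else 0.0
        observed = (
            overlap_counts[mtype] / total_overlap if total_overlap else None
        )
        odds = (
            observed / expected if observed is not None and expected > 0 else None
        )
        out[mtype] = EnrichmentResult(
            mtype, observed, expected, odds, overlap_counts[mtype], total_overlap,
            _binom_p(overlap_counts[mtype], total_overlap, expected)
            if total_overlap else None,
            "elements",
        )
    return out


def mito_strand_analysis(
    sites: APSiteSet,
    chrom: str = "chrM",
    exclude: tuple[int, int] | None = None,
) -> dict[str, float] | None:
    """Read-weighted strand fractions on the mitochondrial chromosome with an
    optional excluded window (applied to both strands), e.g. the control
    region that dominates the signal. Heavy strand is "-", light is "+";
    ``fold`` is heavy/light. None when no reads remain."""
    reads = {"+": 0, "-": 0}
    for (c, pos, strand), depth in sites.sites.items():
        if c != chrom:
            continue
        if exclude is not None and exclude[0] <= pos < exclude[1]:
            continue
        reads[strand] += depth
    total = reads["+"] + reads["-"]
    if total == 0:
        return None
    return {
        "heavy_frac": reads["-"] / total,
        "light_frac": reads["+"] / total,
        "fold": reads["-"] / reads["+"] if reads["+"] else float("inf"),
        "n_reads": total,
    }


def strand_purine_fractions(
    genome: Genome, chrom: str, exclude: tuple[int, int] | None = None
) -> tuple[float, float]:
    """Purine (A+G) fraction of the "-" (heavy) and "+" (light) strands of
    one chromosome, optionally excluding a window."""
    seq = genome.sequences[chrom]
    if exclude is not None:
        seq = seq[: exclude[0]] + seq[exclude[1]:]
    n = len(seq)
    light = (seq.count("A") + seq.count("G")) / n
    heavy = (seq.count("C") + seq.count("T")) / n  # purines on the complement
    return heavy, light


def spearman_age_correlation(
    table: pd.DataFrame,
    metric: str = "apf",
    tissue_col: str = "tissue",
    age_col: str = "age",
) -> dict[str, float | None]:
    """Spearman rho of a per-sample metric against age, per tissue and
    pooled; None for groups with fewer than 3 samples or constant input."""
    out: dict[str, float | None] = {}

    def rho(sub: pd.DataFrame) -> float | None:
        if len(sub) < 3:
            return None
        if sub[metric].nunique() < 2 or sub[age_col].nunique() < 2:
            return None
        return float(stats.spearmanr(sub[metric], sub[age_col]).statistic)

    for tissue, sub in table.groupby(tissue_col):
        out[str(tissue)] = rho(sub)
    out["pooled"] = rho(table)
    return out
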