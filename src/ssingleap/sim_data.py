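"""In-silico simulator of the 3'OH-tagging abasic-site protocol.

The simulator emulates the full molecular chain: abasic sites are planted on
either strand of a synthetic genome (with purine bias, single-nucleotide
hotspots, element-level enrichment multipliers and transcriptional strand
asymmetry); an AP endonuclease cleaves immediately 5' of each lesion leaving
a 3'OH on the base one step 5'-ward on the damaged strand; that terminus is
polyA-tailed and amplified, so read 2 starts with a polyT run followed by
the reverse complement of the damaged strand walking inward from the
terminus, while read 1 carries the polyG-containing tag and sequence from
the other fragment end. Blocking failures ("unblocked" 3'OH at fragment
ends), PCR duplicates and uracil-derived spike-in controls are modelled so
every downstream stage of the pipeline has ground truth to recover.

Geometry, in 0-based coordinates: a lesion at position ``s`` on the "+"
strand has its 3'OH terminus at ``s - 1``; read 2 therefore aligns to the
"-" strand with its first sequenced base on reference position ``s - 1``.
A lesion on "-" mirrors this with the terminus at ``s + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    APSiteSet,
    AlignedRead,
    AlignedReadPair,
    Genome,
    Interval,
    IntervalSet,
    revcomp,
)
from .sitecall import TAG_R1_LITERAL

__all__ = [
    "SimParams",
    "TruthSites",
    "make_genome",
    "make_mito_genome",
    "make_spike_seqs",
    "plant_sites",
    "plant_uniform_sites",
    "simulate_reads",
    "make_spike_reads",
    "align_exact_pairs",
    "write_sam",
    "write_fastq_pairs",
]

SiteKey = tuple[str, int, str]


@dataclass
class SimParams:
    """Tunable study conditions for the genomic simulation.

    Defaults mirror the assay as characterised on real libraries: a
    (39, 31, 15, 15)% A/G/C/T lesion composition, a 1.5% unblocked-terminus
    background, tag runs G9-11 / T11-13, and a flat PCR duplicate rate.
    """

    n_site_reads: int = 20_000
    purine_weights: tuple[float, float, float, float] = (0.39, 0.31, 0.15, 0.15)
    n_hotspots: int = 200
    hotspot_depth_range: tuple[int, int] = (3, 8)
    unblocked_background_rate: float = 0.015
    duplicate_rate: float = 0.10
    read_len: int = 100
    g_run_range: tuple[int, int] = (9, 11)
    t_run_range: tuple[int, int] = (11, 13)
    fragment_range: tuple[int, int] = (150, 400)
    element_enrichment: dict[str, float] = field(default_factory=dict)
    strand_asymmetry: float = 1.0  # template:nontemplate lesion weight in genes
    seed: int = 0

    def __post_init__(self) -> None:
        for rate in (self.unblocked_background_rate, self.duplicate_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"rate {rate} outside [0, 1]")
        w = self.purine_weights
        if any(x < 0 for x in w) or sum(w) == 0:
            raise ValueError("purine_weights must be non-negative, not all zero")
        if self.fragment_range[0] < self.read_len:
            raise ValueError("fragments must be at least one read long")
        if self.strand_asymmetry <= 0:
            raise ValueError("strand_asymmetry must be positive")


@dataclass
class TruthSites:
    """Planted ground truth: lesion positions, expected read counts and the
    subset flagged as hotspots."""

    sites: dict[SiteKey, int]
    hotspots: set[SiteKey]
    class_weights: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        assert all(r >= 1 for r in self.sites.values())
        assert self.hotspots <= set(self.sites)

    def as_site_set(self, **metadata) -> APSiteSet:
        return APSiteSet(sites=dict(self.sites), **metadata)


# ---------------------------------------------------------------------------
# Synthetic genomes


_REPEAT_CLASSES = ("Satellite", "LINE", "SINE", "LTR")
_REGULATORY_CLASSES = ("PLS", "pELS", "dELS")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(np.array(list("ACGT")), size=n, p=probs))


def make_genome(
    n_chrom: int = 2,
    chrom_len: int = 100_000,
    gc: float = 0.42,
    repeat_frac: float = 0.2,
    n_genes: int = 20,
    seed: int = 0,
    tss_flank: int = 1_000,
) -> tuple[Genome, IntervalSet, dict[str, float]]:
    """Build a random genome with repeats, genes and regulatory annotation.

    Returns ``(genome, annotations, expression)``. Annotation classes:
    ``gene``, ``exon``, ``intron``, ``tss_1kb`` (TSS +/- 1 kb, clipped at
    chromosome ends) and the regulatory classes PLS/pELS/dELS. Gene TPMs span
    the three expression strata (<=1, 1-10, >10). Deterministic per seed.
    """
    if not 0.0 <= repeat_frac < 1.0:
        raise ValueError("repeat_frac must be in [0, 1)")
    rng = np.random.default_rng(seed)
    sequences = {
        f"chr{i + 1}": _random_seq(rng, chrom_len, gc) for i in range(n_chrom)
    }
    chroms = list(sequences)

    # repeat mask: random blocks until the target fraction is covered
    # (realised coverage tracked per base so overlaps do not undershoot)
    mask_records: list[Interval] = []
    target = int(repeat_frac * n_chrom * chrom_len)
    covered_mask = {c: np.zeros(chrom_len, dtype=bool) for c in chroms}
    covered = 0
    guard = 0
    while covered < target and guard < 100_000:
        guard += 1
        chrom = chroms[rng.integers(n_chrom)]
        length = int(rng.integers(300, 2_000))
        start = int(rng.integers(0, chrom_len - length))
        mask_records.append(
            Interval(chrom, start, start + length, ".",
                     str(rng.choice(_REPEAT_CLASSES)), ".")
        )
        block = covered_mask[chrom][start : start + length]
        covered += int(length - block.sum())
        block[:] = True

    genome = Genome(sequences=sequences, repeat_mask=IntervalSet(mask_records))

    # non-overlapping genes with exon/intron structure
    annotations: list[Interval] = []
    expression: dict[str, float] = {}
    gene_len = 4_000
    per_chrom = -(-n_genes // n_chrom)
    usable = chrom_len - 2 * tss_flank - gene_len
    if usable < per_chrom * gene_len:
        raise ValueError("genes exceed chromosome: reduce n_genes or gene length")
    gi = 0
    for chrom in chroms:
        slots = np.sort(rng.choice(usable // gene_len, size=per_chrom, replace=False))
        for slot in slots:
            if gi >= n_genes:
                break
            start = tss_flank + int(slot) * gene_len + int(rng.integers(0, 200))
            end = start + gene_len - 400
            strand = "+" if rng.random() < 0.5 else "-"
            name = f"gene{gi + 1}"
            annotations.append(Interval(chrom, start, end, strand, "gene", name))
            # exons: alternating blocks within the gene
            n_exons = int(rng.integers(2, 5))
            bounds = np.sort(rng.choice(
                np.arange(start + 100, end - 100), size=2 * n_exons, replace=False))
            prev_end = None
            for k in range(n_exons):
                es, ee = int(bounds[2 * k]), int(bounds[2 * k + 1])
                if es == ee:
                    ee += 1
                annotations.append(Interval(chrom, es, ee, strand, "exon", name))
                if prev_end is not None and prev_end < es:
                    annotations.append(
                        Interval(chrom, prev_end, es, strand, "intron", name))
                prev_end = ee
            tss = start if strand == "+" else end - 1
            fs = max(0, tss - tss_flank)
            fe = min(chrom_len, tss + tss_flank)
            annotations.append(Interval(chrom, fs, fe, strand, "tss_1kb", name))
            # expression spanning the three strata
            stratum = gi % 3
            if stratum == 0:
                tpm = float(rng.uniform(0.0, 1.0))
            elif stratum == 1:
                tpm = float(rng.uniform(1.001, 10.0))
            else:
                tpm = float(10.0 ** rng.uniform(1.001, 3.0))
            expression[name] = round(tpm, 3)
            gi += 1

    for cls in _REGULATORY_CLASSES:
        for _ in range(max(3, n_genes // 2)):
            chrom = chroms[rng.integers(n_chrom)]
            length = int(rng.integers(200, 500))
            start = int(rng.integers(0, chrom_len - length))
            annotations.append(Interval(chrom, start, start + length, ".", cls, "."))

    return genome, IntervalSet(annotations, stranded=True), expression


def make_mito_genome(
    length: int = 16_299,
    heavy_purine_frac: float = 0.5311,
    seed: int = 0,
    name: str = "chrM",
) -> Genome:
    """Synthetic stand-in for a mitochondrial chromosome.

    The real mitochondrial reference cannot be bundled, so this builds a
    random sequence whose "-" (heavy) strand purine fraction matches the
    requested value: a "-"-strand purine corresponds to a C or T on the "+"
    strand, so P(C) + P(T) is set to ``heavy_purine_frac``.
    """
    rng = np.random.default_rng(seed)
    p_ct = heavy_purine_frac
    probs = [(1 - p_ct) / 2, p_ct / 2, (1 - p_ct) / 2, p_ct / 2]  # A C G T
    seq = "".join(rng.choice(np.array(list("ACGT")), size=length, p=probs))
    return Genome(sequences={name: seq})


def make_spike_seqs(
    n: int = 3, length: int = 500, seed: int = 0, clamp: int = 5
) -> dict[str, str]:
    """Random spike-in amplicon sequences with G/C clamps at both ends
    (primer-design style), so amplicon termini carry no A/T bases."""
    rng = np.random.default_rng(seed)
    out = {}
    for i in range(n):
        core = _random_seq(rng, length - 2 * clamp, 0.5)
        left = "".join(rng.choice(np.array(list("GC")), size=clamp))
        right = "".join(rng.choice(np.array(list("GC")), size=clamp))
        out[f"spike{i + 1}"] = left + core + right
    return out


# ---------------------------------------------------------------------------
# Lesion planting


_BASE_INDEX = {"A": 0, "G": 1, "C": 2, "T": 3}


def _detectable_weights(
    genome: Genome, params: SimParams
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per-position, per-strand sampling weights for lesion placement.

    Weights combine the per-nucleotide class weights with zeros at positions
    the assay cannot report: lesions whose fragment would not fit inside the
    chromosome, N bases, and positions the genomic polyA artifact filter
    removes by construction.
    """
    wA, wG, wC, wT = params.purine_weights
    plus_w = {"A": wA, "G": wG, "C": wC, "T": wT, "N": 0.0}
    frag_max = params.fragment_range[1]
    window = 20
    out = {}
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        n = len(seq)
        w_plus = np.array([plus_w[b] for b in seq])
        # lesion on "-" sits on the complementary base
        comp = {"A": wT, "C": wG, "G": wC, "T": wA, "N": 0.0}
        w_minus = np.array([comp[b] for b in seq])

        # fragment fit: "+" lesion at s needs s >= frag_max;
        # "-" lesion at s needs s <= n - frag_max - 1
        idx = np.arange(n)
        w_plus[idx < frag_max] = 0.0
        w_minus[idx > n - frag_max - 1] = 0.0

        # tag-boundary ambiguity: if the first genomic base of read 2 is a T
        # it merges into the polyT tag run and the maximal-run trimming
        # shifts (or rejects) the call -- the polyA-tailing caveat of the
        # assay. Read 2 starts at the terminus, whose complement is read
        # first: "+" lesions need base[s-1] != A, "-" lesions base[s+1] != T.
        is_a = (arr == b"A").astype(np.int64)
        is_t = (arr == b"T").astype(np.int64)
        prev_a = np.concatenate([[1], is_a[:-1]]).astype(bool)
        next_t = np.concatenate([is_t[1:], [1]]).astype(bool)
        w_plus[prev_a] = 0.0
        w_minus[next_t] = 0.0
        cum_a = np.concatenate([[0], np.cumsum(is_a)])
        cum_t = np.concatenate([[0], np.cumsum(is_t)])
        # "+" lesion at s: read 2 on "-", window is [s, s+20) counted as A
        hi = np.minimum(idx + window, n)
        a_count = cum_a[hi] - cum_a[idx]
        w_plus[a_count / np.maximum(hi - idx, 1) > 0.40] = 0.0
        # "-" lesion at s: read 2 on "+", window is [s-19, s+1) counted as T
        lo = np.maximum(idx - (window - 1), 0)
        t_count = cum_t[idx + 1] - cum_t[lo]
        w_minus[t_count / np.maximum(idx + 1 - lo, 1) > 0.40] = 0.0
        out[chrom] = (w_plus, w_minus)
    return out


def _apply_interval_multiplier(
    weights: np.ndarray, intervals: list[Interval], chrom: str, mult: float,
    strand: str | None = None,
) -> None:
    for r in intervals:
        if r.chrom != chrom:
            continue
        if strand is not None and r.strand != strand:
            continue
        weights[r.start : r.end] *= mult


def _calibrated_multiplier(
    genome: Genome, annotations: IntervalSet, cls: str, target_or: float
) -> float:
    """Density multiplier that makes the *measured* odds ratio of a class
    equal ``target_or``.

    The enrichment statistic divides the class site fraction by the class
    length fraction ``f`` (nonrepeat space); enriched sites also inflate the
    denominator, so a raw density ratio m yields OR = m / (1 + (m - 1) f).
    Inverting gives m = OR (1 - f) / (1 - OR f), feasible while OR f < 1.
    """
    from .enrich import _intersect_length  # local import avoids cycle

    merged = annotations.by_class(cls).merged()
    class_len = _intersect_length(merged, genome.nonrepeat_intervals())
    f = class_len / genome.nonrepeat_len if genome.nonrepeat_len else 0.0
    if target_or * f >= 1.0:
        raise ValueError(
            f"enrichment {target_or} for class {cls!r} infeasible at "
            f"length fraction {f:.3f}"
        )
    return target_or * (1 - f) / (1 - target_or * f)


def plant_sites(
    genome: Genome,
    annotations: IntervalSet | None,
    params: SimParams,
) -> TruthSites:
    """Draw lesion positions with per-nucleotide weights, element enrichment
    multipliers, transcriptional strand asymmetry and flagged hotspots."""
    rng = np.random.default_rng(params.seed)
    weights = _detectable_weights(genome, params)

    if annotations is not None:
        for cls, target_or in params.element_enrichment.items():
            recs = annotations.by_class(cls).records
            mult = _calibrated_multiplier(genome, annotations, cls, target_or)
            for chrom in genome.sequences:
                _apply_interval_multiplier(weights[chrom][0], recs, chrom, mult)
                _apply_interval_multiplier(weights[chrom][1], recs, chrom, mult)
        if params.strand_asymmetry != 1.0:
            genes = annotations.by_class("gene").records
            for chrom in genome.sequences:
                w_plus, w_minus = weights[chrom]
                # template strand is the strand opposite the gene strand
                _apply_interval_multiplier(
                    w_minus, genes, chrom, params.strand_asymmetry, strand="+")
                _apply_interval_multiplier(
                    w_plus, genes, chrom, params.strand_asymmetry, strand="-")

    chroms = list(genome.sequences)
    flat = np.concatenate(
        [weights[c][0] for c in chroms] + [weights[c][1] for c in chroms]
    )
    total_w = flat.sum()
    if total_w == 0:
        raise ValueError("no detectable positions to plant lesions on")
    probs = flat / total_w
    offsets = np.cumsum([0] + [genome.lengths[c] for c in chroms])
    half = offsets[-1]

    def decode(i: int) -> SiteKey:
        strand = "+" if i < half else "-"
        j = i if i < half else i - half
        ci = int(np.searchsorted(offsets, j, side="right")) - 1
        return chroms[ci], int(j - offsets[ci]), strand

    n_avail = int((flat > 0).sum())
    if params.n_hotspots > n_avail:
        raise ValueError("requested more hotspots than available positions")

    sites: dict[SiteKey, int] = {}
    hotspots: set[SiteKey] = set()
    lo, hi = params.hotspot_depth_range
    if params.n_hotspots:
        hot_idx = rng.choice(len(flat), size=params.n_hotspots,
                             replace=False, p=probs)
        depths = rng.integers(lo, hi + 1, size=params.n_hotspots)
        for i, d in zip(hot_idx, depths):
            key = decode(int(i))
            sites[key] = int(d)
            hotspots.add(key)
    n_hot_reads = sum(sites.values())
    n_single = max(0, params.n_site_reads - n_hot_reads)
    if n_single:
        single_idx = rng.choice(len(flat), size=n_single, replace=True, p=probs)
        for i in single_idx:
            key = decode(int(i))
            sites[key] = sites.get(key, 0) + 1
    return TruthSites(sites=sites, hotspots=hotspots,
                      class_weights=params.purine_weights)


def plant_uniform_sites(
    genome: Genome,
    n_reads: int,
    strand_weights: tuple[float, float] = (1.0, 1.0),
    seed: int = 0,
    exclude: tuple[str, int, int] | None = None,
) -> TruthSites:
    """Plant lesions uniformly over positions with a (+, -) strand weighting;
    used for strand-asymmetry scenarios such as the mitochondrial analysis.
    ``exclude`` removes a (chrom, start, end) window from both strands."""
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    lens = np.array([genome.lengths[c] for c in chroms])
    wp, wm = strand_weights
    sites: dict[SiteKey, int] = {}
    strands = rng.choice(np.array(["+", "-"]), size=n_reads,
                         p=[wp / (wp + wm), wm / (wp + wm)])
    ci = rng.choice(len(chroms), size=n_reads, p=lens / lens.sum())
    for k in range(n_reads):
        chrom = chroms[int(ci[k])]
        pos = int(rng.integers(0, genome.lengths[chrom]))
        if exclude is not None and chrom == exclude[0] and exclude[1] <= pos < exclude[2]:
            continue
        key = (chrom, pos, str(strands[k]))
        sites[key] = sites.get(key, 0) + 1
    return TruthSites(sites=sites, hotspots=set(), class_weights=(1, 1, 1, 1))


# ---------------------------------------------------------------------------
# Read simulation


def _tag_runs(rng: np.random.Generator, params: SimParams) -> tuple[str, str]:
    g = int(rng.integers(params.g_run_range[0], params.g_run_range[1] + 1))
    t = int(rng.integers(params.t_run_range[0], params.t_run_range[1] + 1))
    return TAG_R1_LITERAL + "G" * g, "T" * t


def _site_read(
    genome: Genome, key: SiteKey, frag_len: int,
    r1_tag: str, r2_tag: str, read_len: int,
) -> tuple[str, str]:
    """Read pair for one lesion: read 2 walks inward from the 3'OH terminus,
    read 1 carries genomic sequence from the opposite fragment end."""
    chrom, s, strand = key
    r2_glen = read_len - len(r2_tag)
    r1_glen = read_len - len(r1_tag)
    if strand == "+":
        # damaged strand "+": fragment [s - frag_len, s), terminus at s - 1
        seq2 = genome.fetch(chrom, s - r2_glen, s, "-")
        f_start = s - frag_len
        seq1 = genome.fetch(chrom, f_start, f_start + r1_glen, "+")
    else:
        # damaged strand "-": fragment covers [s + 1, s + 1 + frag_len)
        seq2 = genome.fetch(chrom, s + 1, s + 1 + r2_glen, "+")
        f_end = s + 1 + frag_len
        seq1 = genome.fetch(chrom, f_end - r1_glen, f_end, "-")
    return r1_tag + seq1, r2_tag + seq2


def _terminus_read(
    genome: Genome, chrom: str, terminus: int, strand: str, frag_len: int,
    r1_tag: str, r2_tag: str, read_len: int,
) -> tuple[str, str]:
    """Read pair for an unblocked 3'OH at ``terminus`` on ``strand``; the
    geometry equals a lesion one base past the terminus on that strand."""
    fake = terminus + 1 if strand == "+" else terminus - 1
    return _site_read(genome, (chrom, fake, strand), frag_len, r1_tag, r2_tag, read_len)


def _r1_start_ambiguous(genome: Genome, key: SiteKey, frag: int) -> bool:
    """True when read 1's first genomic base would be a G and so merge into
    the tag's G-run (risking rejection by the maximal-run filter)."""
    chrom, s, strand = key
    seq = genome.sequences[chrom]
    if strand == "+":
        return seq[s - frag] == "G"
    return seq[s + frag] == "C"  # complement read on "-" is a G


def _choose_frag(
    rng: np.random.Generator, genome: Genome, key: SiteKey,
    frag_lo: int, frag_hi: int, tries: int = 12,
) -> int:
    """Draw a fragment length whose far end avoids a G-initial read 1."""
    frag = int(rng.integers(frag_lo, frag_hi + 1))
    for _ in range(tries):
        if not _r1_start_ambiguous(genome, key, frag):
            return frag
        frag = int(rng.integers(frag_lo, frag_hi + 1))
    return frag


def _distinct_frags(
    rng: np.random.Generator, genome: Genome, key: SiteKey,
    frag_lo: int, frag_hi: int, n: int,
) -> list[int]:
    """``n`` distinct fragment lengths for one site, preferring lengths whose
    far end avoids a G-initial read 1."""
    candidates = frag_lo + rng.permutation(frag_hi - frag_lo + 1)
    clean = [int(f) for f in candidates if not _r1_start_ambiguous(genome, key, int(f))]
    ambiguous = [int(f) for f in candidates if int(f) not in set(clean)]
    pool = clean + ambiguous
    if n > len(pool):
        raise ValueError(
            f"site {key}: {n} reads exceed {len(pool)} distinct fragment lengths")
    return pool[:n]


def simulate_reads(
    genome: Genome,
    truth: TruthSites,
    params: SimParams,
) -> tuple[list[tuple[str, str, str]], dict[str, tuple[str, SiteKey | None]]]:
    """Emit tagged read pairs for planted truth plus unblocked background and
    PCR duplicates. Returns ``(reads, truth_map)`` where ``truth_map`` maps a
    read name to ("site", key) or ("background", None); duplicate reads map
    like their template.
    """
    rng = np.random.default_rng(params.seed + 1)
    frag_lo, frag_hi = params.fragment_range
    if params.read_len > frag_lo:
        raise ValueError("read_len longer than the shortest fragment")
    reads: list[tuple[str, str, str]] = []
    truth_map: dict[str, tuple[str, SiteKey | None]] = {}

    i = 0
    for key, n in sorted(truth.sites.items()):
        # distinct molecules get distinct fragment lengths so reads of one
        # site are never coordinate-identical (which deduplication would
        # otherwise collapse into a single read)
        for frag in _distinct_frags(rng, genome, key, frag_lo, frag_hi, n):
            r1_tag, r2_tag = _tag_runs(rng, params)
            s1, s2 = _site_read(genome, key, frag, r1_tag, r2_tag, params.read_len)
            name = f"read{i}"
            reads.append((name, s1, s2))
            truth_map[name] = ("site", key)
            i += 1

    n_sites = len(reads)
    rate = params.unblocked_background_rate
    n_bg = int(round(n_sites * rate / (1 - rate))) if rate > 0 else 0
    chroms = list(genome.sequences)
    lens = np.array([genome.lengths[c] for c in chroms], dtype=float)
    for _ in range(n_bg):
        chrom = chroms[int(rng.choice(len(chroms), p=lens / lens.sum()))]
        length = genome.lengths[chrom]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            terminus = int(rng.integers(frag_hi, length - 1))
            fake = terminus + 1
        else:
            terminus = int(rng.integers(1, length - frag_hi))
            fake = terminus - 1
        frag = _choose_frag(rng, genome, (chrom, fake, strand), frag_lo, frag_hi)
        r1_tag, r2_tag = _tag_runs(rng, params)
        s1, s2 = _terminus_read(
            genome, chrom, terminus, strand, frag, r1_tag, r2_tag, params.read_len)
        name = f"read{i}"
        reads.append((name, s1, s2))
        truth_map[name] = ("background", None)
        i += 1

    if params.duplicate_rate > 0:
        dup_flags = rng.random(len(reads)) < params.duplicate_rate
        for j in np.nonzero(dup_flags)[0]:
            name, s1, s2 = reads[int(j)]
            dup_name = f"{name}_dup"
            reads.append((dup_name, s1, s2))
            truth_map[dup_name] = truth_map[name]

    perm = rng.permutation(len(reads))
    return [reads[int(j)] for j in perm], truth_map


def make_spike_reads(
    spike_seqs: dict[str, str],
    mode: str,
    du_rate: float = 1 / 126,
    n_reads: int = 10_000,
    negative_rate_factor: float = 0.1,
    unblocked_rate: float = 0.0,
    n_hotspots: int = 0,
    hotspot_weight: float = 20.0,
    read_len: int = 100,
    params: SimParams | None = None,
    seed: int = 0,
) -> tuple[list[tuple[str, str, str]], TruthSites]:
    """Simulate reads from uracil-derived spike-in amplicons.

    ``positive`` plants abasic sites at thymines of either strand with
    per-position weight proportional to ``du_rate`` (the 1:125 dUTP:dTTP
    incorporation default); ``negative`` plants a smaller spontaneous
    depurination signal at purines; ``unblocked`` emits reads only from the
    amplicon 3' termini, recessed 1-3 nt to model heterogeneous PCR-product
    ends. In positive/negative mode a fraction ``unblocked_rate`` of reads
    comes from such termini (blocking failures). ``n_hotspots`` upweights
    randomly chosen target positions to create single-nucleotide hotspots.
    """
    if mode not in ("positive", "negative", "unblocked"):
        raise ValueError(f"unknown spike mode {mode!r}")
    for name, seq in spike_seqs.items():
        if len(seq) < 100:
            raise ValueError(f"spike {name} shorter than 100 bp")
    params = params or SimParams()
    rng = np.random.default_rng(seed)

    positions: list[SiteKey] = []
    weights: list[float] = []
    if mode != "unblocked":
        for name, seq in spike_seqs.items():
            for j, b in enumerate(seq):
                if mode == "positive":
                    if b == "T":
                        positions.append((name, j, "+"))
                        weights.append(du_rate)
                    elif b == "A":
                        positions.append((name, j, "-"))
                        weights.append(du_rate)
                else:
                    r = du_rate * negative_rate_factor
                    if b in "AG":
                        positions.append((name, j, "+"))
                        weights.append(r)
                    if b in "CT":
                        positions.append((name, j, "-"))
                        weights.append(r)
        # keep lesions clear of the amplicon ends so their fragments fit,
        # and off tag-ambiguous positions (read 2's first genomic base
        # would merge into the polyT run and shift the call)
        frag = min(120, min(len(s) for s in spike_seqs.values()) // 2)

        def usable(key: SiteKey) -> bool:
            name, j, strand = key
            seq = spike_seqs[name]
            if strand == "+":
                return j >= frag and seq[j - 1] != "A"
            return j + frag < len(seq) and seq[j + 1] != "T"

        keep = [k for k, key in enumerate(positions) if usable(key)]
        positions = [positions[k] for k in keep]
        weights = [weights[k] for k in keep]
        w = np.array(weights)
        if n_hotspots:
            hot = rng.choice(len(positions), size=n_hotspots, replace=False)
            w[hot] *= hotspot_weight
            hotspot_keys = {positions[int(h)] for h in hot}
        else:
            hotspot_keys = set()
        w /= w.sum()
    else:
        frag = min(120, min(len(s) for s in spike_seqs.values()) // 2)
        hotspot_keys = set()

    spike_names = list(spike_seqs)
    genome = Genome(sequences=dict(spike_seqs))
    reads: list[tuple[str, str, str]] = []
    sites: dict[SiteKey, int] = {}

    n_unblocked = n_reads if mode == "unblocked" else int(round(n_reads * unblocked_rate))
    n_lesion = n_reads - n_unblocked

    if n_lesion:
        idx = rng.choice(len(positions), size=n_lesion, p=w)
        for i, k in enumerate(idx):
            key = positions[int(k)]
            sites[key] = sites.get(key, 0) + 1
            r1_tag, r2_tag = _tag_runs(rng, params)
            frag_k = _choose_frag(rng, genome, key, frag - 10, frag)
            s1, s2 = _site_read(genome, key, frag_k, r1_tag, r2_tag, read_len)
            reads.append((f"spk{i}", s1, s2))

    for i in range(n_unblocked):
        name = spike_names[int(rng.integers(len(spike_names)))]
        length = len(spike_seqs[name])
        strand = "+" if rng.random() < 0.5 else "-"
        recess = int(rng.integers(1, 4))
        terminus = length - 1 - recess if strand == "+" else recess
        fake = terminus + 1 if strand == "+" else terminus - 1
        r1_tag, r2_tag = _tag_runs(rng, params)
        frag_k = _choose_frag(rng, genome, (name, fake, strand), frag - 10, frag)
        s1, s2 = _terminus_read(
            genome, name, terminus, strand, frag_k, r1_tag, r2_tag, read_len)
        reads.append((f"ub{i}", s1, s2))

    perm = rng.permutation(len(reads))
    reads = [reads[int(j)] for j in perm]
    truth = TruthSites(sites=sites, hotspots=hotspot_keys,
                       class_weights=(1, 1, 1, 1))
    return reads, truth


# ---------------------------------------------------------------------------
# Toy exact aligner


class _KmerIndex:
    """Exact substring lookup on the "+" strand via a k-mer seed table."""

    K = 16

    def __init__(self, genome: Genome):
        self.genome = genome
        self.table: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.sequences.items():
            for i in range(len(seq) - self.K + 1):
                self.table.setdefault(seq[i : i + self.K], []).append((chrom, i))

    def occurrences(self, query: str) -> list[tuple[str, int]]:
        if len(query) < self.K:
            hits = []
            for chrom, seq in self.genome.sequences.items():
                start = seq.find(query)
                while start != -1:
                    hits.append((chrom, start))
                    start = seq.find(query, start + 1)
            return hits
        out = []
        for chrom, i in self.table.get(query[: self.K], ()):
            if self.genome.sequences[chrom][i : i + len(query)] == query:
                out.append((chrom, i))
        return out


def _flag(read2: bool, strand: str, mate_strand: str, proper: bool, mapped: bool) -> int:
    f = 0x1  # paired
    if proper:
        f |= 0x2
    if not mapped:
        f |= 0x4
    if strand == "-":
        f |= 0x10
    if mate_strand == "-":
        f |= 0x20
    f |= 0x80 if read2 else 0x40
    return f


def align_exact_pairs(
    trimmed_pairs: list[tuple[str, str, str]], genome: Genome
) -> list[AlignedReadPair]:
    """Exact alignment of trimmed read pairs against a small genome.

    Unique full-length matches get MAPQ 60; multi-mappers MAPQ 0 (reported at
    their first locus); no match leaves the mate unmapped. Proper-pair flags
    are set when both mates map uniquely to opposite strands of one sequence
    within 1 kb, which yields read-2 flag 147 on "-" and 163 on "+".
    """
    index = _KmerIndex(genome)
    out: list[AlignedReadPair] = []
    for name, s1, s2 in trimmed_pairs:
        mates = []
        for seq in (s1, s2):
            fwd = index.occurrences(seq)
            rev = index.occurrences(revcomp(seq))
            hits = [(c, p, "+") for c, p in fwd] + [(c, p, "-") for c, p in rev]
            if not hits:
                mates.append((None, -1, "+", 0, False))
            else:
                hits.sort()
                chrom, pos, strand = hits[0]
                mapq = 60 if len(hits) == 1 else 0
                mates.append((chrom, pos, strand, mapq, True))
        (c1, p1, st1, q1, m1), (c2, p2, st2, q2, m2) = mates
        proper = (
            m1 and m2 and q1 == 60 and q2 == 60 and c1 == c2
            and st1 != st2 and abs(p1 - p2) < 1_000
        )
        # reference-oriented stored sequences, SAM style
        stored1 = s1 if st1 == "+" else revcomp(s1)
        stored2 = s2 if st2 == "+" else revcomp(s2)
        r1 = AlignedRead(
            chrom=c1, pos=p1, strand=st1, mapq=q1,
            flag=_flag(False, st1, st2, proper, m1),
            cigar=f"{len(s1)}M" if m1 else "", seq=stored1, mapped=m1)
        r2 = AlignedRead(
            chrom=c2, pos=p2, strand=st2, mapq=q2,
            flag=_flag(True, st2, st1, proper, m2),
            cigar=f"{len(s2)}M" if m2 else "", seq=stored2, mapped=m2)
        out.append(AlignedReadPair(name=name, r1=r1, r2=r2))
    return out


def write_sam(pairs: list[AlignedReadPair], genome: Genome, path) -> None:
    """Write aligned pairs as plain SAM with a proper header."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": l} for n, l in genome.lengths.items()],
    }
    refs = {n: i for i, n in enumerate(genome.lengths)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for p in pairs:
            for read, mate in ((p.r1, p.r2), (p.r2, p.r1)):
                seg = pysam.AlignedSegment(out.header)
                seg.query_name = p.name
                seg.flag = read.flag
                if read.mapped:
                    seg.reference_id = refs[read.chrom]
                    seg.reference_start = read.pos
                    seg.cigarstring = read.cigar
                else:
                    seg.reference_id = -1
                    seg.reference_start = -1
                seg.mapping_quality = read.mapq
                seg.query_sequence = read.seq
                if mate.mapped:
                    seg.next_reference_id = refs[mate.chrom]
                    seg.next_reference_start = mate.pos
                out.write(seg)


def write_fastq_pairs(reads: list[tuple[str, str, str]], path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for name, s1, s2 in reads:
            f1.write(f"@{name}/1\n{s1}\n+\n{'I' * len(s1)}\n")
            f2.write(f"@{name}/2\n{s2}\n+\n{'I' * len(s2)}\n")
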