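"""Core site-calling pipeline.

Raw paired reads are filtered for the library tag structure (read 1 begins
with the literal ``AGTTGCGGAT`` followed by a maximal G-run of 9-11, read 2
with a maximal T-run of 11-13, both trimmed off), aligned, deduplicated,
filtered on alignment quality and the genomic polyA artifact, and finally
converted to single-nucleotide lesion coordinates.

The lesion arithmetic: read 2 extends away from the tailed 3'OH terminus, so
the terminus is the reference base under read 2's first sequenced base, and
the lesion strand is the strand opposite the read. The abasic site itself
sits one base past that terminus in the 5'->3' direction of the lesion
strand (the AP endonuclease cleaves 5' of the abasic base), hence the +/-1
shift in AP mode; direct single-strand break calling uses offset 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .io_formats import AlignedReadPair, APSiteSet, Genome, revcomp

__all__ = [
    "TAG_R1_LITERAL",
    "FilterStats",
    "filter_tag_structure",
    "dedup_pairs",
    "filter_alignments_genomic",
    "filter_alignments_spike",
    "genomic_polyA_filter",
    "assign_sites",
    "run_pipeline",
    "read_fastq_pairs",
]

TAG_R1_LITERAL = "AGTTGCGGAT"
G_RUN_RANGE = (9, 11)
T_RUN_RANGE = (11, 13)
POLYA_WINDOW = 20
POLYA_MAX_T_FRAC = 0.40
MIN_MAPQ_GENOMIC = 20  # strict >
MIN_MAPQ_SPIKE = 20  # inclusive >=
SPIKE_MAX_DISTANCE = 500  # strict <


@dataclass
class FilterStats:
    """Per-stage accounting; counts are monotone non-increasing."""

    input_pairs: int = 0
    tag_pass: int = 0
    align_pass: int = 0
    dedup_pass: int = 0
    quality_pass: int = 0
    polya_pass: int = 0
    site_reads: int = 0
    out_of_bounds: int = 0
    rejections: dict[str, int] = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.rejections[reason] = self.rejections.get(reason, 0) + 1

    def to_rows(self) -> list[tuple[str, int]]:
        rows = [
            ("input_pairs", self.input_pairs),
            ("tag_pass", self.tag_pass),
            ("align_pass", self.align_pass),
            ("dedup_pass", self.dedup_pass),
            ("quality_pass", self.quality_pass),
            ("polya_pass", self.polya_pass),
            ("site_reads", self.site_reads),
            ("out_of_bounds", self.out_of_bounds),
        ]
        rows += [(f"reject:{k}", v) for k, v in sorted(self.rejections.items())]
        return rows


def _run_length(seq: str, base: str, start: int = 0) -> int:
    n = 0
    for ch in seq[start:]:
        if ch != base:
            break
        n += 1
    return n


def filter_tag_structure(
    name: str, seq1: str, seq2: str
) -> tuple[str, str] | tuple[None, str]:
    """Check the tag structure of a raw read pair and trim the tags.

    Returns ``(trimmed1, trimmed2)`` on acceptance, else ``(None, reason)``.
    The G- and T-runs must be maximal: a run longer than the allowed maximum
    (which cannot arise from the tailing primers) is rejected.
    """
    if not seq1.startswith(TAG_R1_LITERAL):
        return None, "r1_tag"
    g_run = _run_length(seq1, "G", len(TAG_R1_LITERAL))
    if not (G_RUN_RANGE[0] <= g_run <= G_RUN_RANGE[1]):
        return None, "r1_tag"
    t_run = _run_length(seq2, "T")
    if not (T_RUN_RANGE[0] <= t_run <= T_RUN_RANGE[1]):
        return None, "r2_tag"
    return seq1[len(TAG_R1_LITERAL) + g_run :], seq2[t_run:]


def dedup_pairs(pairs: Iterable[AlignedReadPair]) -> list[AlignedReadPair]:
    """Collapse PCR duplicates: pairs sharing both mates' orientation-aware
    5' end (chrom, first-base position, strand) keep the single best
    representative (highest summed MAPQ, then lexicographically first name).
    The 5' end, not the leftmost coordinate, is the duplicate key so that
    trimmed-tag length variation cannot split or merge duplicate groups."""
    best: dict[tuple, AlignedReadPair] = {}
    order: list[tuple] = []
    for p in pairs:
        key = (
            p.r1.chrom, p.r1.first_base_pos, p.r1.strand,
            p.r2.chrom, p.r2.first_base_pos, p.r2.strand,
        )
        cur = best.get(key)
        if cur is None:
            best[key] = p
            order.append(key)
        else:
            cand, incumbent = p.r1.mapq + p.r2.mapq, cur.r1.mapq + cur.r2.mapq
            if cand > incumbent or (cand == incumbent and p.name < cur.name):
                best[key] = p
    return [best[k] for k in order]


def _first_base_matches(pair: AlignedReadPair, genome: Genome | None) -> bool:
    """The first sequenced base of read 2 aligns as a reference match.

    CIGAR must not start (in sequencing orientation) with a clip/insertion;
    when a genome is supplied the base is additionally compared with the
    reference.
    """
    r2 = pair.r2
    if not r2.mapped or not r2.cigar:
        return False
    ops = _cigar_ops(r2.cigar)
    first_op = ops[0] if r2.strand == "+" else ops[-1]
    if first_op[1] not in "M=":
        return False
    if genome is not None and r2.seq:
        # stored sequence is reference-oriented (SAM style): the first
        # sequenced base is seq[0] on "+" and seq[-1] on "-"
        read_base = r2.seq[0] if r2.strand == "+" else r2.seq[-1]
        if read_base != genome.sequences[r2.chrom][r2.first_base_pos]:
            return False
    return True


def _cigar_ops(cigar: str) -> list[tuple[int, str]]:
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((int(num), ch))
            num = ""
    return ops


def filter_alignments_genomic(
    pair: AlignedReadPair, genome: Genome | None = None
) -> tuple[bool, str]:
    """Genomic alignment filter: read-2 MAPQ strictly above 20, read-2 flag
    147 or 163 (mapped proper pair, second in pair), and a matched first
    read-2 base."""
    if pair.r2.mapq is None:
        return False, "mapq"
    if pair.r2.mapq <= MIN_MAPQ_GENOMIC:
        return False, "mapq"
    if pair.r2.flag not in (147, 163):
        return False, "flag"
    if not _first_base_matches(pair, genome):
        return False, "first_base"
    return True, ""


def filter_alignments_spike(
    pair: AlignedReadPair, spike_lengths: dict[str, int], genome: Genome | None = None
) -> tuple[bool, str]:
    """Spike alignment filter: both mates uniquely mapped (MAPQ >= 20) to
    opposite strands of the same spike within 500 bp, matched first base."""
    if not (pair.r1.mapped and pair.r2.mapped):
        return False, "unmapped"
    if pair.r1.mapq < MIN_MAPQ_SPIKE or pair.r2.mapq < MIN_MAPQ_SPIKE:
        return False, "mapq"
    if pair.r1.chrom != pair.r2.chrom or pair.r1.chrom not in spike_lengths:
        return False, "chrom"
    if pair.r1.strand == pair.r2.strand:
        return False, "strand"
    if abs(pair.r1.pos - pair.r2.pos) >= SPIKE_MAX_DISTANCE:
        return False, "distance"
    if not _first_base_matches(pair, genome):
        return False, "first_base"
    return True, ""


def genomic_polyA_filter(
    pair: AlignedReadPair,
    genome: Genome,
    window: int = POLYA_WINDOW,
    max_t_frac: float = POLYA_MAX_T_FRAC,
) -> bool:
    """Reject read 2 positions downstream of genomic polyA runs.

    The ``window`` reference bases immediately 5' of read 2's first aligned
    base, read in read orientation on the read's alignment strand, must not
    exceed ``max_t_frac`` thymines. Windows truncated by a chromosome end are
    rescaled to the available length. Returns True when the pair passes.
    """
    r2 = pair.r2
    p = r2.first_base_pos
    length = genome.lengths[r2.chrom]
    if r2.strand == "+":
        start, end = max(0, p - window), p
        win = genome.fetch(r2.chrom, start, end, "+")
    else:
        start, end = p + 1, min(length, p + 1 + window)
        win = genome.fetch(r2.chrom, start, end, "-")
    if not win:
        return True
    return win.count("T") / len(win) <= max_t_frac


def assign_sites(
    pairs: Iterable[AlignedReadPair],
    lesion_offset: int,
    genome_lengths: dict[str, int],
    stats: FilterStats | None = None,
    **metadata,
) -> APSiteSet:
    """Convert surviving read pairs to lesion coordinates.

    The site strand is opposite the read-2 strand; the position is the read-2
    first-base coordinate shifted by ``lesion_offset`` (1 for abasic sites,
    0 for single-strand breaks) along the site strand's 5'->3' direction.
    Out-of-bounds positions are dropped and counted.
    """
    out = APSiteSet(**metadata)
    dropped = 0
    for pair in pairs:
        r2 = pair.r2
        p = r2.first_base_pos
        if r2.strand == "+":
            site_strand, pos = "-", p - lesion_offset
        else:
            site_strand, pos = "+", p + lesion_offset
        if 0 <= pos < genome_lengths[r2.chrom]:
            out.add(r2.chrom, pos, site_strand)
        else:
            dropped += 1
    if stats is not None:
        stats.out_of_bounds += dropped
        stats.site_reads = out.site_reads
    return out


def read_fastq_pairs(fastq1, fastq2) -> list[tuple[str, str, str]]:
    """Read mate FASTQ files into (name, seq1, seq2) tuples."""
    reads1 = list(SeqIO.parse(str(fastq1), "fastq"))
    reads2 = list(SeqIO.parse(str(fastq2), "fastq"))
    if len(reads1) != len(reads2):
        raise ValueError("mate FASTQ files differ in record count")
    out = []
    for a, b in zip(reads1, reads2):
        name = a.id.removesuffix("/1")
        if b.id.removesuffix("/2") != name:
            raise ValueError(f"mate name mismatch: {a.id} vs {b.id}")
        out.append((name, str(a.seq).upper(), str(b.seq).upper()))
    return out


def run_pipeline(
    read_pairs: Sequence[tuple[str, str, str]],
    genome: Genome,
    mode: str = "ap",
    spike: bool = False,
    aligned_pairs: Sequence[AlignedReadPair] | None = None,
    polya_filter: bool = True,
    **metadata,
) -> tuple[APSiteSet, FilterStats]:
    """Run the full pipeline on raw read pairs.

    Stages: tag filter/trim -> alignment (exact toy aligner on ``genome``
    unless pre-aligned ``aligned_pairs`` for the tag-passing reads are
    supplied) -> deduplication -> quality/flag/first-base filter -> genomic
    polyA artifact filter -> site assignment. ``mode`` is ``"ap"`` (offset 1)
    or ``"ssb"`` (offset 0); ``spike=True`` swaps in the spike-specific
    alignment filter and skips the polyA filter.
    """
    if mode not in ("ap", "ssb"):
        raise ValueError(f"mode must be 'ap' or 'ssb', got {mode!r}")
    stats = FilterStats(input_pairs=len(read_pairs))

    trimmed: list[tuple[str, str, str]] = []
    for name, s1, s2 in read_pairs:
        t1, t2 = filter_tag_structure(name, s1, s2)
        if t1 is None:
            stats.reject(t2)
        else:
            trimmed.append((name, t1, t2))
    stats.tag_pass = len(trimmed)

    if aligned_pairs is None:
        from .sim_data import align_exact_pairs

        aligned = align_exact_pairs(trimmed, genome)
    else:
        names = {n for n, _, _ in trimmed}
        aligned = [p for p in aligned_pairs if p.name in names]
    aligned = [p for p in aligned if p.r1.mapped and p.r2.mapped]
    stats.align_pass = len(aligned)

    # spike analyses keep duplicates: amplicon read stacks are legitimate
    # depth and the spike filter has no duplicate-removal step
    deduped = aligned if spike else dedup_pairs(aligned)
    stats.dedup_pass = len(deduped)

    if spike:
        spike_lengths = dict(genome.lengths)
        kept = []
        for p in deduped:
            ok, reason = filter_alignments_spike(p, spike_lengths, genome)
            if ok:
                kept.append(p)
            else:
                stats.reject(f"spike_{reason}" if reason else "spike")
        quality = kept
    else:
        quality = []
        for p in deduped:
            ok, reason = filter_alignments_genomic(p, genome)
            if ok:
                quality.append(p)
            else:
                stats.reject(reason)
    stats.quality_pass = len(quality)

    if polya_filter and not spike:
        surviving = [p for p in quality if genomic_polyA_filter(p, genome)]
        stats.rejections["polya"] = len(quality) - len(surviving)
    else:
        surviving = quality
    stats.polya_pass = len(surviving)

    offset = 1 if mode == "ap" else 0
    sites = assign_sites(surviving, offset, genome.lengths, stats, **metadata)
    sites.tag_pass_pairs = stats.tag_pass
    sites.assay = "AP" if mode == "ap" else "SSB"
    return sites, stats
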