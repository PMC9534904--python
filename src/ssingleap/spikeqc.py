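"""Spike-in quality control.

Spike-in amplicons with uracil-derived abasic sites at known thymine
positions quantify the assay: the unblocked-terminus background (fraction of
site reads at the four 3'-most bases of each spike strand), per-position
relative depth, depth-normalised comparison of paired positive/negative
libraries, single-nucleotide spike hotspots, and the negative-vs-positive
artifactual background estimate.
"""

from __future__ import annotations

import numpy as np

from .io_formats import APSiteSet

__all__ = [
    "spike_background",
    "spike_relative_depth",
    "spike_normalized_depth",
    "spike_hotspots",
    "negative_background_estimate",
    "nt_composition_at_spike_sites",
]

BACKGROUND_WINDOW = 4  # 3'-most bases per spike strand

PosKey = tuple[str, int, str]


def _terminal_window(spike: str, length: int, strand: str) -> set[int]:
    if strand == "+":
        return set(range(max(0, length - BACKGROUND_WINDOW), length))
    return set(range(0, min(BACKGROUND_WINDOW, length)))


def spike_background(sites: APSiteSet, spike_lengths: dict[str, int]) -> float | None:
    """Read-weighted fraction of spike site reads at the four 3'-most bases
    of either strand; None when there are no spike reads."""
    total = 0
    terminal = 0
    for (chrom, pos, strand), depth in sites.sites.items():
        if chrom not in spike_lengths:
            continue
        total += depth
        if pos in _terminal_window(chrom, spike_lengths[chrom], strand):
            terminal += depth
    if total == 0:
        return None
    return terminal / total


def spike_relative_depth(
    sites: APSiteSet, spike_lengths: dict[str, int]
) -> dict[PosKey, float]:
    """Per-position read depth divided by the total reads over all sites in
    the pooled spikes; values sum to 1."""
    depths = {
        k: d for k, d in sites.sites.items() if k[0] in spike_lengths
    }
    total = sum(depths.values())
    if total == 0:
        return {}
    return {k: d / total for k, d in depths.items()}


def spike_normalized_depth(
    lib_a: APSiteSet,
    lib_b: APSiteSet,
    spike_lengths: dict[str, int],
) -> tuple[dict[PosKey, float], dict[PosKey, float]]:
    """Depth-normalised per-position profiles comparable across a library
    pair (e.g. positive vs negative spikes).

    Each depth is divided by its library's total spike reads and by the
    fraction of reads mapping to that spike strand pooled over both
    libraries; positions on a strand with zero pooled reads are absent.
    """
    def spike_depths(lib: APSiteSet) -> dict[PosKey, int]:
        return {k: d for k, d in lib.sites.items() if k[0] in spike_lengths}

    da, db = spike_depths(lib_a), spike_depths(lib_b)
    tot_a, tot_b = sum(da.values()), sum(db.values())
    pooled_total = tot_a + tot_b
    strand_reads: dict[tuple[str, str], int] = {}
    for d in (da, db):
        for (chrom, _, strand), depth in d.items():
            strand_reads[(chrom, strand)] = strand_reads.get((chrom, strand), 0) + depth

    def normalise(d: dict[PosKey, int], lib_total: int) -> dict[PosKey, float]:
        out = {}
        for (chrom, pos, strand), depth in d.items():
            pooled_strand = strand_reads.get((chrom, strand), 0)
            if lib_total == 0 or pooled_strand == 0:
                continue
            strand_frac = pooled_strand / pooled_total
            out[(chrom, pos, strand)] = depth / lib_total / strand_frac
        return out

    return normalise(da, tot_a), normalise(db, tot_b)


def spike_hotspots(
    relative_depth: dict[PosKey, float], threshold: float
) -> list[PosKey]:
    """Positions whose value strictly exceeds the threshold and both flanking
    neighbours on the same spike strand (missing neighbours count as 0)."""
    out = []
    for (chrom, pos, strand), value in relative_depth.items():
        if value <= threshold:
            continue
        left = relative_depth.get((chrom, pos - 1, strand), 0.0)
        right = relative_depth.get((chrom, pos + 1, strand), 0.0)
        if value > left and value > right:
            out.append((chrom, pos, strand))
    return sorted(out)


def negative_background_estimate(
    positive_libs: list[APSiteSet] | APSiteSet,
    negative_libs: list[APSiteSet] | APSiteSet,
    spike_lengths: dict[str, int],
) -> float | None:
    """Maximum-bound artifact background: negative-library spike site reads
    over the paired positive library's, median across replicate pairs."""
    if isinstance(positive_libs, APSiteSet):
        positive_libs = [positive_libs]
    if isinstance(negative_libs, APSiteSet):
        negative_libs = [negative_libs]
    ratios = []
    for pos_lib, neg_lib in zip(positive_libs, negative_libs):
        pos_reads = sum(
            d for k, d in pos_lib.sites.items() if k[0] in spike_lengths)
        neg_reads = sum(
            d for k, d in neg_lib.sites.items() if k[0] in spike_lengths)
        if pos_reads == 0:
            continue
        ratios.append(neg_reads / pos_reads)
    if not ratios:
        return None
    return float(np.median(ratios))


def nt_composition_at_spike_sites(
    relative_depth: dict[PosKey, float],
    spike_seqs: dict[str, str],
    thresholds: list[float],
) -> dict[float, dict[str, float]]:
    """Base composition of spike hotspot positions at each relative-depth
    threshold (fractions of A/C/G/T among hotspot positions, base read on
    the site strand)."""
    comp_table: dict[float, dict[str, float]] = {}
    complement = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    for thr in thresholds:
        hits = spike_hotspots(relative_depth, thr)
        counts = {b: 0 for b in "ACGT"}
        for chrom, pos, strand in hits:
            base = spike_seqs[chrom][pos]
            if strand == "-":
                base = complement[base]
            if base in counts:
                counts[base] += 1
        n = sum(counts.values())
        comp_table[thr] = {b: (c / n if n else 0.0) for b, c in counts.items()}
    return comp_table
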