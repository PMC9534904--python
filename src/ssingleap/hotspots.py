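"""Single-nucleotide hotspot calling, sharing, group specificity and nulls.

A sample-level hotspot is a stranded genomic position detected with read
depth >= 2 (configurable) in one sample. A sample-shared hotspot recurs in
multiple samples. A group-specific (tissue- or age-specific) hotspot is
shared with depth >= 2 by at least two samples of one group while no sample
of any other group detects it with depth above 1. Two null models probe
whether these structures arise by chance: random re-placement of the same
number of reads in the nonrepeat genome, and permutation of sample labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import APSiteSet, Genome

__all__ = [
    "call_hotspots",
    "HotspotCatalog",
    "SharingSummary",
    "shared_hotspots",
    "sharing_percentages",
    "group_specific_hotspots",
    "simulate_random_sites",
    "permute_labels_shared_null",
]

SiteKey = tuple[str, int, str]
DEFAULT_MIN_DEPTH = 2


def call_hotspots(sites: APSiteSet, min_depth: int = DEFAULT_MIN_DEPTH) -> set[SiteKey]:
    """Stranded positions with depth >= ``min_depth``. Nested: raising the
    threshold can only shrink the set."""
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    return {k for k, d in sites.sites.items() if d >= min_depth}


@dataclass
class HotspotCatalog:
    """Per-sample site sets plus their hotspot calls and group labels."""

    samples: dict[str, APSiteSet]
    min_depth: int = DEFAULT_MIN_DEPTH
    labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.hotspots: dict[str, set[SiteKey]] = {
            sid: call_hotspots(s, self.min_depth) for sid, s in self.samples.items()
        }

    def sample_counts(self) -> dict[SiteKey, int]:
        """Pooled table: hotspot position -> number of samples carrying it."""
        counts: dict[SiteKey, int] = {}
        for hs in self.hotspots.values():
            for k in hs:
                counts[k] = counts.get(k, 0) + 1
        return counts


@dataclass
class SharingSummary:
    total: int  # pooled distinct hotspot positions
    by_n_samples: dict[int, int]  # exactly-k-samples -> count

    @property
    def singleton_percent(self) -> float:
        return 100.0 * self.by_n_samples.get(1, 0) / self.total if self.total else 0.0

    def shared_by_at_least(self, k: int) -> int:
        return sum(c for n, c in self.by_n_samples.items() if n >= k)

    def shared_percent(self, k: int) -> float:
        return 100.0 * self.shared_by_at_least(k) / self.total if self.total else 0.0


def shared_hotspots(
    catalog: HotspotCatalog, min_samples: int = 2
) -> tuple[set[SiteKey], SharingSummary]:
    """Hotspots found in >= ``min_samples`` samples, plus the sharing
    breakdown over the pooled catalog."""
    counts = catalog.sample_counts()
    by_n: dict[int, int] = {}
    for n in counts.values():
        by_n[n] = by_n.get(n, 0) + 1
    summary = SharingSummary(total=len(counts), by_n_samples=by_n)
    shared = {k for k, n in counts.items() if n >= min_samples}
    return shared, summary


def sharing_percentages(total: int, singleton: int, shared_counts: dict[int, int]) -> dict:
    """Percentage view of a sharing table given pooled totals; e.g. a catalog
    of 1,038,844 hotspots with 1,036,139 singletons is 99.7% sample-specific."""
    out = {"singleton_percent": 100.0 * singleton / total if total else 0.0}
    for k, n in shared_counts.items():
        out[f"shared_ge_{k}_percent"] = 100.0 * n / total if total else 0.0
    return out


def group_specific_hotspots(
    catalog: HotspotCatalog, grouping: dict[str, str] | None = None
) -> dict[str, set[SiteKey]]:
    """Group-specific hotspots per the two-clause definition: (1) hotspot
    (depth >= min_depth) in at least two samples of the group, and (2) depth
    <= min_depth - 1 in every sample of every other group."""
    grouping = grouping if grouping is not None else catalog.labels
    unlabeled = set(catalog.samples) - set(grouping)
    if unlabeled:
        raise ValueError(f"samples without a group label: {sorted(unlabeled)}")
    groups: dict[str, list[str]] = {}
    for sid, g in grouping.items():
        if sid in catalog.samples:
            groups.setdefault(g, []).append(sid)

    out: dict[str, set[SiteKey]] = {}
    for g, members in groups.items():
        counts: dict[SiteKey, int] = {}
        for sid in members:
            for k in catalog.hotspots[sid]:
                counts[k] = counts.get(k, 0) + 1
        candidates = {k for k, n in counts.items() if n >= 2}
        others = [sid for sid in catalog.samples if grouping[sid] != g]
        specific = set()
        for k in candidates:
            if all(
                catalog.samples[sid].sites.get(k, 0) < catalog.min_depth
                for sid in others
            ):
                specific.add(k)
        out[g] = specific
    return out


def simulate_random_sites(
    n_reads: int, genome: Genome, seed: int = 0, **metadata
) -> APSiteSet:
    """Random re-placement null: ``n_reads`` positions drawn uniformly with
    replacement from the nonrepeat genomic space on both strands, aggregated
    to depths."""
    rng = np.random.default_rng(seed)
    intervals = genome.nonrepeat_intervals()
    chroms, starts, lengths = [], [], []
    for chrom, arr in intervals.items():
        for s, e in arr:
            chroms.append(chrom)
            starts.append(int(s))
            lengths.append(int(e - s))
    lengths_arr = np.asarray(lengths, dtype=np.int64)
    space = int(lengths_arr.sum())
    if space == 0:
        raise ValueError("nonrepeat genomic space is empty")
    cum = np.concatenate([[0], np.cumsum(lengths_arr)])
    draws = rng.integers(0, space, size=n_reads)
    strand_draws = rng.integers(0, 2, size=n_reads)
    out = APSiteSet(**metadata)
    for d, sd in zip(draws, strand_draws):
        i = int(np.searchsorted(cum, d, side="right")) - 1
        pos = starts[i] + int(d - cum[i])
        out.add(chroms[i], pos, "+" if sd == 0 else "-")
    return out


def permute_labels_shared_null(
    catalog: HotspotCatalog,
    grouping: dict[str, str] | None = None,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[int, np.ndarray, float]:
    """Label-permutation null for group-specific hotspot counts.

    The statistic is the total number of group-specific hotspots over all
    groups. Sample labels are permuted ``n_perm`` times (hotspot sets stay
    fixed, only labels move) and the empirical p-value uses the add-one
    correction (1 + #null >= observed) / (n_perm + 1).
    """
    grouping = dict(grouping if grouping is not None else catalog.labels)
    observed = sum(len(v) for v in group_specific_hotspots(catalog, grouping).values())
    rng = np.random.default_rng(seed)
    sids = sorted(catalog.samples)
    labels = [grouping[s] for s in sids]
    if len(set(labels)) < 2:
        raise ValueError("need at least two groups to permute")
    null = np.empty(n_perm, dtype=np.int64)
    for b in range(n_perm):
        perm = rng.permutation(len(labels))
        permuted = {sids[i]: labels[int(perm[i])] for i in range(len(sids))}
        null[b] = sum(
            len(v) for v in group_specific_hotspots(catalog, permuted).values()
        )
    p = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return observed, null, p
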