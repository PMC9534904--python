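"""Readers/writers for external formats and the internal site representation.

Coordinate conventions, used everywhere in this package:

* all intervals are 0-based, half-open ``[start, end)``;
* single positions are 0-based;
* SAM records are converted from 1-based coordinates on read (pysam already
  does this); BED is written 0-based half-open.

Chromosome names are matched verbatim; no ``chr`` normalisation is applied.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, NamedTuple

import numpy as np
import pysam
from Bio import SeqIO

__all__ = [
    "Interval",
    "IntervalSet",
    "Genome",
    "APSite",
    "APSiteSet",
    "Variant",
    "VariantTable",
    "AlignedRead",
    "AlignedReadPair",
    "load_genome",
    "load_intervals",
    "write_intervals",
    "load_alignments",
    "load_sites",
    "write_sites",
    "load_variants",
    "load_expression",
    "load_size_profile",
    "merge_intervals",
    "PointIndex",
]

VALID_BASES = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised on malformed or out-of-bounds input records."""


# ---------------------------------------------------------------------------
# Intervals


class Interval(NamedTuple):
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str = "."  # "+", "-" or "."
    class_label: str = "feature"
    name: str = "."


@dataclass
class IntervalSet:
    """A BED-style collection of (possibly stranded) genomic features."""

    records: list[Interval] = field(default_factory=list)
    stranded: bool = False

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.records)

    def classes(self) -> list[str]:
        return sorted({r.class_label for r in self.records})

    def by_class(self, class_label: str) -> "IntervalSet":
        return IntervalSet(
            [r for r in self.records if r.class_label == class_label],
            stranded=self.stranded,
        )

    def validate(self, genome: "Genome") -> None:
        for r in self.records:
            if r.start >= r.end:
                raise FormatError(f"empty or inverted interval: {r}")
            if r.chrom not in genome.lengths:
                raise FormatError(f"unknown chromosome in interval: {r}")
            if r.start < 0 or r.end > genome.lengths[r.chrom]:
                raise FormatError(f"interval out of chromosome bounds: {r}")

    def merged(self) -> dict[str, np.ndarray]:
        """Merged intervals per chromosome as an (n, 2) int array, strand ignored."""
        return merge_intervals(self.records)

    def total_merged_length(self) -> int:
        return sum(int((m[:, 1] - m[:, 0]).sum()) for m in self.merged().values())


def merge_intervals(records: Iterable[Interval]) -> dict[str, np.ndarray]:
    """Merge overlapping/adjacent intervals per chromosome (strand-blind)."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in records:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    out: dict[str, np.ndarray] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        merged: list[list[int]] = []
        for s, e in ivs:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = np.asarray(merged, dtype=np.int64)
    return out


class PointIndex:
    """Fast point-in-merged-intervals lookup via searchsorted."""

    def __init__(self, merged: dict[str, np.ndarray]):
        self._starts = {c: m[:, 0] for c, m in merged.items()}
        self._ends = {c: m[:, 1] for c, m in merged.items()}

    def __call__(self, chrom: str, pos: int) -> bool:
        starts = self._starts.get(chrom)
        if starts is None or len(starts) == 0:
            return False
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < self._ends[chrom][i]


# ---------------------------------------------------------------------------
# Genome


@dataclass
class Genome:
    """Reference sequences plus a merged repeat mask.

    ``total_len`` is the single-strand base count; odds-ratio code that treats
    positions as stranded doubles it explicitly.
    """

    sequences: dict[str, str]
    repeat_mask: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise FormatError(f"invalid bases {sorted(bad)} in sequence {name!r}")
        self.lengths: dict[str, int] = {n: len(s) for n, s in self.sequences.items()}
        self.repeat_mask.validate(self)
        self._merged_mask = self.repeat_mask.merged()
        self._mask_index = PointIndex(self._merged_mask)

    @property
    def total_len(self) -> int:
        return sum(self.lengths.values())

    @property
    def masked_len(self) -> int:
        return sum(int((m[:, 1] - m[:, 0]).sum()) for m in self._merged_mask.values())

    @property
    def nonrepeat_len(self) -> int:
        return self.total_len - self.masked_len

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        """Sequence of ``[start, end)``; minus strand returns the reverse complement."""
        seq = self.sequences[chrom][start:end]
        return revcomp(seq) if strand == "-" else seq

    def base(self, chrom: str, pos: int, strand: str = "+") -> str:
        b = self.sequences[chrom][pos]
        return b.translate(_COMPLEMENT) if strand == "-" else b

    def is_masked(self, chrom: str, pos: int) -> bool:
        return self._mask_index(chrom, pos)

    def nonrepeat_intervals(self) -> dict[str, np.ndarray]:
        """Complement of the merged repeat mask, per chromosome."""
        out: dict[str, np.ndarray] = {}
        for chrom, length in self.lengths.items():
            mask = self._merged_mask.get(chrom)
            if mask is None or len(mask) == 0:
                out[chrom] = np.array([[0, length]], dtype=np.int64)
                continue
            gaps: list[tuple[int, int]] = []
            prev = 0
            for s, e in mask:
                if s > prev:
                    gaps.append((prev, int(s)))
                prev = max(prev, int(e))
            if prev < length:
                gaps.append((prev, length))
            out[chrom] = (
                np.asarray(gaps, dtype=np.int64)
                if gaps
                else np.empty((0, 2), dtype=np.int64)
            )
        return out


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def load_genome(fasta_path, repeat_bed=None) -> Genome:
    """Load a FASTA reference, optionally with a repeat-mask BED.

    BED chromosomes must be a subset of the FASTA chromosomes; an
    out-of-bounds mask record raises :class:`FormatError` naming the record.
    """
    with _open_text(fasta_path) as fh:
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    if not sequences:
        raise FormatError(f"no sequences parsed from {fasta_path}")
    mask = (
        load_intervals(repeat_bed, default_class="repeat")
        if repeat_bed is not None
        else IntervalSet()
    )
    return Genome(sequences=sequences, repeat_mask=mask)


# ---------------------------------------------------------------------------
# BED intervals

# BED6 columns: chrom start end name score strand; we store the feature class
# in the name column with an optional "class:name" form.


def load_intervals(path, default_class: str = "feature", stranded: bool | None = None) -> IntervalSet:
    records: list[Interval] = []
    saw_strand = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            name = fields[3] if len(fields) > 3 and fields[3] != "." else ""
            strand = fields[5] if len(fields) > 5 else "."
            if strand in ("+", "-"):
                saw_strand = True
            elif strand != ".":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            if ":" in name:
                class_label, feat_name = name.split(":", 1)
            else:
                class_label, feat_name = (name or default_class), "."
            records.append(Interval(chrom, start, end, strand, class_label, feat_name))
    return IntervalSet(records, stranded=saw_strand if stranded is None else stranded)


def write_intervals(intervals: IntervalSet, path) -> None:
    recs = sorted(intervals.records, key=lambda r: (r.chrom, r.start, r.end, r.strand))
    with open(path, "w") as fh:
        for r in recs:
            name = f"{r.class_label}:{r.name}" if r.name != "." else r.class_label
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\t0\t{r.strand}\n")


# ---------------------------------------------------------------------------
# AP / SSB site sets


class APSite(NamedTuple):
    chrom: str
    pos: int  # 0-based
    strand: str  # "+" or "-"
    depth: int  # supporting reads, >= 1


@dataclass
class APSiteSet:
    """Per-sample multiset of single-nucleotide lesion calls.

    ``tag_pass_pairs`` is the number of read pairs with the expected tag
    structure (the denominator of the global AP/SSB fraction); ``site_reads``
    always equals the sum of the per-site depths.
    """

    sample_id: str = "sample"
    tissue: str = ""
    age: float | None = None
    assay: str = "AP"  # AP, SSB, unblocked or spike
    enzyme: str = "APE1"  # APE1, EndoIV or none
    sites: dict[tuple[str, int, str], int] = field(default_factory=dict)
    tag_pass_pairs: int = 0

    def __post_init__(self) -> None:
        for key, depth in self.sites.items():
            if depth < 1:
                raise FormatError(f"site {key} has depth {depth} < 1")

    @property
    def site_reads(self) -> int:
        return sum(self.sites.values())

    @property
    def n_positions(self) -> int:
        return len(self.sites)

    def __iter__(self) -> Iterator[APSite]:
        for (chrom, pos, strand), depth in self.sites.items():
            yield APSite(chrom, pos, strand, depth)

    def add(self, chrom: str, pos: int, strand: str, depth: int = 1) -> None:
        key = (chrom, pos, strand)
        self.sites[key] = self.sites.get(key, 0) + depth

    def filtered(self, min_depth: int = 1, exclude_masked: "Genome | None" = None) -> "APSiteSet":
        """Copy keeping sites with depth >= ``min_depth``; optionally drop
        sites inside the genome's repeat mask."""
        sites = {
            k: d
            for k, d in self.sites.items()
            if d >= min_depth
            and (exclude_masked is None or not exclude_masked.is_masked(k[0], k[1]))
        }
        return replace(self, sites=sites)


def write_sites(sites: APSiteSet, path) -> None:
    """Write an APSiteSet as BED6 (score column = read depth)."""
    keys = sorted(sites.sites, key=lambda k: (k[0], k[1], k[2]))
    with open(path, "w") as fh:
        fh.write(
            f"#ssingleap sites sample={sites.sample_id} tissue={sites.tissue} "
            f"age={'' if sites.age is None else sites.age} assay={sites.assay} "
            f"enzyme={sites.enzyme} tag_pass_pairs={sites.tag_pass_pairs}\n"
        )
        for chrom, pos, strand in keys:
            depth = sites.sites[(chrom, pos, strand)]
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t.\t{depth}\t{strand}\n")


def load_sites(path) -> APSiteSet:
    meta: dict[str, str] = {}
    sites: dict[tuple[str, int, str], int] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{lineno}: expected BED6")
            chrom, start, end, _, score, strand = f[:6]
            start, end, depth = int(start), int(end), int(score)
            if end != start + 1:
                raise FormatError(f"{path}:{lineno}: site interval must be 1 bp")
            if strand not in ("+", "-"):
                raise FormatError(f"{path}:{lineno}: site strand must be +/-")
            if depth < 1:
                raise FormatError(f"{path}:{lineno}: depth {depth} < 1")
            sites[(chrom, start, strand)] = sites.get((chrom, start, strand), 0) + depth
    age = meta.get("age", "")
    return APSiteSet(
        sample_id=meta.get("sample", "sample"),
        tissue=meta.get("tissue", ""),
        age=float(age) if age else None,
        assay=meta.get("assay", "AP"),
        enzyme=meta.get("enzyme", "APE1"),
        sites=sites,
        tag_pass_pairs=int(meta.get("tag_pass_pairs", 0)),
    )


# ---------------------------------------------------------------------------
# Alignments


@dataclass
class AlignedRead:
    chrom: str | None
    pos: int  # 0-based leftmost reference coordinate
    strand: str  # "+" or "-"
    mapq: int
    flag: int
    cigar: str
    seq: str
    mapped: bool = True

    @property
    def first_base_pos(self) -> int:
        """Reference coordinate of the first *sequenced* base (the read 5' end)."""
        if self.strand == "+":
            return self.pos
        return self.pos + _cigar_ref_span(self.cigar) - 1


@dataclass
class AlignedReadPair:
    name: str
    r1: AlignedRead
    r2: AlignedRead


def _cigar_ref_span(cigar: str) -> int:
    span = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch in "MDN=X":
                span += int(num)
            num = ""
    return span


def _read_from_segment(seg: pysam.AlignedSegment) -> AlignedRead:
    return AlignedRead(
        chrom=seg.reference_name if not seg.is_unmapped else None,
        pos=seg.reference_start if not seg.is_unmapped else -1,
        strand="-" if seg.is_reverse else "+",
        mapq=seg.mapping_quality,
        flag=seg.flag,
        cigar=seg.cigarstring or "",
        seq=seg.query_sequence or "",
        mapped=not seg.is_unmapped,
    )


def load_alignments(path) -> tuple[list[AlignedReadPair], int]:
    """Assemble mate pairs from a SAM file, in order of first appearance.

    Returns ``(pairs, n_skipped)`` where ``n_skipped`` counts records whose
    mate never appears. Secondary/supplementary records are ignored.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[AlignedReadPair] = []
    order: list[str] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for seg in sam:
            if seg.is_secondary or seg.is_supplementary:
                continue
            mate = pending.pop(seg.query_name, None)
            if mate is None:
                pending[seg.query_name] = seg
                order.append(seg.query_name)
                continue
            first, second = (mate, seg) if mate.is_read1 else (seg, mate)
            pairs.append(
                AlignedReadPair(
                    name=seg.query_name,
                    r1=_read_from_segment(first),
                    r2=_read_from_segment(second),
                )
            )
    # preserve input order of completed pairs
    done = {p.name: p for p in pairs}
    ordered = [done[n] for n in order if n in done]
    return ordered, len(pending)


# ---------------------------------------------------------------------------
# Variants


class Variant(NamedTuple):
    chrom: str
    pos: int  # 0-based position of the VCF anchor base
    ref: str
    alt: str
    vtype: str  # SNP, insertion or deletion
    zygosity: str  # het or hom
    context: str | None  # + strand reference triplet centred on pos, if defined


@dataclass
class VariantTable:
    records: list[Variant] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.records)


def _classify_variant(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(alt) > len(ref):
        return "insertion"
    return "deletion"


def load_variants(path, genome: Genome) -> VariantTable:
    """Load a VCF into a :class:`VariantTable`.

    Zygosity comes from the first sample's GT field (het if the two alleles
    differ). Deletions keep the VCF anchor position; the trinucleotide
    ``context`` is the + strand reference triplet centred on the anchor base,
    absent at chromosome edges.
    """
    records: list[Variant] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            chrom, pos = rec.chrom, rec.pos - 1  # to 0-based
            if chrom not in genome.sequences:
                raise FormatError(f"variant chromosome {chrom!r} not in genome")
            ref = rec.ref
            genome_ref = genome.sequences[chrom][pos : pos + len(ref)]
            if genome_ref != ref:
                raise FormatError(
                    f"REF mismatch at {chrom}:{rec.pos}: VCF {ref!r} vs genome {genome_ref!r}"
                )
            zygosity = "hom"
            if rec.samples:
                gt = rec.samples[0].get("GT")
                if gt is not None and len(set(a for a in gt if a is not None)) > 1:
                    zygosity = "het"
            context = None
            if 1 <= pos <= genome.lengths[chrom] - 2:
                context = genome.sequences[chrom][pos - 1 : pos + 2]
            for alt in rec.alts or ():
                records.append(
                    Variant(
                        chrom=chrom,
                        pos=pos,
                        ref=ref,
                        alt=alt,
                        vtype=_classify_variant(ref, alt),
                        zygosity=zygosity,
                        context=context,
                    )
                )
    return VariantTable(records)


# ---------------------------------------------------------------------------
# Simple TSV inputs


def load_expression(path) -> dict[str, float]:
    """Gene expression table: two tab-separated columns, gene and TPM."""
    tpm: dict[str, float] = {}
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("gene\t"):
                continue
            gene, value = line.split("\t")[:2]
            tpm[gene] = float(value)
    return tpm


def load_size_profile(path) -> np.ndarray:
    """Fragment-size profile: (size_bp, intensity) rows -> (n, 2) float array."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("size"):
                continue
            size, intensity = line.split("\t")[:2]
            rows.append((float(size), float(intensity)))
    return np.asarray(rows, dtype=float)
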