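# Methods

This note documents the models, conventions and design choices behind the
package; the README gives the high-level pipeline. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Coordinate model

All internal coordinates are 0-based; intervals are half-open. SAM input is
converted on read (pysam), BED is written 0-based half-open, and VCF anchors
are converted to 0-based on load. Sites are stranded throughout: a lesion on
the "−" strand at position *p* is a different site from one on "+" at *p*,
and hotspot sharing across samples requires strand agreement.

The lesion arithmetic follows the assay chemistry. The AP endonuclease cuts
5' of the abasic base on the damaged strand, so the tailed 3'OH terminus is
the base one step 5' of the lesion. Read 2 extends away from the terminus on
the opposite strand; its first sequenced base therefore sits on the terminus
coordinate, the site strand is opposite the read strand, and the abasic base
is one step past the terminus in the site strand's 5'→3' direction. SSB mode
maps the terminus itself (offset 0). The two modes differ by exactly ±1
along the site strand on identical input, which the tests assert.

## Filtering conventions

* **Tag grammar.** Read 1 must start with the literal `AGTTGCGGAT` followed
  by a *maximal* G-run of 9–11; read 2 with a maximal T-run of 11–13. Runs
  longer than the maximum cannot arise from the tailing primers (a non-G/V
  base follows the homopolymer in the primer) and are rejected. The G-run is
  anchored after `…GAT`, not `…GATG`; both readings accept the canonical
  primer read.
* **Deduplication** keys on both mates' orientation-aware 5'-end coordinates
  (chromosome, first-base position, strand), Picard-style, not on the
  leftmost coordinate — tag-length variation shifts the leftmost coordinate
  of minus-strand mates and would otherwise merge distinct molecules. Ties
  keep the highest summed MAPQ, then the lexicographically first name.
  Spike-in analyses skip deduplication entirely: the spike filter has no
  duplicate-removal step and amplicon read stacks are legitimate depth.
* **Thresholds.** Genomic MAPQ is strictly > 20; the spike filter uses
  ≥ 20 and a strict < 500 bp mate distance. The first read-2 base must align
  as a match: no clip/insertion at the sequencing-side CIGAR end and, when a
  reference is available, base equality with the reference.
* **PolyA artifact window.** The 20 reference bases immediately 5' of
  read 2's first aligned base, read in read orientation on the read's
  alignment strand; a pair fails when T/length exceeds 0.40 strictly.
  Windows truncated by a chromosome end are rescaled to the available
  length rather than dropped.
* **Stage order**: tag → align → dedup → MAPQ/flag/first-base → polyA →
  assignment, with per-stage counters that conserve read totals.

## Simulator

The simulator generates what the protocol would sequence, not abstract
reads. For each lesion, read 2 is a T-run (11–13) plus the reverse
complement of the damaged strand walking inward from the terminus; read 1 is
the tag plus genomic sequence from the opposite fragment end. Fragments are
drawn uniformly from 150–400 bp (distinct lengths per molecule of one site,
so that genuine depth is never coordinate-identical and collapsed by
deduplication, while emitted PCR duplicates are exact copies and always
are). Unblocked background reads are emitted from random fragment 3' ends at
a configurable fraction (default 1.5%, matching the assay's observed 1–2%
range).

Defaults are the study conditions: per-nucleotide lesion weights
(A, G, C, T) = (0.39, 0.31, 0.15, 0.15), hotspot depth 3–8, duplicate rate
0.10, read length 100, tag runs G9–11/T11–13. Acceptance-scale runs use
8,000–50,000 reads on 200 kb genomes — sizes at which every recovered
quantity is within its sampling error in seconds of compute.

Three deliberate idealisations keep ground truth exact, and bound what
passing tests show about real data:

* **Detectability masking.** Lesions are not planted at positions the assay
  cannot faithfully report: positions whose fragments would not fit in the
  chromosome, positions the polyA filter removes by construction, and
  positions where read 2's first genomic base is a T and would merge into
  the tag run (the assay's documented polyA-tailing ambiguity at
  A-adjacent lesions; in real data such sites map to the nearest A).
  Fragment ends are likewise re-drawn (up to 12 times) away from G-initial
  read-1 starts. Real libraries contain these ambiguous molecules; the
  simulator's 100%-exact coordinate recovery therefore demonstrates the
  correctness of the coordinate arithmetic, not a precision the wet assay
  attains at ambiguous positions.
* **Calibrated element enrichment.** The `element_enrichment` mapping is the
  *measured* odds ratio to emulate. Because enriched sites also inflate the
  denominator of the observed fraction, a raw density ratio *m* yields
  OR = m/(1 + (m−1)f) at class length-fraction *f*; the simulator inverts
  this (m = OR(1−f)/(1−OR·f)) so the estimator recovers the configured
  value. No sequencing error, base-quality model, or PCR bias beyond a flat
  duplicate rate is simulated.
* **Spike-ins** are random 500 bp amplicons with G/C-clamped termini (a
  primer-design convention) so amplicon ends carry no T/A positions; planted
  uracil-derived lesions then never collide with the 4-base terminal
  background windows, and the unblocked-background estimator is unbiased.
  Unblocked termini are recessed 1–3 nt to model heterogeneous PCR product
  ends; with the +1 lesion shift every such read reports inside the
  terminal window. The negative-spike spontaneous rate is 0.1× the positive
  per-T rate, applied per purine; the expected negative/positive read ratio
  follows the planted weight masses, not a fixed 0.1.
* The **mitochondrial stand-in** (`make_mito_genome`) is a synthetic 16,299
  bp sequence whose heavy-strand purine fraction is set to the requested
  value (default 53.11%); the real mitochondrial reference is not bundled.

The toy aligner does exact substring search with a 16-mer seed index: unique
full-length matches get MAPQ 60 and proper-pair flags (read-2 flag 147 on
"−", 163 on "+"), multi-mappers MAPQ 0, others unmapped. It exists for
synthetic genomes only; real data should arrive as SAM from a production
aligner.

## Statistics

* Odds ratios are observed/expected fractions in three modes — pairwise
  (whole stranded genome, G = 2 × base count; the doubling is a convention
  choice consistent with stranded site identity and affects only the
  pairwise OR scale), read-weighted repeat classes (unmasked genome), and
  collapsed coordinates vs element classes (repeat-masked genome,
  nonrepeat lengths). Significance is the exact two-sided binomial test
  (scipy), with n = total sites/reads and p = expected fraction. Sites
  overlapping several element classes count in each; no multiple-testing
  correction is applied.
* Template/nontemplate: a site on the strand opposite a gene's annotated
  strand is template; sites overlapping multiple stranded elements count
  once per element. Expression strata are TPM ≤ 1, 1 < TPM ≤ 10, TPM > 10;
  genes without a TPM fall into the nonexpressed stratum with the
  element-level density defined as distinct nonrepeat sites per merged
  element bp.
* The technical-bias estimate is the squared Pearson correlation of read
  depths at the sample's site universe (all sites or depth ≥ 2 hotspots)
  against an unblocked control, zero where absent; undefined for constant
  vectors.
* TpCpN variant signature: heterozygous SNPs whose C allele sits in a TpC
  context *on the strand where the allele reads C* (reference-G variants
  are evaluated on the reverse complement); per-type odds ratios compare
  each type's share among site-overlapping variants with its genome-wide
  share among the three types.
* Empirical permutation p-values use the add-one correction
  (1 + #null ≥ obs)/(n + 1), so p is never 0 at 100 permutations. The
  permutation statistic is the total group-specific hotspot count over all
  groups; hotspot sets stay fixed and only labels move.
* APL integrates the electropherogram by trapezoid with linear
  interpolation at the 1/180/1000 bp band edges. The APF denominator counts
  tag-passing pairs before deduplication, the reading closest to "pairs
  with the expected tag structure".

## Degenerate inputs and numeric edges

Zero denominators return `None` (undefined) rather than raising: APF with no
tag-passing pairs, APL with zero band mass, background with no spike reads,
odds ratios against empty catalogs or fully-masked classes, r² with constant
vectors, Spearman rho with < 3 samples. Out-of-bounds site coordinates
(possible for termini at sequence edges) are dropped and counted. Variant
context is undefined at chromosome edges; such records are kept with
`context = None` and excluded from context-dependent analyses. Chromosome
names match verbatim.

## Known limitations

Real aligner behaviour (soft-clipping, mismatches near lesions, MAPQ
calibration) is out of scope — alignment arrives as SAM, and the exact toy
aligner is for synthetic data only. The simulator has no sequencing-error or
chromatin model, so enrichment recoveries validate the estimators, not the
biology. BAM/CRAM random access and bgzip beyond plain gzip are unsupported.
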