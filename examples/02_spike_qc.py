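"""Spike-in quality control: background and single-nucleotide precision.

Positive spike-ins carry uracil-derived abasic sites at thymines (1:126 per
T); 2% of reads are emitted from unblocked 3' termini. The terminal-window
background estimate should recover that 2%, and essentially all site reads
should map onto planted thymine lesions.
"""

from ssingleap.io_formats import Genome
from ssingleap.sim_data import make_spike_reads, make_spike_seqs
from ssingleap.sitecall import run_pipeline
from ssingleap.spikeqc import spike_background, spike_hotspots, spike_relative_depth

spikes = make_spike_seqs(n=3, length=500, seed=3)
genome = Genome(sequences=dict(spikes))

reads, truth = make_spike_reads(
    spikes, "positive", n_reads=50_000, unblocked_rate=0.02,
    n_hotspots=10, hotspot_weight=40.0, seed=4)
sites, stats = run_pipeline(reads, genome, mode="ap", spike=True)

bg = spike_background(sites, genome.lengths)
print(f"unblocked-terminus background: {bg:.4f} (planted 0.02)")

on_truth = sum(d for k, d in sites.sites.items() if k in truth.sites)
print(f"site reads at planted thymine lesions: {on_truth / sites.site_reads:.4f}")

rd = spike_relative_depth(sites, genome.lengths)
hot = spike_hotspots(rd, threshold=3.0 / len(rd))
recovered = len(set(hot) & truth.hotspots)
print(f"spike hotspots called: {len(hot)}, of {len(truth.hotspots)} planted "
      f"recovered: {recovered}")
# Background near 0.02 and on-truth fraction near 0.98 (the 2% remainder is
# the planted unblocked background) demonstrate low background and
# single-nucleotide precision.
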