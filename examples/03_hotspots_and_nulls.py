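"""Hotspot catalogs and the two null models.

Compares the fraction of depth>=2 positions in a hotspot-planted sample with
a random re-placement of the same reads, then shows that group-structured
samples share more hotspots than any of 100 label permutations.
"""

import numpy as np

from ssingleap.hotspots import (
    HotspotCatalog,
    call_hotspots,
    permute_labels_shared_null,
    shared_hotspots,
    simulate_random_sites,
)
from ssingleap.io_formats import APSiteSet
from ssingleap.sim_data import SimParams, make_genome, plant_sites

genome, annotations, _ = make_genome(seed=11)
params = SimParams(n_site_reads=6_000, n_hotspots=150, seed=12)
real = plant_sites(genome, annotations, params).as_site_set()
random = simulate_random_sites(real.site_reads, genome, seed=13)

f_real = len(call_hotspots(real, 2)) / real.n_positions
f_rand = len(call_hotspots(random, 2)) / random.n_positions
print(f"depth>=2 fraction, real: {f_real:.4f}, random placement: {f_rand:.4f}")

rng = np.random.default_rng(14)
samples, grouping = {}, {}
for g, group in enumerate(["brain", "liver", "heart"]):
    planted = {("c1", int(p), "+"): 2
               for p in rng.choice(np.arange(g * 60_000, (g + 1) * 60_000),
                                   30, replace=False)}
    for i in range(4):
        private = {("c1", int(p), "+"): 2
                   for p in rng.choice(200_000, 50, replace=False)}
        sid = f"{group}{i}"
        samples[sid] = APSiteSet(sites={**planted, **private})
        grouping[sid] = group

catalog = HotspotCatalog(samples)
_, summary = shared_hotspots(catalog)
print(f"pooled hotspots: {summary.total}, "
      f"found in one sample only: {summary.singleton_percent:.1f}%")
observed, null, p = permute_labels_shared_null(catalog, grouping,
                                               n_perm=100, seed=15)
print(f"group-specific hotspots observed: {observed}, "
      f"null max: {int(null.max())}, empirical p: {p:.4f}")
# Real data exceeds the random null severalfold, and the tissue structure
# beats every label permutation (p = 1/101 at 100 permutations).
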