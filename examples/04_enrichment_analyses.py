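"""Downstream association tests on called islands.

Takes a set of islands plus annotation tracks (genes, TFBS, a
recombination map) and runs the permutation and categorical machinery:
gene-overlap block permutation, hotspot definition, the weighted t-test
on recombination rates, Fisher category enrichment and the island-size
vs recombination ANCOVA.
"""

import numpy as np

import diffislands as di
from diffislands.enrichment import genic_mask

spec = di.SynthSpec(chrom_n_snps={"1": 1500, "2": 1500},
                    chrom_length_bp={"1": 5 * 10**7, "2": 5 * 10**7},
                    gene_density=2.0, hotspot_fraction=0.05, seed=31)
genes, tfbs, hotspots, recmap = di.synth_annotations(spec)
print(f"annotation tracks: {len(genes)} genes, {len(tfbs)} TFBS, "
      f"{len(hotspots)} recombination hotspots (rate > 10)")

rng = np.random.default_rng(1)
islands = []
for chrom in ("1", "2"):
    for _ in range(6):
        start = int(rng.integers(0, 45_000_000))
        islands.append(di.Island(chrom=chrom, start=start + 1,
                                 end=start + int(rng.integers(30_000, 600_000)),
                                 type="HDI", n_snps=20, n_fdr_snps=2,
                                 mean_fst=0.3, mean_het=0.3, mean_z=2.2))
chrom_lengths = dict(spec.chrom_length_bp)

res = di.permute_block_overlap(islands, genes, chrom_lengths,
                               n_perm=2000, seed=2)
print(f"gene overlap: {res.statistic:.0f} of {len(islands)} islands touch a "
      f"gene (null mean {res.null_mean:.1f}), permutation p = {res.p_value:.3f}")

res = di.permute_block_overlap(islands, hotspots, chrom_lengths,
                               n_perm=2000, seed=3)
print(f"hotspot overlap: observed {res.statistic:.0f}, p = {res.p_value:.3f}")

summary = di.summarize_islands(islands, recmap)
genic = genic_mask(islands, genes)
w = summary["n_rec_windows"].to_numpy().astype(float)
rates = summary["mean_rec_rate"].to_numpy()
bg_rates = recmap.rate
tt = di.weighted_ttest_recomb(rates, w, bg_rates, np.ones(len(bg_rates)))
print(f"island vs background recombination: weighted t = {tt.statistic:.2f}, "
      f"p = {tt.p_value:.3f}")

anc = di.ancova_size_recomb(summary["length_bp"], rates, genic)
print(f"size~rate ancova: slope(non-genic) = {anc['slope_nongenic']:+.3f}, "
      f"slope(genic) = {anc['slope_genic']:+.3f}, "
      f"interaction p = {anc['p_interaction']:.3f}")
print("a negative slope means larger islands sit in low-recombination "
      "regions; the interaction asks whether that relationship differs "
      "between genic and non-genic islands (here islands are random, so "
      "expect null results).")
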