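"""Call permutation-FDR peaks and score binding clusters on simulated data.

A site is a peak when its +/-3 nt window height beats a uniform
redistribution of the gene's events (FDR < 0.05); peaks closer than 20 nt
merge into clusters scored by peak plus adjacent signal.
"""
from clipfunnel import SimulationConfig, simulate_clip_events, simulate_transcriptome
from clipfunnel.peaks import call_peaks_and_clusters, region_distribution

cfg = SimulationConfig(n_genes=100, n_ligands=15, seed=42)
transcriptome, truth = simulate_transcriptome(cfg)
sites1, _ = simulate_clip_events(cfg, transcriptome, truth)

peaks, clusters = call_peaks_and_clusters(sites1, transcriptome.genes,
                                          n_perm=100, alpha=0.05, seed=7)
fractions, counts = region_distribution(clusters)
print(f"{len(peaks)} significant peaks -> {len(clusters)} clusters")
print("cluster distribution over gene regions:")
for region, frac in sorted(fractions.items(), key=lambda kv: -kv[1]):
    print(f"  {region:7s} {frac:6.1%}  ({counts[region]} clusters)")
# Planted signal sits in 3'UTRs, so well over half of the clusters should
# fall there, mirroring the region bias seen for a 3'UTR-binding RBP.
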