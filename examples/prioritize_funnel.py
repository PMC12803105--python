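"""Multistep prioritization funnel on simulated annotation resources.

Sequential filters: expressed -> ligand in either experiment -> ligand in
both -> top quarter of keyword citations -> disease-catalogue member -> top
quarter of lens enrichment.
"""
from clipfunnel import SimulationConfig, simulate_annotations, simulate_transcriptome
from clipfunnel.funnel import run_funnel
from clipfunnel.simulate import simulate_clip_events
from clipfunnel.peaks import call_peaks_and_clusters
from clipfunnel.scoring import build_profiles, retain_ligands

cfg = SimulationConfig(n_genes=300, n_ligands=40, seed=42)
transcriptome, truth = simulate_transcriptome(cfg)
ann = simulate_annotations(cfg, truth, transcriptome.gene_ids)

for exp, col in (("clip1", "in_clip1"), ("clip2", "in_clip2")):
    sites = simulate_clip_events(cfg, transcriptome, truth)[0 if exp == "clip1" else 1]
    _, clusters = call_peaks_and_clusters(sites, transcriptome.genes, n_perm=60, seed=7)
    prof = build_profiles(clusters, transcriptome.expression,
                          transcriptome.genes, transcriptome.utr3_seqs)
    calls = retain_ligands(prof)
    ann[col] = ann["gene_id"].isin(set(calls.loc[calls["retained"], "gene_id"]))

stages, final = run_funnel(ann)
for s in stages:
    print(f"  {s.name:28s} {s.n_in:4d} -> {s.n_out:4d}   ({s.predicate})")
print(f"final prioritized genes: {final}")
# Counts shrink monotonically; the survivors are ligands of both experiments
# that are also literature-supported, disease-linked and lens-enriched.
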