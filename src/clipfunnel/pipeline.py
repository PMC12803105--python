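"""End-to-end orchestration: simulate -> sites -> peaks -> clusters ->
profiles -> ligand sets -> UGU enrichment -> GSEA -> funnel.

Every stage writes its table under the output directory and the run manifest
records the config snapshot, package version, input checksums and per-stage
record counts.  A single global seed fans out to per-stage seeds through a
stable hash of the stage name, so reruns with the same config and seed are
byte-identical (the manifest carries no wall-clock timestamp by default for
exactly that reason)."""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import enrichment, funnel, io, peaks, scoring
from .simulate import SimulationConfig, simulate_annotations, simulate_clip_events, \
    simulate_de_table, simulate_transcriptome, substream

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters in one serializable bundle."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    window: int = 3
    max_gap: int = 20
    flank: int = 3
    n_perm: int = 100
    alpha: float = 0.05
    clip_top_frac: float = 0.10
    expr_top_frac: float = 0.005
    ugu_threshold: int = 3
    gsea_n_perm: int = 1000
    funnel_top_frac: float = 0.25
    seed: int = 0

    def validate(self) -> None:
        self.simulation.validate()
        if self.n_perm < 1 or self.gsea_n_perm < 1:
            raise ValueError("permutation counts must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        for name in ("clip_top_frac", "expr_top_frac", "funnel_top_frac"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.window < 0 or self.max_gap < 1 or self.flank < 0:
            raise ValueError("window/flank must be >= 0 and max_gap >= 1")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim.setdefault("base_composition", (0.25, 0.25, 0.25, 0.25))
            sim["base_composition"] = tuple(sim["base_composition"])
            sim = SimulationConfig(**sim)
        return cls(simulation=sim, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _clusters_for_output(clusters: pd.DataFrame) -> pd.DataFrame:
    out = clusters.copy()
    if "member_peak_positions" in out.columns:
        out["member_peak_positions"] = [
            ",".join(str(p) for p in v) for v in out["member_peak_positions"]
        ]
    return out


def run_pipeline(config: PipelineConfig, outdir, timestamps: bool = False) -> dict:
    """Execute the full analysis on simulated inputs and write every stage
    output under ``outdir``.  Returns the manifest dict (also written as
    manifest.json)."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.simulation
    counts: dict[str, int] = {}

    # --- inputs ---------------------------------------------------------
    transcriptome, truth = simulate_transcriptome(cfg)
    sites1, sites2 = simulate_clip_events(cfg, transcriptome, truth)
    de = simulate_de_table(cfg, truth, transcriptome.gene_ids)
    ann = simulate_annotations(cfg, truth, transcriptome.gene_ids)

    io.write_gtf(transcriptome.genes, outdir / "genes.gtf")
    io.write_fasta(transcriptome.utr3_seqs, outdir / "utr3.fa")
    io.write_crosslink_bed(sites1, outdir / "sites_clip1.bed")
    io.write_crosslink_bed(sites2, outdir / "sites_clip2.bed")
    expr_df = transcriptome.expression.rename_axis("gene_id").reset_index()
    io.write_tsv(expr_df, outdir / "expression.tsv")
    io.write_tsv(de, outdir / "de_table.tsv")
    io.write_ground_truth(truth, outdir / "ground_truth.json")
    counts["genes"] = len(transcriptome.genes)
    counts["sites_clip1"] = len(sites1)
    counts["sites_clip2"] = len(sites2)

    # --- peaks, clusters, profiles, retention per experiment ------------
    retained: dict[str, set[str]] = {}
    profiles_by_exp: dict[str, pd.DataFrame] = {}
    calls_by_exp: dict[str, pd.DataFrame] = {}
    for exp, sites in (("clip1", sites1), ("clip2", sites2)):
        pk, cl = peaks.call_peaks_and_clusters(
            sites, transcriptome.genes, n_perm=config.n_perm, window=config.window,
            alpha=config.alpha, max_gap=config.max_gap, flank=config.flank,
            seed=int(substream(config.seed, f"stage-{exp}").integers(2**31)))
        prof = scoring.build_profiles(cl, transcriptome.expression, transcriptome.genes,
                                      transcriptome.utr3_seqs)
        calls = scoring.retain_ligands(prof, config.clip_top_frac, config.expr_top_frac)
        io.write_tsv(pk, outdir / f"peaks_{exp}.tsv")
        io.write_tsv(_clusters_for_output(cl), outdir / f"clusters_{exp}.tsv")
        io.write_tsv(prof.merge(calls, on="gene_id"), outdir / f"profiles_{exp}.tsv")
        counts[f"peaks_{exp}"] = len(pk)
        counts[f"clusters_{exp}"] = len(cl)
        retained[exp] = set(calls.loc[calls["retained"], "gene_id"])
        profiles_by_exp[exp], calls_by_exp[exp] = prof, calls
        logger.info("%s: %d peaks, %d clusters, %d retained ligands",
                    exp, len(pk), len(cl), len(retained[exp]))

    # --- ligand sets and UGU enrichment ---------------------------------
    sets = enrichment.build_sets(retained["clip1"], retained["clip2"])
    set_summary = sets.summary()
    counts.update({f"ligands_{k}": v for k, v in set_summary.items()})
    ugu = scoring.ugu_enrichment(calls_by_exp["clip1"], profiles_by_exp["clip1"],
                                 threshold=config.ugu_threshold)

    # --- GSEA on the knockout DE table ----------------------------------
    ranked = enrichment.rank_genes(de)
    gsea_out = {}
    for name, gene_set in (("intersection", sets.intersection), ("union", sets.union)):
        if 0 < len(gene_set & set(ranked["gene_id"])) < len(ranked):
            res = enrichment.gsea_permutation_p(
                ranked["gene_id"], gene_set, n_perm=config.gsea_n_perm,
                rng=substream(config.seed, f"gsea-{name}"))
            gsea_out[name] = {"es": res.es, "p_perm": res.p_perm, "n_perm": res.n_perm,
                              "n_hits": res.n_hits,
                              "leading_edge_size": len(res.leading_edge)}
        else:
            gsea_out[name] = {"es": None, "p_perm": None, "n_perm": 0, "n_hits": 0,
                              "leading_edge_size": 0}

    # --- funnel ----------------------------------------------------------
    ann = ann.copy()
    ann["in_clip1"] = ann["gene_id"].isin(retained["clip1"])
    ann["in_clip2"] = ann["gene_id"].isin(retained["clip2"])
    io.write_tsv(ann, outdir / "annotation.tsv")
    stages, final_genes = funnel.run_funnel(ann, top_frac=config.funnel_top_frac)
    io.write_tsv(funnel.stages_to_frame(stages), outdir / "funnel_stages.tsv")
    io.write_gene_list(final_genes, outdir / "final_gene_list.txt")
    counts["funnel_final"] = len(final_genes)

    # --- enrichment report and manifest ----------------------------------
    report = {
        "ligand_sets": set_summary,
        "clip2_containment": sets.containment_of_clip2() if sets.clip2 else None,
        "ugu_enrichment": {"chi2": ugu.chi2, "p": ugu.p,
                           "observed": ugu.observed.astype(int).tolist()},
        "gsea": gsea_out,
        "funnel_stages": [(s.name, s.n_in, s.n_out) for s in stages],
    }
    (outdir / "enrichment_report.json").write_text(json.dumps(report, indent=1) + "\n")

    input_files = ["genes.gtf", "utr3.fa", "sites_clip1.bed", "sites_clip2.bed",
                   "expression.tsv", "de_table.tsv"]
    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "input_checksums": {f: _sha256(outdir / f) for f in input_files},
        "counts": counts,
    }
    if timestamps:
        import datetime
        manifest["timestamp"] = datetime.datetime.now().isoformat()
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1) + "\n")
    return manifest
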