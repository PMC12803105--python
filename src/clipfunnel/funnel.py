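"""Multistep gene prioritization funnel.

Starting from the expressed genes, the funnel keeps (1) ligands of either
CLIP experiment, (2) ligands of both, (3) genes in the upper quarter of
literature co-citations with the organ keyword, (4) members of the curated
disease-gene catalogue, and (5) genes in the upper quarter of the
lens-enrichment score.  Quartile cutoffs are rank-based (k = ceil(0.25 x
stage input size), ties broken by gene_id) and are computed within each
stage's surviving population by default, since the stages are sequential
filtrations; a flag switches to quartiles over the full starting table.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .enrichment import ContingencyResult, chi_square_2x2, rank_sum_test

REQUIRED_COLUMNS = ["gene_id", "expressed", "in_clip1", "in_clip2",
                    "n_pubs", "in_disease_list", "lens_enrichment"]


@dataclass
class FunnelStage:
    name: str
    predicate: str
    n_in: int
    n_out: int


def _top_quarter(df: pd.DataFrame, column: str, frac: float,
                 reference: pd.DataFrame | None = None) -> pd.Series:
    """Boolean mask of rows at or above the rank-based upper-fraction cutoff.

    With ``reference`` given, the cutoff rank is computed on the reference
    population instead of ``df`` (global-quartile mode)."""
    pop = df if reference is None else reference
    k = math.ceil(frac * len(pop))
    ordered = pop.sort_values([column, "gene_id"], ascending=[False, True], kind="mergesort")
    keep = set(ordered["gene_id"].head(k))
    return df["gene_id"].isin(keep)


def run_funnel(annotation: pd.DataFrame, top_frac: float = 0.25,
               global_quartiles: bool = False) -> tuple[list[FunnelStage], list[str]]:
    """Apply the default stage sequence and report per-stage counts.

    Returns (stages, final_gene_ids); final ids sorted for determinism.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in annotation.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if len(annotation) == 0:
        raise ValueError("empty annotation table")

    current = annotation.copy()
    reference = annotation if global_quartiles else None
    stages: list[FunnelStage] = []

    def apply(name: str, predicate: str, mask: pd.Series) -> None:
        nonlocal current
        n_in = len(current)
        current = current[mask.to_numpy(dtype=bool)]
        stages.append(FunnelStage(name, predicate, n_in, len(current)))

    apply("expressed", "expressed in the tissue", current["expressed"])
    apply("clip_union", "ligand in at least one CLIP experiment",
          current["in_clip1"] | current["in_clip2"])
    apply("clip_intersection", "ligand in both CLIP experiments",
          current["in_clip1"] & current["in_clip2"])
    apply("pubs_top_quarter", f"top {top_frac:.0%} of keyword citation counts",
          _top_quarter(current, "n_pubs", top_frac, reference))
    apply("disease_list", "member of the disease-gene catalogue",
          current["in_disease_list"])
    apply("lens_enrichment_top_quarter", f"top {top_frac:.0%} of lens enrichment",
          _top_quarter(current, "lens_enrichment", top_frac, reference))

    return stages, sorted(current["gene_id"])


def citation_presence_test(ligand_flags, n_pubs) -> ContingencyResult:
    """Chi-square test of (ligand vs not) x (no citation vs >= 1 citation)."""
    flags = pd.Series(list(ligand_flags), dtype=bool)
    pubs = pd.Series(list(n_pubs), dtype=int)
    cited = pubs >= 1
    table = [[int((flags & ~cited).sum()), int((flags & cited).sum())],
             [int((~flags & ~cited).sum()), int((~flags & cited).sum())]]
    return chi_square_2x2(table)


def lens_enrichment_compare(ligand_flags, lens_enrichment) -> float:
    """Two-sided rank-sum p comparing lens enrichment of ligands vs
    non-ligands (delegates to the shared Wilcoxon implementation)."""
    flags = pd.Series(list(ligand_flags), dtype=bool).to_numpy()
    scores = pd.Series(list(lens_enrichment), dtype=float).to_numpy()
    return rank_sum_test(scores[flags], scores[~flags])


def stages_to_frame(stages: list[FunnelStage]) -> pd.DataFrame:
    return pd.DataFrame([(s.name, s.predicate, s.n_in, s.n_out) for s in stages],
                        columns=["stage", "predicate", "n_in", "n_out"])
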