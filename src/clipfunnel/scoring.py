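"""Per-gene CLIP scores, the dual percentile retention rule and UGU counting.

The *CLIP score* of a gene is the sum of its 3'UTR cluster scores.  Genes in
the top 10% of CLIP scores are retained as ligands, except those among the
top 0.5% most highly expressed genes (abundant transcripts, crystallins in
the lens, attract non-specific cross-linking).  As a quality control, the
retained group's best cluster should be enriched for the UGU trinucleotide,
the binding determinant of CELF-family proteins.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .models import GeneModel, genomic_to_utr3_local

_VALID_NT = set("ACGUTacgut")


def clip_score(gene_clusters: pd.DataFrame) -> float:
    """Sum of cluster scores over clusters labelled 3UTR."""
    if len(gene_clusters) == 0:
        return 0.0
    sel = gene_clusters[gene_clusters["region"] == "3UTR"]
    return float(sel["cluster_score"].sum())


def count_ugu(sequence: str) -> int:
    """Overlapping occurrences of the UGU trinucleotide (T read as U,
    case-insensitive)."""
    bad = set(sequence) - _VALID_NT
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    s = sequence.upper().replace("T", "U")
    return sum(1 for i in range(len(s) - 2) if s[i:i + 3] == "UGU")


def extract_cluster_sequence(cluster_start: int, cluster_end: int, gene: GeneModel,
                             utr3_seq: str) -> str | None:
    """Sequence of the part of a cluster that lies in the gene's 3'UTR,
    in transcript orientation; None when the cluster misses the UTR."""
    local = genomic_to_utr3_local(gene, cluster_start, cluster_end)
    if local is None:
        return None
    return utr3_seq[local[0]:local[1]]


def max_ugu_per_gene(gene_clusters: pd.DataFrame, gene: GeneModel,
                     utr3_seq: str) -> int:
    """Highest UGU count among the gene's sequence-resolvable (3'UTR)
    clusters; 0 when none resolves to sequence."""
    best = 0
    for row in gene_clusters.itertuples(index=False):
        seq = extract_cluster_sequence(int(row.start), int(row.end), gene, utr3_seq)
        if seq:
            best = max(best, count_ugu(seq))
    return best


def build_profiles(clusters: pd.DataFrame, expression: pd.Series,
                   gene_models: dict[str, GeneModel],
                   utr3_seqs: dict[str, str] | None = None) -> pd.DataFrame:
    """Per-gene CLIP profiles over every gene in ``expression``.

    Columns: gene_id, clip_score, expression, n_3utr_clusters, max_ugu.
    Genes without 3'UTR clusters get clip_score 0 (so the ceil-rank
    thresholds of :func:`retain_ligands` see the full assayed population).
    """
    by_gene = dict(tuple(clusters.groupby("gene_id"))) if len(clusters) else {}
    rows = []
    for gid in expression.index:
        gclusters = by_gene.get(gid)
        if gclusters is None:
            gclusters = clusters.iloc[0:0]
        utr_clusters = gclusters[gclusters["region"] == "3UTR"] if len(gclusters) else gclusters
        score = float(utr_clusters["cluster_score"].sum()) if len(utr_clusters) else 0.0
        if utr3_seqs is not None and len(utr_clusters):
            mu = max_ugu_per_gene(utr_clusters, gene_models[gid], utr3_seqs[gid])
        else:
            mu = 0
        rows.append((gid, score, float(expression[gid]), int(len(utr_clusters)), mu))
    return pd.DataFrame(rows, columns=["gene_id", "clip_score", "expression",
                                       "n_3utr_clusters", "max_ugu"])


def _top_k_ids(profiles: pd.DataFrame, column: str, k: int) -> set[str]:
    ordered = profiles.sort_values([column, "gene_id"], ascending=[False, True],
                                   kind="mergesort")
    return set(ordered["gene_id"].head(k))


def retain_ligands(profiles: pd.DataFrame, clip_top_frac: float = 0.10,
                   expr_top_frac: float = 0.005,
                   threshold_after_exclusion: bool = False) -> pd.DataFrame:
    """Apply the dual percentile rule.

    A gene is retained when it ranks in the top ``ceil(clip_top_frac * N)``
    genes by CLIP score and is *not* among the top
    ``ceil(expr_top_frac * N)`` most highly expressed genes.  Both rank
    cutoffs are computed on the full input population (ties broken by
    gene_id), matching the two independent dashed thresholds of the original
    analysis; ``threshold_after_exclusion=True`` instead recomputes the CLIP
    cutoff after dropping the expression outliers.

    Returns a table with columns gene_id, retained, reason where reason is
    one of {retained, expression_outlier, below_clip_threshold}.
    """
    if len(profiles) == 0:
        raise ValueError("empty profile table")
    n = len(profiles)
    k_expr = math.ceil(expr_top_frac * n)
    expr_top = _top_k_ids(profiles, "expression", k_expr)
    if threshold_after_exclusion:
        pool = profiles[~profiles["gene_id"].isin(expr_top)]
        k_clip = math.ceil(clip_top_frac * len(pool))
        clip_top = _top_k_ids(pool, "clip_score", k_clip)
    else:
        k_clip = math.ceil(clip_top_frac * n)
        clip_top = _top_k_ids(profiles, "clip_score", k_clip)

    def classify(gid: str) -> tuple[bool, str]:
        if gid not in clip_top:
            return False, "below_clip_threshold"
        if gid in expr_top:
            return False, "expression_outlier"
        return True, "retained"

    out = profiles[["gene_id"]].copy()
    flags = [classify(g) for g in out["gene_id"]]
    out["retained"] = [f for f, _ in flags]
    out["reason"] = [r for _, r in flags]
    return out


def ugu_enrichment(calls: pd.DataFrame, profiles: pd.DataFrame, threshold: int = 3,
                   correction: bool = False):
    """Chi-square test of max-UGU >= threshold between retained and
    non-retained genes (2x2, 1 df, no continuity correction by default).

    Returns a ContingencyResult (observed, expected, chi2, p); rows are
    (retained, not retained), columns are (max_ugu >= threshold, below).
    """
    from .enrichment import chi_square_2x2

    merged = profiles.merge(calls[["gene_id", "retained"]], on="gene_id")
    rich = merged["max_ugu"] >= threshold
    table = np.array([
        [int((merged["retained"] & rich).sum()), int((merged["retained"] & ~rich).sum())],
        [int((~merged["retained"] & rich).sum()), int((~merged["retained"] & ~rich).sum())],
    ])
    return chi_square_2x2(table, correction=correction)
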